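"""The five surface descriptors of membrane-active cyclic peptides.

Lipophilicity enters per residue as a *lipophilic intensity*: the residue's
normalized scale value weighted by its fractional side-chain exposure
(side-chain SASA over the residue's maximal side-chain SASA).  Each
intensity points along the unit vector from the peptide's geometric center
to the side-chain heavy-atom centroid, giving a per-residue lipophilic
vector l_i·û_i.  From these:

* L_S   — total lipophilicity, the signed sum Σ l_i
* L_M   — lipophilic moment, |Σ l_i û_i| / N, the length-normalized
          resultant; large when lipophilic and lipophobic residues occupy
          opposite faces
* L_S*  — exclusive lipophilicity, the sum of intensities of residues that
          are lipophilic (positive scale value) *and* sit in the
          lipid-attractive hemisphere (positive projection on the resultant)

The electrostatic pair comes from the classified surface-sample set:

* E_S   — HBD surface area, Σ of sample areas on the positively charged
          hydrogen-bond-donor surface (Ų)
* E_M   — HBD amphipathic moment, the distance (Å) between the
          area-weighted HBD-surface centroid and the area-weighted centroid
          of the surface owned by uncharged lipophilic residues
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .lipo_scale import LipophilicityScale
from .structpep import Peptide, UnsupportedResidueError
from .surface import SurfaceSamples, classify_hbd, electrostatic_potential, shrake_rupley

__all__ = [
    "ResidueLipo",
    "DescriptorSet",
    "residue_lipophilicity",
    "lipophilic_moment",
    "lipophilic_resultant",
    "total_lipophilicity",
    "exclusive_lipophilicity",
    "hbd_surface_area",
    "hbd_amphipathic_moment",
    "loop_lipophilicity_profile",
    "compute_descriptors",
]


@dataclass
class ResidueLipo:
    residue_index: int
    intensity: float
    direction: np.ndarray        # unit vector (zeros when intensity is 0)
    normalized_scale: float      # residue's scale value, sign used for L_S*

    @property
    def vector(self) -> np.ndarray:
        return self.intensity * self.direction


@dataclass(frozen=True)
class DescriptorSet:
    label: str
    L_S: float
    L_S_star: float
    L_M: float
    E_S: float
    E_M: float

    def as_dict(self) -> dict[str, float]:
        return {
            "label": self.label, "L_S": self.L_S, "L_S_star": self.L_S_star,
            "L_M": self.L_M, "E_S": self.E_S, "E_M": self.E_M,
        }


def residue_lipophilicity(peptide: Peptide, scale: LipophilicityScale,
                          atom_sasa: np.ndarray) -> list[ResidueLipo]:
    """Per-residue lipophilic intensities and direction vectors.

    intensity_i = normalized_i × min(1, SASA_sidechain_i / sasa_max_i);
    a fully buried side chain contributes nothing regardless of its scale
    value, and Gly (no side chain) is identically zero.
    """
    missing = sorted({r.code for r in peptide.residues if r.code not in scale})
    if missing:
        raise UnsupportedResidueError(
            f"no scale entry for residue codes: {', '.join(missing)}"
        )
    center = peptide.center
    out = []
    offset = 0
    for res in peptide.residues:
        n_atoms = len(res.atoms)
        sc_sasa = sum(
            atom_sasa[offset + j] for j, a in enumerate(res.atoms) if a.is_sidechain
        )
        offset += n_atoms
        entry = scale[res.code]
        if entry.sasa_max <= 0:
            exposure = 0.0
        else:
            exposure = min(1.0, sc_sasa / entry.sasa_max)
        intensity = entry.normalized * exposure
        centroid = res.sidechain_heavy_centroid()
        if centroid is None or intensity == 0.0:
            direction = np.zeros(3)
        else:
            v = centroid - center
            norm = np.linalg.norm(v)
            direction = v / norm if norm > 0 else np.zeros(3)
        out.append(ResidueLipo(
            residue_index=res.index, intensity=intensity,
            direction=direction, normalized_scale=entry.normalized,
        ))
    return out


def lipophilic_resultant(residues: list[ResidueLipo]) -> np.ndarray:
    """Unnormalized resultant Σ l_i û_i of the per-residue lipophilic vectors."""
    if not residues:
        return np.zeros(3)
    return np.sum([r.vector for r in residues], axis=0)


def lipophilic_moment(residues: list[ResidueLipo]) -> float:
    """L_M: length of the resultant divided by the residue count."""
    if not residues:
        return 0.0
    return float(np.linalg.norm(lipophilic_resultant(residues))) / len(residues)


def total_lipophilicity(residues: list[ResidueLipo]) -> float:
    """L_S: signed sum of all intensities."""
    return float(sum(r.intensity for r in residues))


def exclusive_lipophilicity(residues: list[ResidueLipo],
                            resultant: np.ndarray | None = None) -> float:
    """L_S*: intensities of lipophilic residues in the lipid-attractive region.

    The region is the hemisphere of positive projection on the lipophilic
    resultant.  If the resultant vanishes there is no preferred direction;
    the sum then falls back to all positive intensities (with a warning).
    """
    if resultant is None:
        resultant = lipophilic_resultant(residues)
    norm = np.linalg.norm(resultant)
    if norm == 0.0:
        warnings.warn(
            "zero lipophilic resultant: L_S* falls back to the sum of all "
            "positive intensities"
        )
        return float(sum(r.intensity for r in residues if r.normalized_scale > 0
                         and r.intensity > 0))
    return float(sum(
        r.intensity for r in residues
        if r.normalized_scale > 0 and float(np.dot(r.direction, resultant)) > 0
    ))


def hbd_surface_area(samples: SurfaceSamples) -> float:
    """E_S: total area of the HBD-positive surface, Ų."""
    if samples.is_hbd is None:
        raise ValueError("classify_hbd must run before hbd_surface_area")
    return float(samples.areas[samples.is_hbd].sum())


def hbd_amphipathic_moment(peptide: Peptide, samples: SurfaceSamples,
                           scale: LipophilicityScale) -> float:
    """E_M: distance between the HBD and hydrophobic surface centroids, Å.

    The hydrophobic surface is the set of samples owned by residues with a
    positive normalized scale value and zero formal charge.  Returns 0 when
    either surface is empty.
    """
    if samples.is_hbd is None:
        raise ValueError("classify_hbd must run before hbd_amphipathic_moment")
    hbd_mask = samples.is_hbd
    hydrophobic_res = {
        r.index for r in peptide.residues
        if r.code in scale and scale[r.code].normalized > 0 and r.formal_charge == 0
    }
    hyd_mask = np.isin(samples.residue_index, list(hydrophobic_res))
    if not hbd_mask.any() or not hyd_mask.any():
        return 0.0

    def centroid(mask):
        w = samples.areas[mask]
        return (samples.points[mask] * w[:, None]).sum(axis=0) / w.sum()

    return float(np.linalg.norm(centroid(hbd_mask) - centroid(hyd_mask)))


def loop_lipophilicity_profile(peptide: Peptide, residues: list[ResidueLipo]
                               ) -> dict[int, float]:
    """Per-loop total lipophilicity: Σ of intensities of each loop's residues."""
    if all(r.loop_id is None for r in peptide.residues):
        raise ValueError("loops are not assigned; run assign_loops first")
    by_index = {r.residue_index: r.intensity for r in residues}
    profile: dict[int, float] = {k: 0.0 for k in range(1, 7)}
    for res in peptide.residues:
        if res.loop_id is not None:
            profile[res.loop_id] += by_index.get(res.index, 0.0)
    return profile


def compute_descriptors(peptide: Peptide, scale: LipophilicityScale,
                        probe: float = 1.4, n_points: int = 960) -> DescriptorSet:
    """Run the full surface pipeline and return all five descriptors."""
    atom_sasa, samples = shrake_rupley(peptide, probe=probe, n_points=n_points)
    electrostatic_potential(peptide, samples)
    classify_hbd(peptide, samples)
    rl = residue_lipophilicity(peptide, scale, atom_sasa)
    resultant = lipophilic_resultant(rl)
    return DescriptorSet(
        label=peptide.label,
        L_S=total_lipophilicity(rl),
        L_S_star=exclusive_lipophilicity(rl, resultant),
        L_M=lipophilic_moment(rl),
        E_S=hbd_surface_area(samples),
        E_M=hbd_amphipathic_moment(peptide, samples, scale),
    )
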