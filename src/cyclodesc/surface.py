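"""Solvent-accessible surface sampling, electrostatic potential and HBD surface.

The Shrake–Rupley construction places a deterministic quasi-uniform point
set on each atom's probe-inflated sphere and discards points buried inside
any neighbouring sphere.  Each surviving point carries an area weight
(sphere area / points per sphere), its owner atom and residue, and is the
substrate for the electrostatic surface descriptors: the potential is a
screened Coulomb sum with a distance-dependent dielectric ε(r) = 4r, and a
point belongs to the hydrogen-bond-donor (HBD) surface when its owner atom
is a donor atom of a positively charged side chain *and* the local
potential is positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structpep import Peptide

__all__ = [
    "SurfaceSamples",
    "sphere_points",
    "shrake_rupley",
    "electrostatic_potential",
    "classify_hbd",
]

_MIN_CHARGE_DISTANCE = 0.1  # Å; samples closer to a point charge are clamped


@dataclass
class SurfaceSamples:
    """Columnar set of exposed surface sample points."""

    points: np.ndarray                 # (m, 3) Å
    areas: np.ndarray                  # (m,) Ų quadrature weights
    owner_atom: np.ndarray             # (m,) flat atom index into peptide.atoms
    residue_index: np.ndarray          # (m,) 1-based residue index
    potential: np.ndarray | None = None
    is_hbd: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.areas)

    def to_tsv(self, path) -> None:
        pot = self.potential if self.potential is not None else np.full(len(self), np.nan)
        hbd = self.is_hbd if self.is_hbd is not None else np.zeros(len(self), dtype=bool)
        with open(path, "w") as fh:
            fh.write("#x\ty\tz\tarea\tpotential\thbd\tresidue_index\n")
            for i in range(len(self)):
                x, y, z = self.points[i]
                fh.write(
                    f"{x:.4f}\t{y:.4f}\t{z:.4f}\t{self.areas[i]:.6f}\t"
                    f"{pot[i]:.6g}\t{int(hbd[i])}\t{self.residue_index[i]}\n"
                )


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set (golden spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def _covariant_frame(coords: np.ndarray) -> np.ndarray:
    """Molecule-fixed orthonormal frame that rotates with the structure.

    Principal axes of the coordinate cloud, with each axis's sign fixed by
    the third moment of the projections.  Anchoring the quadrature point
    set to this frame makes the sampled surface exactly rigid-motion
    covariant, so surface areas are invariant to far better than the
    quadrature resolution.  Degenerate clouds (e.g. a single atom) fall
    back to the identity frame.
    """
    X = coords - coords.mean(axis=0)
    C = X.T @ X
    try:
        _, V = np.linalg.eigh(C)
    except np.linalg.LinAlgError:
        return np.eye(3)
    for k in range(3):
        proj = X @ V[:, k]
        s = float(np.sum(proj ** 3))
        if s < 0:
            V[:, k] = -V[:, k]
        elif s == 0.0:
            j = int(np.argmax(np.abs(V[:, k])))
            if V[j, k] < 0:
                V[:, k] = -V[:, k]
    if np.linalg.det(V) < 0:
        V[:, 2] = -V[:, 2]
    return V


def shrake_rupley(peptide: Peptide, probe: float = 1.4, n_points: int = 960
                  ) -> tuple[np.ndarray, SurfaceSamples]:
    """Per-atom SASA (Ų) and the exposed surface-sample set.

    Each atom's SASA is (exposed samples / n_points) × 4π(r + probe)².
    """
    if n_points < 16:
        raise ValueError("n_points must be at least 16")
    atoms = peptide.atoms
    coords = np.array([a.coords for a in atoms])
    radii = np.array([a.vdw_radius for a in atoms]) + probe
    res_of_atom = np.concatenate(
        [np.full(len(r.atoms), r.index, dtype=int) for r in peptide.residues]
    )
    n_atoms = len(atoms)
    unit = sphere_points(n_points) @ _covariant_frame(coords).T

    tree = cKDTree(coords)
    sasa = np.zeros(n_atoms)
    pts_out, areas_out, owner_out, res_out = [], [], [], []
    rmax = radii.max()
    for i in range(n_atoms):
        pts = coords[i] + radii[i] * unit
        neighbors = tree.query_ball_point(coords[i], radii[i] + rmax)
        neighbors = [j for j in neighbors if j != i
                     and np.linalg.norm(coords[j] - coords[i]) < radii[i] + radii[j]]
        exposed = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            exposed &= d2 > radii[j] ** 2
        n_exp = int(exposed.sum())
        area_per_point = 4.0 * np.pi * radii[i] ** 2 / n_points
        sasa[i] = n_exp * area_per_point
        if n_exp:
            pts_out.append(pts[exposed])
            areas_out.append(np.full(n_exp, area_per_point))
            owner_out.append(np.full(n_exp, i, dtype=int))
            res_out.append(np.full(n_exp, res_of_atom[i], dtype=int))

    if pts_out:
        samples = SurfaceSamples(
            points=np.vstack(pts_out),
            areas=np.concatenate(areas_out),
            owner_atom=np.concatenate(owner_out),
            residue_index=np.concatenate(res_out),
        )
    else:
        samples = SurfaceSamples(
            points=np.empty((0, 3)), areas=np.empty(0),
            owner_atom=np.empty(0, dtype=int), residue_index=np.empty(0, dtype=int),
        )
    return sasa, samples


def electrostatic_potential(peptide: Peptide, samples: SurfaceSamples
                            ) -> SurfaceSamples:
    """Screened Coulomb potential at every sample point (in place).

    V(p) = Σ_j q_j / (ε(r_j) · r_j) with ε(r) = 4r, i.e. q_j / (4 r_j²),
    summed over all atoms carrying a formal-charge share.  Units are
    e/Å² times the implicit 1/(4πε₀) prefactor — arbitrary but consistent,
    since only the sign and relative magnitude enter the descriptors.
    """
    charges, positions = [], []
    for a in peptide.atoms:
        if a.formal_charge_share != 0.0:
            charges.append(a.formal_charge_share)
            positions.append(a.coords)
    pot = np.zeros(len(samples))
    if charges:
        q = np.array(charges)
        pos = np.array(positions)
        d = np.linalg.norm(samples.points[:, None, :] - pos[None, :, :], axis=2)
        if np.any(d < _MIN_CHARGE_DISTANCE):
            warnings.warn("surface sample closer than 0.1 Å to a point charge; clamped")
            d = np.maximum(d, _MIN_CHARGE_DISTANCE)
        pot = (q[None, :] / (4.0 * d ** 2)).sum(axis=1)
    samples.potential = pot
    return samples


def classify_hbd(peptide: Peptide, samples: SurfaceSamples) -> SurfaceSamples:
    """Flag samples on the HBD surface (in place).

    A sample is HBD when its owner atom is a donor atom of a positively
    charged residue's side chain (or a polar hydrogen on one) and the local
    electrostatic potential is positive.
    """
    if samples.potential is None:
        raise ValueError("electrostatic_potential must be computed before classify_hbd")
    donor = np.array([a.is_hbd for a in peptide.atoms], dtype=bool)
    samples.is_hbd = donor[samples.owner_atom] & (samples.potential > 0)
    return samples
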