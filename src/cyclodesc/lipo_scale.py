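"""Normalized side-chain lipophilicity scale.

The scale anchors every residue's octanol/water logP on two reference
values: Arg⁺ (the most lipophobic side chain, raw logP −3.800) and Ile
(raw logP 2.657).  Raw values are mapped affinely to

    scaled     = (raw + 3.800) / 6.457
    normalized = scaled − scaled(Gly)

so that Gly is exactly 0, Ile − Arg⁺ spans exactly 1, positive values mean
lipophilic and negative lipophobic.  The packaged default stores the
normalized column (the only quantity consumed downstream) together with
each residue's maximal side-chain solvent accessibility, defined as the
side-chain SASA of X in the extended Gly-X-Gly tripeptide.

Ionizable side chains enter at their pH 7.4 state; His is a Boltzmann
mixture of its protonated and neutral forms (pKa 6.50 by default), and
half-cystine carries half the lipophilicity of the cystine dimer.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

from .structpep import UnsupportedResidueError, build_extended_tripeptide

__all__ = [
    "RAW_OFFSET",
    "RAW_SPAN",
    "ScaleEntry",
    "LipophilicityScale",
    "scale_and_normalize",
    "his_effective_logp",
    "his_protonated_fraction",
    "cys_from_cystine",
    "max_sidechain_sasa",
    "load_default_scale",
]

RAW_OFFSET = 3.800   # |raw logP(Arg+)|
RAW_SPAN = 6.457     # |raw logP(Arg+)| + |raw logP(Ile)|


@dataclass(frozen=True)
class ScaleEntry:
    code: str
    normalized: float
    sasa_max: float
    name: str = ""
    raw_logp: float | None = None
    scaled: float | None = None

    def __post_init__(self):
        if self.sasa_max < 0:
            raise ValueError(f"{self.code}: sasa_max must be non-negative")


def scale_and_normalize(raw_logp: float, scaled_gly: float) -> tuple[float, float]:
    """Apply the two affine maps taking a raw side-chain logP to the scale."""
    scaled = (raw_logp + RAW_OFFSET) / RAW_SPAN
    return scaled, scaled - scaled_gly


def his_protonated_fraction(ph: float = 7.4, pka: float = 6.50) -> float:
    """Henderson–Hasselbalch mole fraction of the protonated imidazolium."""
    return 1.0 / (1.0 + 10.0 ** (ph - pka))


def his_effective_logp(logp_protonated: float, logp_neutral: float,
                       ph: float = 7.4, pka: float = 6.50) -> float:
    """Population-weighted logP of His as a protonation-state mixture."""
    f = his_protonated_fraction(ph, pka)
    return f * logp_protonated + (1.0 - f) * logp_neutral


def cys_from_cystine(logp_cystine: float) -> float:
    """Half-cystine: each oxidized Cys carries half the cystine lipophilicity."""
    return logp_cystine / 2.0


class LipophilicityScale:
    """Mapping of residue codes to :class:`ScaleEntry`.

    Serialized as tab-separated text (code, name, normalized, sasa_max,
    optional raw_logp); users may append entries for further modified
    residues.
    """

    def __init__(self, entries: dict[str, ScaleEntry], ph: float = 7.4):
        self.entries = dict(entries)
        self.ph = ph

    def __contains__(self, code: str) -> bool:
        return code.upper() in self.entries

    def __getitem__(self, code: str) -> ScaleEntry:
        try:
            return self.entries[code.upper()]
        except KeyError:
            raise UnsupportedResidueError(
                f"residue code {code!r} not in lipophilicity scale"
            ) from None

    def __len__(self) -> int:
        return len(self.entries)

    def normalized(self, code: str) -> float:
        return self[code].normalized

    def sasa_max(self, code: str) -> float:
        return self[code].sasa_max

    def add_entry(self, entry: ScaleEntry) -> None:
        self.entries[entry.code.upper()] = entry

    def add_raw(self, code: str, name: str, raw_logp: float, sasa_max: float,
                scaled_gly: float) -> ScaleEntry:
        """Add a residue from a raw logP via the standard affine maps."""
        scaled, normalized = scale_and_normalize(raw_logp, scaled_gly)
        entry = ScaleEntry(code=code.upper(), name=name, normalized=normalized,
                           sasa_max=sasa_max, raw_logp=raw_logp, scaled=scaled)
        self.add_entry(entry)
        return entry

    # -- serialization ------------------------------------------------------

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#code\tname\tnormalized\tsasa_max\traw_logp\n")
            for e in self.entries.values():
                raw = "" if e.raw_logp is None else f"{e.raw_logp:g}"
                fh.write(f"{e.code}\t{e.name}\t{e.normalized:g}\t{e.sasa_max:g}\t{raw}\n")

    @classmethod
    def from_tsv(cls, path, ph: float = 7.4) -> "LipophilicityScale":
        entries = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            code, name, normalized, sasa_max = parts[:4]
            raw = None
            if len(parts) > 4 and parts[4] != "":
                raw = float(parts[4])
            entries[code.upper()] = ScaleEntry(
                code=code.upper(), name=name, normalized=float(normalized),
                sasa_max=float(sasa_max), raw_logp=raw,
            )
        return cls(entries, ph=ph)


def load_default_scale(ph: float = 7.4) -> LipophilicityScale:
    """Load the packaged 24-residue scale (20 standard + Ack, Cdr⁺, Kyw, Mee)."""
    ref = importlib.resources.files("cyclodesc") / "data" / "lipo_scale.tsv"
    with importlib.resources.as_file(ref) as path:
        return LipophilicityScale.from_tsv(path, ph=ph)


def max_sidechain_sasa(code: str, probe: float = 1.4, n_points: int = 960,
                       geometry: dict | None = None) -> float:
    """Side-chain SASA of X in the extended Gly-X-Gly tripeptide, Ų."""
    from .surface import shrake_rupley

    pep = build_extended_tripeptide(code, geometry=geometry)
    atom_sasa, _ = shrake_rupley(pep, probe=probe, n_points=n_points)
    central = pep.residues[1]
    total = 0.0
    offset = 0
    for res in pep.residues:
        for j, a in enumerate(res.atoms):
            if res is central and a.is_sidechain:
                total += atom_sasa[offset + j]
        offset += len(res.atoms)
    return total
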