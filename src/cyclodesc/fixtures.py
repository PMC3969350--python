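"""Synthetic structures, synthetic QSAR datasets and the packaged activity
table.

The toy-peptide generator emulates the two populations seen on the
(L_M, E_M) moment plot: pseudo-residues (one side-chain sphere each) are
placed on a sphere, and a *segregation* dial in [0, 1] controls how
strongly lipophilic residues sort into the +z hemisphere (and charged
ones into −z).  At segregation 1 the peptide is perfectly amphipathic
(high moments); at 0 residue identities are random over the surface (low
moments).

The QSAR twin draws descriptors from uniform ranges spanning the search
grid and generates responses from the dummy-variable model itself, so
that breakpoint and coefficient recovery can be tested against known
ground truth.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .qsar import ActivityRecord, tau_diagonal
from .structpep import Atom, BONDI_RADII, Peptide, make_residue

__all__ = [
    "SyntheticSpec",
    "make_toy_peptide",
    "make_cck_toy",
    "make_qsar_dataset",
    "load_table2",
    "activity_table",
    "CENSOR_LIMIT_ANTHELMINTIC",
]

#: highest tested concentration in the anthelmintic assay, µM
CENSOR_LIMIT_ANTHELMINTIC = 11.5

# pseudo-residue casting: codes with clearly lipophilic / polar / charged
# side chains in the packaged scale
_LIPOPHILIC_CODE = "ILE"   # normalized +0.38
_POLAR_CODE = "ASN"        # normalized −0.18
_CHARGED_CODE = "ARG"      # normalized −0.62, formal charge +1


@dataclass(frozen=True)
class SyntheticSpec:
    n_residues: int = 30
    fraction_lipophilic: float = 0.4
    spatial_segregation: float = 1.0    # 0 = scrambled, 1 = hemispheric split
    n_charged: int = 3
    radius: float = 10.0                # Å
    seed: int = 0

    def __post_init__(self):
        if self.n_residues < 4:
            raise ValueError("need at least 4 residues")
        if not 0.0 <= self.fraction_lipophilic <= 1.0:
            raise ValueError("fraction_lipophilic must be in [0, 1]")
        if not 0.0 <= self.spatial_segregation <= 1.0:
            raise ValueError("spatial_segregation must be in [0, 1]")


def _uniform_sphere(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def make_toy_peptide(spec: SyntheticSpec) -> Peptide:
    """Pseudo-residue peptide on a sphere with controlled amphipathicity.

    Each residue carries a backbone CA (inner shell) and a single
    side-chain sphere CB at the given radius.  Deterministic per seed; at
    segregation 1 every lipophilic residue sits at positive z.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_residues
    dirs = _uniform_sphere(rng, n)
    n_lip = int(round(spec.fraction_lipophilic * n))
    n_chg = min(spec.n_charged, n - n_lip)

    s = spec.spatial_segregation
    z_rank = np.argsort(np.argsort(-dirs[:, 2]))          # 0 = highest z
    random_rank = rng.permutation(n)
    score = s * z_rank + (1.0 - s) * random_rank
    order = np.argsort(score, kind="stable")              # top of +z first at s=1
    lip_idx = set(order[:n_lip].tolist())
    chg_idx = set(order[n - n_chg:].tolist()) if n_chg else set()

    if s == 1.0:
        # guarantee the hemispheric postcondition even if the +z hemisphere
        # holds fewer than n_lip points in this draw
        for i in list(lip_idx):
            if dirs[i, 2] <= 0:
                dirs[i, 2] = -dirs[i, 2]

    residues = []
    for i in range(n):
        if i in lip_idx:
            code = _LIPOPHILIC_CODE
        elif i in chg_idx:
            code = _CHARGED_CODE
        else:
            code = _POLAR_CODE
        u = dirs[i]
        ca = Atom(name="CA", element="C", coords=u * (spec.radius - 2.0),
                  vdw_radius=BONDI_RADII["C"])
        cb = Atom(name="CB", element="C", coords=u * spec.radius,
                  vdw_radius=BONDI_RADII["C"])
        residues.append(make_residue(code, i + 1, [ca, cb]))
    return Peptide(label=f"toy-s{spec.spatial_segregation:g}-{spec.seed}",
                   residues=residues, cyclic=False)


def make_cck_toy(loop_codes: list[list[str]], radius: float = 8.0,
                 label: str = "cck-toy") -> Peptide:
    """Full-ring cyclic toy with six Cys and the given loop contents.

    ``loop_codes[k]`` lists the residue codes of loop k+1 (may be empty).
    Residues are spaced evenly on a circle in the xy-plane, CA on the ring
    and a single CB sphere pushed outward, which makes loop geometry and
    descriptors analytic enough for oracle tests while still exercising
    the CCK annotation path.
    """
    if len(loop_codes) != 6:
        raise ValueError("need exactly six loops")
    codes: list[str] = []
    for loop in loop_codes:
        codes.append("CYS")
        codes.extend(c.upper() for c in loop)
    n = len(codes)
    residues = []
    for i, code in enumerate(codes):
        ang = 2.0 * np.pi * i / n
        u = np.array([np.cos(ang), np.sin(ang), 0.0])
        ca = Atom(name="CA", element="C", coords=u * (radius - 1.5),
                  vdw_radius=BONDI_RADII["C"])
        cb = Atom(name="CB", element="C", coords=u * radius,
                  vdw_radius=BONDI_RADII["C"])
        residues.append(make_residue(code, i + 1, [ca, cb]))
    cys = [i for i, c in enumerate(codes) if c == "CYS"]
    disulfides = [(cys[k] + 1, cys[k + 3] + 1) for k in range(3)]  # I–IV, II–V, III–VI
    return Peptide(label=label, residues=residues, cyclic=True,
                   disulfides=disulfides)


def make_qsar_dataset(n: int, k: float = 0.1, l: float = 0.05, m: float = 0.002,
                      critical_point: tuple[float, float] = (0.03750, 4.5000),
                      noise_sd: float = 0.02, seed: int = 0) -> pd.DataFrame:
    """Synthetic descriptor/response records from the dummy-variable model.

    Descriptors are drawn uniformly over ranges spanning the search grid
    (L_S* over [0, 4], E_S over [0, 300] Ų, L_M over [0, 0.050], E_M over
    [0, 9.000]) and y = k + l·τ·L_S* + m·τ·E_S + ε with ε ~ N(0, σ²).
    """
    if n < 10:
        raise ValueError("need n >= 10")
    rng = np.random.default_rng(seed)
    ls_star = rng.uniform(0.0, 4.0, n)
    e_s = rng.uniform(0.0, 300.0, n)
    l_m = rng.uniform(0.0, 0.050, n)
    e_m = rng.uniform(0.0, 9.000, n)
    tau = tau_diagonal(np.column_stack([l_m, e_m]), critical_point)
    y = k + l * tau * ls_star + m * tau * e_s + rng.normal(0.0, noise_sd, n)
    return pd.DataFrame({
        "label": [f"S{i + 1}" for i in range(n)],
        "L_S_star": ls_star, "E_S": e_s, "L_M": l_m, "E_M": e_m,
        "tau_true": tau, "y": y,
    })


def _parse_ic50(cell: str) -> tuple[float | None, bool, float | None]:
    cell = cell.strip()
    if cell in ("-", ""):
        return None, False, None
    if cell.startswith(">"):
        limit = float(cell[1:])
        return None, True, limit
    return float(cell), False, None


def activity_table() -> pd.DataFrame:
    """The packaged activity table as a DataFrame (IC50 µM per assay,
    censoring flags and limits)."""
    ref = importlib.resources.files("cyclodesc") / "data" / "activity_table.tsv"
    with importlib.resources.as_file(ref) as path:
        raw = pd.read_csv(path, sep="\t", comment=None, header=0,
                          names=["label", "protein", "subfamily",
                                 "anthelmintic", "cytotoxic"])
    rows = []
    for _, r in raw.iterrows():
        a_val, a_cen, a_lim = _parse_ic50(str(r["anthelmintic"]))
        c_val, c_cen, c_lim = _parse_ic50(str(r["cytotoxic"]))
        rows.append({
            "label": r["label"], "protein": r["protein"],
            "subfamily": r["subfamily"],
            "anthelmintic_ic50": a_val, "anthelmintic_censored": a_cen,
            "anthelmintic_limit": a_lim,
            "cytotoxic_ic50": c_val, "cytotoxic_censored": c_cen,
            "cytotoxic_limit": c_lim,
        })
    return pd.DataFrame(rows)


def load_table2() -> dict[str, dict[str, ActivityRecord]]:
    """Packaged activity records: label -> assay -> :class:`ActivityRecord`.

    Assays are ``"anthelmintic"`` (*H. contortus*) and ``"cytotoxic"``
    (U-937GTB); censored entries carry their censoring limit.
    """
    out: dict[str, dict[str, ActivityRecord]] = {}
    for _, r in activity_table().iterrows():
        per_assay = {}
        for assay in ("anthelmintic", "cytotoxic"):
            ic50 = r[f"{assay}_ic50"]
            ic50 = None if pd.isna(ic50) else float(ic50)
            censored = bool(r[f"{assay}_censored"])
            limit = r[f"{assay}_limit"]
            limit = None if pd.isna(limit) else float(limit)
            if ic50 is None and not censored:
                continue
            per_assay[assay] = ActivityRecord(
                label=r["label"], subfamily=r["subfamily"],
                ic50=ic50, censored=censored, limit=limit,
            )
        out[r["label"]] = per_assay
    return out
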