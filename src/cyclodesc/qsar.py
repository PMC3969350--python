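"""Dummy-variable QSAR linking surface descriptors to membrane activity.

Activity enters as a relative potency x = IC50(reference) / IC50(peptide),
so that more potent peptides have larger x and censored measurements
("> highest tested concentration") consistently map to x = 0.  The
response is the shifted transform y = log10(x + 1) (λ = 1 path), which
keeps censored records at exactly 0; the λ = −0.5 Box-Cox path uses the
shifted power (x + 1)^(−0.5), finite at x = 0 and order-inverting.

The regression is a two-predictor ordinary least squares gated by a 0/1
dummy τ:

    y_i = k + l·τ_ii·L*_S,i + m·τ_ii·E_S,i

where τ_ii = 0 iff both moments (L_M, E_M) of record i lie strictly below
a critical point (L_M^c, E_M^c), else 1.  The critical point is found by
exhaustive grid search, scoring every node by leave-one-out q²
(1 − PRESS/TSS) with r² as tie-break.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ActivityRecord",
    "DummyModel",
    "GridSearchResult",
    "relative_potency",
    "transform_activity",
    "classify_activity",
    "tau_diagonal",
    "fit_dummy_model",
    "grid_search_critical_point",
    "refit_excluding",
    "DEFAULT_GRID",
]

#: Fig-11-style grid: 17×17 nodes over [0, 0.050] × [0, 9.000]
#: (step = range/16 on both axes, so the reported critical points are nodes).
DEFAULT_GRID = {"lm_max": 0.050, "em_max": 9.000, "n_lm": 17, "n_em": 17}


@dataclass
class ActivityRecord:
    """One peptide's activity in one assay."""

    label: str
    subfamily: str = ""
    ic50: float | None = None          # µM
    censored: bool = False
    limit: float | None = None         # µM, censoring limit

    def __post_init__(self):
        if self.ic50 is not None and self.ic50 <= 0:
            raise ValueError(f"{self.label}: IC50 must be positive")
        if self.censored and self.limit is None:
            raise ValueError(f"{self.label}: censored record requires a limit")


def relative_potency(ic50: float | None, ic50_ref: float, censored: bool = False
                     ) -> float:
    """x = IC50(reference) / IC50: larger means more potent; censored → 0."""
    if ic50_ref <= 0:
        raise ValueError("reference IC50 must be positive")
    if censored:
        return 0.0
    if ic50 is None or ic50 <= 0:
        raise ValueError("IC50 must be positive for an uncensored record")
    return ic50_ref / ic50


def transform_activity(x: float, lam: float = 1.0) -> float:
    """Shifted activity transform; λ = 1 → log10(x+1), λ = −0.5 → (x+1)^−0.5."""
    if x < 0:
        raise ValueError("relative potency must be non-negative")
    if lam == 1.0:
        return float(np.log10(x + 1.0))
    if lam == -0.5:
        return float((x + 1.0) ** -0.5)
    raise ValueError(f"unsupported lambda {lam}; use 1.0 or -0.5")


def classify_activity(ratio: float | None) -> str:
    """Relative-activity class from the IC50(peptide)/IC50(reference) ratio.

    A2 (< 0.2, high), A1 ([0.2, 1.0], moderate), A0 (> 1.0, low),
    An (unknown).
    """
    if ratio is None:
        return "An"
    if ratio <= 0:
        raise ValueError("IC50 ratio must be positive")
    if ratio < 0.2:
        return "A2"
    if ratio <= 1.0:
        return "A1"
    return "A0"


def tau_diagonal(moments, critical_point) -> np.ndarray:
    """0/1 dummy per record: 0 iff both moments are strictly below the
    critical point, else 1 (boundary counts as "not below")."""
    m = np.asarray(moments, dtype=float).reshape(-1, 2)
    lc, ec = float(critical_point[0]), float(critical_point[1])
    below = (m[:, 0] < lc) & (m[:, 1] < ec)
    return (~below).astype(int)


@dataclass
class DummyModel:
    k: float
    l: float
    m: float
    critical_point: tuple[float, float]
    tau: np.ndarray
    r2: float
    q2: float
    F: float
    F_crit: float
    n: int
    residuals: np.ndarray = field(repr=False, default=None)
    labels: list[str] = field(repr=False, default=None)

    def predict(self, L_S_star, E_S, L_M, E_M) -> np.ndarray:
        tau = tau_diagonal(np.column_stack([L_M, E_M]), self.critical_point)
        return self.k + self.l * tau * np.asarray(L_S_star) + self.m * tau * np.asarray(E_S)

    def studentized_residuals(self) -> np.ndarray:
        """Internally studentized residuals for outlier *flagging* (never
        auto-applied)."""
        e = self.residuals
        dof = self.n - 3
        s2 = float(e @ e) / dof
        return e / np.sqrt(s2 * (1.0 - self._leverage))

    _leverage: np.ndarray = field(repr=False, default=None)


def _as_frame(records) -> pd.DataFrame:
    df = pd.DataFrame(records) if not isinstance(records, pd.DataFrame) else records.copy()
    required = {"L_S_star", "E_S", "L_M", "E_M", "y"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"records lack columns: {sorted(missing)}")
    if "label" not in df.columns:
        df["label"] = [f"r{i}" for i in range(len(df))]
    return df


def fit_dummy_model(records, critical_point) -> DummyModel:
    """OLS of y on [1, τ·L_S*, τ·E_S] with LOO q² and the model F test.

    q² = 1 − PRESS/TSS with PRESS from the leave-one-out identity
    e_(i) = e_i/(1 − h_ii); F = (SSR/2)/(SSE/(n−3)) against F(2, n−3)
    at 95%.
    """
    df = _as_frame(records)
    n = len(df)
    if n < 5:
        raise ValueError(f"need at least 5 records, got {n}")
    tau = tau_diagonal(df[["L_M", "E_M"]].to_numpy(), critical_point)
    if not tau.any():
        raise ValueError("degenerate model: all tau are zero at this critical point")
    y = df["y"].to_numpy(dtype=float)
    X = np.column_stack([
        np.ones(n), tau * df["L_S_star"].to_numpy(float), tau * df["E_S"].to_numpy(float)
    ])
    XtX = X.T @ X
    if np.linalg.matrix_rank(XtX) < 3:
        raise np.linalg.LinAlgError("singular fit: rank-deficient design matrix")
    beta = np.linalg.solve(XtX, X.T @ y)
    yhat = X @ beta
    e = y - yhat
    tss = float(np.sum((y - y.mean()) ** 2))
    sse = float(e @ e)
    ssr = tss - sse
    r2 = 1.0 - sse / tss if tss > 0 else 1.0
    h = np.einsum("ij,jk,ik->i", X, np.linalg.inv(XtX), X)
    h = np.minimum(h, 1.0 - 1e-12)
    press = float(np.sum((e / (1.0 - h)) ** 2))
    q2 = 1.0 - press / tss if tss > 0 else 1.0
    dof = n - 3
    F = (ssr / 2.0) / (sse / dof) if sse > 0 else np.inf
    F_crit = float(stats.f.ppf(0.95, 2, dof))
    model = DummyModel(
        k=float(beta[0]), l=float(beta[1]), m=float(beta[2]),
        critical_point=(float(critical_point[0]), float(critical_point[1])),
        tau=tau, r2=float(r2), q2=float(q2), F=float(F), F_crit=F_crit, n=n,
        residuals=e, labels=list(df["label"]),
    )
    model._leverage = h
    return model


@dataclass
class GridSearchResult:
    best: DummyModel
    lm_nodes: np.ndarray
    em_nodes: np.ndarray
    r2_surface: np.ndarray      # (n_lm, n_em); NaN at skipped nodes
    q2_surface: np.ndarray


def grid_search_critical_point(records, grid: dict | None = None) -> GridSearchResult:
    """Fit a dummy model at every grid node and return the q²-optimal one.

    Ties in q² break by r², then by lowest flat node index (L_M-major
    enumeration from the origin).  Degenerate nodes (all-τ-zero or singular)
    are skipped with a warning.
    """
    g = dict(DEFAULT_GRID, **(grid or {}))
    lm_nodes = np.linspace(0.0, g["lm_max"], g["n_lm"])
    em_nodes = np.linspace(0.0, g["em_max"], g["n_em"])
    r2s = np.full((len(lm_nodes), len(em_nodes)), np.nan)
    q2s = np.full_like(r2s, np.nan)
    best_model = None
    best_key = None
    n_skipped = 0
    for i, lc in enumerate(lm_nodes):
        for j, ec in enumerate(em_nodes):
            try:
                model = fit_dummy_model(records, (lc, ec))
            except (ValueError, np.linalg.LinAlgError):
                n_skipped += 1
                continue
            r2s[i, j] = model.r2
            q2s[i, j] = model.q2
            # maximize (q2, r2), then prefer the lowest flat index
            key = (model.q2, model.r2, -(i * len(em_nodes) + j))
            if best_key is None or key > best_key:
                best_key = key
                best_model = model
    if best_model is None:
        raise ValueError("all grid nodes degenerate; no model could be fitted")
    if n_skipped:
        warnings.warn(f"{n_skipped} degenerate grid nodes skipped")
    return GridSearchResult(
        best=best_model, lm_nodes=lm_nodes, em_nodes=em_nodes,
        r2_surface=r2s, q2_surface=q2s,
    )


def refit_excluding(records, exclude, critical_point=None, grid: dict | None = None
                    ) -> tuple[DummyModel, DummyModel]:
    """Refit after removing the named outliers; returns (full, refit).

    With ``critical_point`` given both models are fitted there; otherwise
    each is the result of its own grid search.
    """
    df = _as_frame(records)
    exclude = list(exclude)
    unknown = set(exclude) - set(df["label"])
    if unknown:
        raise KeyError(f"unknown labels in exclusion list: {sorted(unknown)}")
    kept = df[~df["label"].isin(exclude)]
    if critical_point is not None:
        full = fit_dummy_model(df, critical_point)
        refit = fit_dummy_model(kept, critical_point)
    else:
        full = grid_search_critical_point(df, grid).best
        refit = grid_search_critical_point(kept, grid).best
    return full, refit
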