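"""Per-feature differential expression: Box-Cox, Welch's t, Storey q-values.

The testing model: for each feature (array probe or gene), expression is
power-transformed toward normality with a Box-Cox transform whose exponent
lambda is estimated by profile maximum likelihood on all samples pooled,
then the tumor and normal group means are compared on the transformed
scale with Welch's unequal-variance two-sided t-test (H0: mu_T = mu_N).
P-values over all features of one family are converted to q-values with
Storey's FDR procedure (pi0 estimated from the p-value distribution).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

log = logging.getLogger(__name__)

__all__ = [
    "ExpressionStudy",
    "DERecord",
    "estimate_boxcox_lambda",
    "boxcox_transform",
    "welch_test",
    "storey_qvalues",
    "run_de",
]

TUMOR, NORMAL = "tumor", "normal"


@dataclass
class ExpressionStudy:
    """Feature-by-sample expression matrix with tumor/normal labels.

    ``values`` has shape (n_features, n_samples) and must be free of
    missing values; each group needs at least two samples.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    groups: list[str]
    platform: str = "microarray"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} inconsistent with "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if len(self.groups) != len(self.sample_ids):
            raise ValueError("one group label required per sample")
        if np.isnan(self.values).any():
            raise ValueError("expression matrix contains missing values")
        bad = set(self.groups) - {TUMOR, NORMAL}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        for g in (TUMOR, NORMAL):
            if self.groups.count(g) < 2:
                raise ValueError(f"need >= 2 {g} samples, got {self.groups.count(g)}")

    @property
    def group_mask(self) -> np.ndarray:
        """Boolean mask of tumor samples."""
        return np.asarray([g == TUMOR for g in self.groups])

    def subset(self, feature_ids: Sequence[str]) -> "ExpressionStudy":
        idx = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in feature_ids if f not in idx]
        if missing:
            raise KeyError(f"features not in study: {missing}")
        rows = [idx[f] for f in feature_ids]
        return ExpressionStudy(
            list(feature_ids), list(self.sample_ids), self.values[rows],
            list(self.groups), self.platform,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, groups: Sequence[str], platform: str = "microarray"):
        return cls(
            [str(i) for i in df.index], [str(c) for c in df.columns],
            df.to_numpy(dtype=float), list(groups), platform,
        )


@dataclass(frozen=True)
class DERecord:
    """Differential-expression result for one feature."""

    feature_id: str
    lam: float  # Box-Cox exponent used for the transform
    mean_tumor: float
    mean_normal: float
    t_stat: float
    df: float
    p_value: float
    q_value: float = float("nan")
    direction: str = "up"
    shifted: bool = False  # non-positive values shifted before transform

    @property
    def lambda_(self) -> float:
        return self.lam


# ---------------------------------------------------------------------------
# Box-Cox

# integer construction keeps 0.0 exactly on the grid
_GRID = np.arange(-300, 301) / 100.0


def _grid_llf(x: np.ndarray, grid: np.ndarray = _GRID) -> np.ndarray:
    """Box-Cox profile log-likelihood on a lambda grid, vectorised.

    llf(lam) = (lam - 1) * sum(log x) - n/2 * log(var(y_lam)), with
    y_lam = (x^lam - 1)/lam (log x at lam = 0).
    """
    logx = np.log(x)
    n = x.size
    # y for all grid lambdas at once: exp(lam * log x) guarded at lam=0
    lam = grid[:, None]
    with np.errstate(over="ignore", invalid="ignore"):
        y = np.where(lam == 0, logx[None, :], (np.exp(lam * logx[None, :]) - 1.0) / np.where(lam == 0, 1.0, lam))
        var = y.var(axis=1)
    llf = (grid - 1.0) * logx.sum() - 0.5 * n * np.log(var)
    llf[~np.isfinite(llf)] = -np.inf
    return llf


def estimate_boxcox_lambda(values: np.ndarray, feature_id: str = "<vector>") -> float:
    """Profile-ML Box-Cox exponent on the grid [-3, 3], refined locally.

    Coarse grid search at step 0.01 followed by bounded golden-section
    refinement (tolerance 1e-5).  A constant vector has no defined
    optimum and returns ``nan`` (callers fall back to the identity
    transform); any non-positive value is an error.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError(f"{feature_id}: need >= 3 values to estimate lambda")
    if np.any(x <= 0):
        raise ValueError(f"{feature_id}: Box-Cox requires strictly positive values")
    if np.ptp(x) == 0:
        log.warning("%s: constant vector, Box-Cox lambda undefined", feature_id)
        return float("nan")
    llf = _grid_llf(x)
    i = int(np.argmax(llf))
    lo = _GRID[max(0, i - 1)]
    hi = _GRID[min(_GRID.size - 1, i + 1)]
    res = optimize.minimize_scalar(
        lambda lam: -stats.boxcox_llf(lam, x),
        bounds=(lo, hi), method="bounded", options={"xatol": 1e-5},
    )
    return float(res.x)


def boxcox_transform(values: np.ndarray, lam: float) -> np.ndarray:
    """y = (x^lam - 1)/lam for lam != 0, ln x for lam = 0; identity if lam is nan."""
    x = np.asarray(values, dtype=float)
    if np.isnan(lam):
        return x.copy()
    if lam == 0:
        return np.log(x)
    # expm1 formulation is stable as lam -> 0
    return np.expm1(lam * np.log(x)) / lam


# ---------------------------------------------------------------------------
# Welch's t-test


def welch_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Welch two-sample two-sided t-test: returns (t, df, p).

    t = (mean(x) - mean(y)) / sqrt(s2x/nx + s2y/ny) with
    Welch-Satterthwaite degrees of freedom.  When both groups have zero
    variance and equal means the test is degenerate; by convention
    t = 0, p = 1 (flagged via a warning).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("Welch test needs >= 2 observations per group")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            log.warning("degenerate Welch test: zero variance, equal means")
            return 0.0, float(x.size + y.size - 2), 1.0
        return float("inf") if x.mean() > y.mean() else float("-inf"), float(x.size + y.size - 2), 0.0
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


# ---------------------------------------------------------------------------
# Storey q-values

_PI0_GRID = np.arange(0.05, 0.951, 0.05)


def _estimate_pi0(p: np.ndarray) -> float:
    """Storey's smoother estimate of the null proportion pi0.

    pi0(l) = #{p > l} / (m (1 - l)) on the grid l = 0.05..0.95; a cubic
    least-squares smoother in l is evaluated at the grid maximum, and the
    result is clamped into (0, 1].
    """
    m = p.size
    pi0_l = np.array([(p > l).sum() / (m * (1.0 - l)) for l in _PI0_GRID])
    coef = np.polynomial.polynomial.polyfit(_PI0_GRID, pi0_l, deg=3)
    pi0 = float(np.polynomial.polynomial.polyval(_PI0_GRID[-1], coef))
    return min(max(pi0, 1.0 / m), 1.0)


def storey_qvalues(p_values: Sequence[float], pi0: Optional[float] = None) -> np.ndarray:
    """Storey FDR q-values for a family of p-values.

    With ``pi0`` forced to 1 this reduces exactly to Benjamini-Hochberg
    adjusted p-values.  Fewer than 10 p-values cannot support a pi0
    estimate, so pi0 falls back to 1 with a warning.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if pi0 is None:
        if m < 10:
            log.warning("only %d p-values: falling back to pi0 = 1 (BH)", m)
            pi0 = 1.0
        else:
            pi0 = _estimate_pi0(p)
    if not 0 < pi0 <= 1:
        raise ValueError(f"pi0 must be in (0, 1], got {pi0}")
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.clip(q, 0.0, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


# ---------------------------------------------------------------------------
# Study-level driver


def run_de(study: ExpressionStudy, pi0: Optional[float] = None) -> list[DERecord]:
    """Per-feature Box-Cox + Welch + Storey q over one expression family.

    Lambda is estimated per feature on all samples pooled; both groups
    are transformed with that single lambda before the Welch test.
    Features containing non-positive values are shifted by ``1 - min``
    first and flagged.  Records are returned sorted by q ascending
    (stable in the input order for ties).
    """
    mask = study.group_mask
    records: list[DERecord] = []
    for i, fid in enumerate(study.feature_ids):
        row = study.values[i]
        shifted = False
        if row.min() <= 0:
            row = row + (1.0 - row.min())
            shifted = True
        lam = estimate_boxcox_lambda(row, feature_id=fid) if np.ptp(row) > 0 else float("nan")
        y = boxcox_transform(row, lam)
        t, df, pval = welch_test(y[mask], y[~mask])
        mu_t, mu_n = float(y[mask].mean()), float(y[~mask].mean())
        records.append(
            DERecord(
                feature_id=fid, lam=lam, mean_tumor=mu_t, mean_normal=mu_n,
                t_stat=t, df=df, p_value=pval,
                direction="up" if mu_t > mu_n else "down", shifted=shifted,
            )
        )
    q = storey_qvalues([r.p_value for r in records], pi0=pi0)
    records = [replace(r, q_value=float(qv)) for r, qv in zip(records, q)]
    order = np.argsort([r.q_value for r in records], kind="stable")
    return [records[i] for i in order]


def de_table(records: Sequence[DERecord]) -> pd.DataFrame:
    """DE results as a tidy table (one row per feature)."""
    return pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in records],
            "lambda": [r.lam for r in records],
            "mean_tumor": [r.mean_tumor for r in records],
            "mean_normal": [r.mean_normal for r in records],
            "direction": [r.direction for r in records],
            "t": [r.t_stat for r in records],
            "df": [r.df for r in records],
            "p": [r.p_value for r in records],
            "q": [r.q_value for r in records],
        }
    )
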