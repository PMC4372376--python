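"""Flow-cytometry gating, FSC back-gating, and contingency comparison.

Quadrant cuts are set from an unstained control (percentile rule), the
annexin+/PI- quadrant is split on log-FSC into a smaller (R1) and a larger
(R2) sub-population by a deterministic two-component mixture fit, gated
counts are mapped onto the morphology size classes (plain or adjusted for
oncosis), and two 3-class count vectors are compared with an uncorrected
Pearson chi-squared test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skimage.filters import threshold_otsu

__all__ = [
    "GateConfig",
    "QuadrantCounts",
    "BackgateResult",
    "SizeClassCounts",
    "ContingencyResult",
    "fit_quadrant_gates",
    "quadrant_counts",
    "backgate_fsc_split",
    "bimodality_test",
    "map_to_size_classes",
    "chi2_compare",
]


@dataclass(frozen=True)
class GateConfig:
    annexin_cut: float  # FL1, a.u.
    pi_cut: float  # FL3, a.u.
    percentile_used: float

    def __post_init__(self) -> None:
        if self.annexin_cut <= 0 or self.pi_cut <= 0:
            raise ValueError("gate cuts must be > 0")


@dataclass(frozen=True)
class QuadrantCounts:
    q1: int  # annexin- / PI+
    q2: int  # annexin+ / PI+
    q3: int  # annexin- / PI-
    q4: int  # annexin+ / PI-

    @property
    def total(self) -> int:
        return self.q1 + self.q2 + self.q3 + self.q4


@dataclass(frozen=True)
class BackgateResult:
    r1: int  # Q4, lower FSC (smaller cells)
    r2: int  # Q4, higher FSC (larger cells)
    fsc_split: float  # a.u.
    low_confidence: bool = False
    method: str = "gmm2"


@dataclass(frozen=True)
class SizeClassCounts:
    no_change: int
    increase: int
    decrease: int
    debris: int  # Q1, excluded from the size classes


@dataclass(frozen=True)
class ContingencyResult:
    table: np.ndarray
    chi2: float
    df: int
    p: float


def fit_quadrant_gates(unstained: pd.DataFrame, percentile: float = 99.5) -> GateConfig:
    """Set the annexin (FL1) and PI (FL3) cuts from an unstained control."""
    if len(unstained) < 100:
        raise ValueError(f"need >= 100 control events, got {len(unstained)}")
    return GateConfig(
        annexin_cut=float(np.percentile(unstained["FL1"], percentile)),
        pi_cut=float(np.percentile(unstained["FL3"], percentile)),
        percentile_used=float(percentile),
    )


def quadrant_counts(events: pd.DataFrame, gates: GateConfig) -> QuadrantCounts:
    """Partition events into Q1-Q4; values on a cut count as positive."""
    ann = np.asarray(events["FL1"]) >= gates.annexin_cut
    pi = np.asarray(events["FL3"]) >= gates.pi_cut
    return QuadrantCounts(
        q1=int((~ann & pi).sum()),
        q2=int((ann & pi).sum()),
        q3=int((~ann & ~pi).sum()),
        q4=int((ann & ~pi).sum()),
    )


# ---------------------------------------------------------------------------
# 1D two-component Gaussian mixture, deterministic initialisation


def _em_gmm2(x: np.ndarray, max_iter: int = 200, tol: float = 1e-8):
    """Equal-weight init at the 25th/75th percentiles; returns
    (weights, means, sds, loglik) or None when the fit degenerates."""
    mu = np.array([np.percentile(x, 25), np.percentile(x, 75)], dtype=float)
    sd = np.array([x.std(ddof=0), x.std(ddof=0)], dtype=float)
    w = np.array([0.5, 0.5])
    if sd[0] < 1e-12 or mu[0] == mu[1]:
        return None
    ll_old = -np.inf
    for _ in range(max_iter):
        comp = w[None, :] * stats.norm.pdf(x[:, None], mu[None, :], sd[None, :])
        tot = comp.sum(axis=1)
        if np.any(tot <= 0):
            return None
        ll = float(np.log(tot).sum())
        resp = comp / tot[:, None]
        nk = resp.sum(axis=0)
        if np.any(nk < 1e-6):
            return None
        w = nk / len(x)
        mu = (resp * x[:, None]).sum(axis=0) / nk
        sd = np.sqrt((resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk)
        if np.any(sd < 1e-9):
            return None
        if abs(ll - ll_old) < tol:
            break
        ll_old = ll
    if abs(mu[1] - mu[0]) < 1e-9:
        return None
    return w, mu, sd, ll


def _equal_posterior_boundary(w, mu, sd) -> float | None:
    """Point between the sorted means where the two posteriors are equal."""
    order = np.argsort(mu)
    w, mu, sd = w[order], mu[order], sd[order]
    a = 1.0 / (2 * sd[1] ** 2) - 1.0 / (2 * sd[0] ** 2)
    b = mu[0] / sd[0] ** 2 - mu[1] / sd[1] ** 2
    c = (
        mu[1] ** 2 / (2 * sd[1] ** 2)
        - mu[0] ** 2 / (2 * sd[0] ** 2)
        + np.log((w[0] * sd[1]) / (w[1] * sd[0]))
    )
    if abs(a) < 1e-12:
        if abs(b) < 1e-12:
            return None
        root = -c / b
        return float(root) if mu[0] <= root <= mu[1] else None
    disc = b * b - 4 * a * c
    if disc < 0:
        return None
    roots = (-b + np.array([-1.0, 1.0]) * np.sqrt(disc)) / (2 * a)
    inside = [r for r in roots if mu[0] <= r <= mu[1]]
    return float(inside[0]) if inside else None


def bimodality_test(
    x: np.ndarray, n_boot: int = 100, seed: int = 0
) -> tuple[float, float]:
    """Parametric-bootstrap mixture test of unimodality.

    Statistic: log-likelihood ratio of a two-component versus a single
    Gaussian fit. The null distribution is simulated from the fitted single
    Gaussian. Returns ``(lrt, p_value)``; small p means bimodal.
    """
    x = np.asarray(x, dtype=float)
    rng = np.random.default_rng(seed)

    def lrt_of(sample: np.ndarray) -> float:
        mu0, sd0 = sample.mean(), sample.std(ddof=0)
        if sd0 < 1e-12:
            return 0.0
        ll1 = float(stats.norm.logpdf(sample, mu0, sd0).sum())
        fit = _em_gmm2(sample)
        if fit is None:
            return 0.0
        return max(0.0, 2.0 * (fit[3] - ll1))

    obs = lrt_of(x)
    mu0, sd0 = x.mean(), x.std(ddof=0)
    null = np.array(
        [lrt_of(rng.normal(mu0, sd0, size=len(x))) for _ in range(n_boot)]
    )
    p = float((1 + (null >= obs).sum()) / (1 + n_boot))
    return obs, p


def backgate_fsc_split(
    q4_events: pd.DataFrame,
    method: str = "gmm2",
    n_boot: int = 50,
    seed: int = 0,
) -> BackgateResult:
    """Split the annexin+/PI- population on log-FSC into R1 (small) / R2 (large).

    The default is a deterministic two-component mixture with the boundary
    at the equal-posterior point; a histogram-valley (Otsu) split is the
    fallback when the mixture fit degenerates. A non-significant bimodality
    test flags the result low-confidence.
    """
    if len(q4_events) < 20:
        raise ValueError(f"need >= 20 Q4 events to back-gate, got {len(q4_events)}")
    if method not in ("gmm2", "otsu"):
        raise ValueError(f"unknown back-gating method {method!r}")
    logfsc = np.log(np.asarray(q4_events["FSC"], dtype=float))

    split = None
    used = method
    if method == "gmm2":
        fit = _em_gmm2(logfsc)
        if fit is not None:
            split = _equal_posterior_boundary(fit[0], fit[1], fit[2])
        if split is None:
            used = "otsu"
    if split is None:
        if np.ptp(logfsc) < 1e-12:
            # all events identical: degenerate, split at the common value
            split = float(logfsc[0])
            low_conf = True
            warnings.warn("degenerate FSC distribution; back-gate split is arbitrary", stacklevel=2)
            r1 = int((logfsc < split).sum())
            return BackgateResult(r1, len(logfsc) - r1, float(np.exp(split)), low_conf, "degenerate")
        split = float(threshold_otsu(logfsc, nbins=256))

    _, p = bimodality_test(logfsc, n_boot=n_boot, seed=seed)
    low_conf = p > 0.05
    if low_conf:
        warnings.warn(
            f"Q4 FSC distribution not significantly bimodal (p={p:.3f}); "
            "back-gate split flagged low-confidence",
            stacklevel=2,
        )
    r1 = int((logfsc < split).sum())
    return BackgateResult(
        r1=r1,
        r2=len(logfsc) - r1,
        fsc_split=float(np.exp(split)),
        low_confidence=low_conf,
        method=used,
    )


def map_to_size_classes(
    q: QuadrantCounts,
    b: BackgateResult | None = None,
    adjusted: bool = False,
) -> SizeClassCounts:
    """Map gated counts onto the (no_change, increase, decrease) classes.

    Plain: double-negative -> no_change, double-positive -> increase,
    annexin+/PI- -> decrease. Adjusted for oncosis: the larger-FSC part of
    Q4 (R2) moves from decrease to increase. Q1 (debris) is excluded and
    reported separately.
    """
    if not adjusted:
        return SizeClassCounts(no_change=q.q3, increase=q.q2, decrease=q.q4, debris=q.q1)
    if b is None:
        raise ValueError("adjusted mapping requires a back-gate result")
    if b.r1 + b.r2 != q.q4:
        raise ValueError("back-gate counts do not partition Q4")
    return SizeClassCounts(no_change=q.q3, increase=q.q2 + b.r2, decrease=b.r1, debris=q.q1)


def chi2_compare(row_a, row_b) -> ContingencyResult:
    """Pearson chi-squared on a 2xK contingency table, no continuity correction."""
    table = np.array([row_a, row_b], dtype=float)
    if np.any(table < 0):
        raise ValueError("counts must be >= 0")
    col_tot = table.sum(axis=0)
    if np.any(col_tot == 0):
        raise ValueError("every column total must be > 0")
    row_tot = table.sum(axis=1, keepdims=True)
    expected = row_tot * col_tot[None, :] / table.sum()
    chi2 = float(((table - expected) ** 2 / expected).sum())
    df = (table.shape[0] - 1) * (table.shape[1] - 1)
    return ContingencyResult(table=table, chi2=chi2, df=df, p=float(stats.chi2.sf(chi2, df)))
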