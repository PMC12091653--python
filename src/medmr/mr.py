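"""Two-sample MR estimators on harmonized summary statistics.

Implements the Wald ratio, inverse-variance weighted (fixed and
multiplicative-random-effects) meta-analysis, MR-Egger regression, the
weighted median, and a profile maximum-likelihood estimator, together with
Cochran's Q heterogeneity and odds-ratio conversions.

All estimators consume either :class:`~medmr.harmonize.IVSet` objects or
plain arrays of per-variant effects; p-values are two-sided normal except the
Egger slope and intercept, which use a t reference with k-2 degrees of
freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .harmonize import IVSet

logger = logging.getLogger(__name__)

Z95 = 1.959964  # two-sided 95% normal quantile, conventional rounding


class InsufficientInstrumentsError(ValueError):
    """Fewer instruments than the estimator requires."""


class DegenerateInstrumentError(ValueError):
    """An instrument with zero exposure effect cannot form a Wald ratio."""


@dataclass(frozen=True)
class WaldRatio:
    """Per-variant causal estimate beta_out/beta_exp with first-order SE."""

    variant_id: str
    ratio: float
    se_ratio: float

    @property
    def weight(self) -> float:
        return 1.0 / self.se_ratio**2


@dataclass
class MREstimate:
    """A causal estimate from one MR method, with diagnostics.

    ``beta`` is on the outcome scale per SD of exposure (log-OR for binary
    outcomes); ``or_with_ci`` is derived at report time as exp(beta +/- 1.96 se).
    """

    method: str
    beta: float
    se: float
    pval: float
    n_snp: int
    q: float | None = None
    q_pval: float | None = None
    egger_intercept: float | None = None
    intercept_se: float | None = None
    intercept_pval: float | None = None
    exposure_id: str | None = None
    outcome_id: str | None = None

    @property
    def or_with_ci(self) -> tuple[float, float, float]:
        return (
            float(np.exp(self.beta)),
            float(np.exp(self.beta - Z95 * self.se)),
            float(np.exp(self.beta + Z95 * self.se)),
        )

    def to_row(self) -> dict:
        or_, lo, hi = self.or_with_ci
        return {
            "exposure": self.exposure_id,
            "outcome": self.outcome_id,
            "method": self.method,
            "n_snp": self.n_snp,
            "beta": self.beta,
            "se": self.se,
            "pval": self.pval,
            "or": or_,
            "or_lo95": lo,
            "or_hi95": hi,
            "q": self.q,
            "q_pval": self.q_pval,
            "egger_intercept": self.egger_intercept,
            "egger_intercept_se": self.intercept_se,
            "egger_intercept_pval": self.intercept_pval,
        }


def _pairs(ivset: IVSet | Sequence) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, list[str]]:
    if isinstance(ivset, IVSet):
        hp = ivset.harmonized
        bx = np.array([p.beta_exp for p in hp])
        sx = np.array([p.se_exp for p in hp])
        by = np.array([p.beta_out for p in hp])
        sy = np.array([p.se_out for p in hp])
        ids = [p.variant_id for p in hp]
        return bx, sx, by, sy, ids
    raise TypeError("expected an IVSet")


# ---------------------------------------------------------------------------
# Wald ratios and IVW


def wald_ratios(ivset: IVSet) -> list[WaldRatio]:
    """One Wald ratio per instrument with first-order (se_out/|beta_exp|) SE."""
    if isinstance(ivset, IVSet) and ivset.is_empty:
        raise InsufficientInstrumentsError("empty instrument set")
    bx, _, by, sy, ids = _pairs(ivset)
    zero = np.flatnonzero(bx == 0)
    if zero.size:
        raise DegenerateInstrumentError(f"beta_exp = 0 for variant {ids[zero[0]]!r}")
    return [
        WaldRatio(vid, float(b / a), float(s / abs(a)))
        for vid, a, b, s in zip(ids, bx, by, sy)
    ]


def cochran_q(ratios: Sequence[WaldRatio], beta: float) -> tuple[float, float | None]:
    """Weighted heterogeneity statistic around ``beta`` and its chi2 p (k-1 df)."""
    r = np.array([w.ratio for w in ratios])
    w = np.array([w.weight for w in ratios])
    q = float(np.sum(w * (r - beta) ** 2))
    k = len(ratios)
    q_pval = float(stats.chi2.sf(q, k - 1)) if k >= 2 else None
    return q, q_pval


def ivw(
    ratios: Sequence[WaldRatio] | IVSet,
    mode: str = "multiplicative_random",
) -> MREstimate:
    """Inverse-variance-weighted meta-analysis of Wald ratios.

    Fixed-effect SE is 1/sqrt(sum of weights); the multiplicative
    random-effects mode inflates it by max(1, sqrt(Q/(k-1))), the standard
    overdispersion correction when Cochran's Q exceeds its degrees of freedom.
    """
    if isinstance(ratios, IVSet):
        ratios = wald_ratios(ratios)
    if mode not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown IVW mode {mode!r}")
    if len(ratios) == 0:
        raise InsufficientInstrumentsError("IVW requires at least one Wald ratio")
    r = np.array([x.ratio for x in ratios])
    w = np.array([x.weight for x in ratios])
    beta = float(np.sum(w * r) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    q, q_pval = cochran_q(ratios, beta)
    k = len(ratios)
    if mode == "multiplicative_random" and k >= 2:
        se *= max(1.0, float(np.sqrt(q / (k - 1))))
    pval = float(2 * stats.norm.sf(abs(beta / se)))
    return MREstimate(
        method="ivw_fixed" if mode == "fixed" else "ivw_mre",
        beta=beta, se=se, pval=pval, n_snp=k, q=q, q_pval=q_pval,
    )


# ---------------------------------------------------------------------------
# MR-Egger


def mr_egger(ivset: IVSet) -> MREstimate:
    """Weighted regression of outcome on exposure effects with a free intercept.

    Exposure effects are oriented non-negative first (required for the
    intercept to measure directional pleiotropy); weights are 1/se_out^2 and
    both SEs carry the multiplicative scaling max(1, sqrt(RSS_w/(k-2))).
    Slope and intercept p-values use a t reference with k-2 df.
    """
    bx, _, by, sy, _ = _pairs(ivset)
    k = len(bx)
    if k < 3:
        raise InsufficientInstrumentsError(f"MR-Egger requires >= 3 instruments, got {k}")
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    w = 1.0 / sy**2
    X = np.column_stack([np.ones(k), bx])
    WX = X * w[:, None]
    xtwx = X.T @ WX
    coef = np.linalg.solve(xtwx, WX.T @ by)
    resid = by - X @ coef
    rss_w = float(np.sum(w * resid**2))
    scale = max(1.0, np.sqrt(rss_w / (k - 2)))
    cov = np.linalg.inv(xtwx) * scale**2
    inter, slope = float(coef[0]), float(coef[1])
    se_inter, se_slope = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    t = stats.t(df=k - 2)
    q, q_pval = None, None
    try:
        wr = wald_ratios(ivset)
        est = ivw(wr, mode="fixed")
        q, q_pval = est.q, est.q_pval
    except DegenerateInstrumentError:
        pass
    return MREstimate(
        method="egger",
        beta=slope,
        se=se_slope,
        pval=float(2 * t.sf(abs(slope / se_slope))),
        n_snp=k,
        q=q,
        q_pval=q_pval,
        egger_intercept=inter,
        intercept_se=se_inter,
        intercept_pval=float(2 * t.sf(abs(inter / se_inter))),
    )


# ---------------------------------------------------------------------------
# weighted median


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Value at the 0.5 crossing of the cumulative normalized weights.

    The crossing estimator returns the value whose weight mass contains the
    0.5 point, so any value carrying a strict majority of the weight is
    returned exactly; an exact boundary hit averages the two neighbours.
    """
    order = np.argsort(values, kind="stable")
    v = values[order]
    cum = np.cumsum(weights[order]) / np.sum(weights)
    i = int(np.searchsorted(cum, 0.5, side="left"))
    if np.isclose(cum[i], 0.5, rtol=0, atol=1e-12) and i + 1 < len(v):
        return float(0.5 * (v[i] + v[i + 1]))
    return float(v[i])


def weighted_median(
    ratios: Sequence[WaldRatio] | IVSet,
    n_boot: int = 1000,
    seed: int = 20_240_501,
) -> MREstimate:
    """Weighted-median causal estimate with parametric-bootstrap SE.

    Robust when instruments carrying at most half of the total weight are
    invalid. The SE is the standard deviation of the estimate across
    ``n_boot`` replicates in which each ratio is resampled from
    Normal(ratio_i, se_ratio_i); the seed is fixed and recorded.
    """
    if isinstance(ratios, IVSet):
        ratios = wald_ratios(ratios)
    if len(ratios) < 3:
        raise InsufficientInstrumentsError(
            f"weighted median requires >= 3 ratios, got {len(ratios)}"
        )
    if n_boot < 100:
        logger.warning("weighted_median: n_boot=%d < 100 gives an unstable SE", n_boot)
    r = np.array([x.ratio for x in ratios])
    s = np.array([x.se_ratio for x in ratios])
    w = np.array([x.weight for x in ratios])
    est = _weighted_median(r, w)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        boots[b] = _weighted_median(rng.normal(r, s), w)
    se = float(np.std(boots, ddof=1))
    pval = float(2 * stats.norm.sf(abs(est / se))) if se > 0 else (1.0 if est == 0 else 0.0)
    return MREstimate(method="weighted_median", beta=est, se=se, pval=pval, n_snp=len(ratios))


# ---------------------------------------------------------------------------
# maximum likelihood


def _ml_negloglik(theta: float, bx, sx, by, sy) -> float:
    # profile likelihood: per-SNP true effects xi_i maximized out analytically;
    # normalization constants do not involve theta, so only the quadratic survives
    return float(0.5 * np.sum((by - theta * bx) ** 2 / (sy**2 + theta**2 * sx**2)))


def max_likelihood(ivset: IVSet, tol: float = 1e-10, max_iter: int = 200) -> MREstimate:
    """Profile maximum-likelihood causal estimate.

    Observed (beta_exp_i, beta_out_i) are modelled as independent normals
    around (xi_i, theta*xi_i) with the reported SEs; the nuisance xi_i are
    profiled out analytically, leaving a one-dimensional optimization in
    theta. The SE comes from the curvature (observed information) of the
    profile log-likelihood at the optimum.
    """
    bx, sx, by, sy, _ = _pairs(ivset)
    if len(bx) < 2:
        raise InsufficientInstrumentsError("maximum likelihood requires >= 2 instruments")
    theta0 = float(np.sum(bx * by / sy**2) / np.sum(bx**2 / sy**2))
    span = 10 * (abs(theta0) + 1.0)
    res = optimize.minimize_scalar(
        _ml_negloglik,
        args=(bx, sx, by, sy),
        bounds=(theta0 - span, theta0 + span),
        method="bounded",
        options={"xatol": tol, "maxiter": max_iter},
    )
    if not res.success:
        raise RuntimeError(f"maximum-likelihood optimization failed: {res.message}")
    theta = float(res.x)
    h = max(1e-6, 1e-6 * abs(theta))
    info = (
        _ml_negloglik(theta + h, bx, sx, by, sy)
        - 2 * _ml_negloglik(theta, bx, sx, by, sy)
        + _ml_negloglik(theta - h, bx, sx, by, sy)
    ) / h**2
    se = float(1.0 / np.sqrt(info)) if info > 0 else float("nan")
    pval = float(2 * stats.norm.sf(abs(theta / se))) if np.isfinite(se) and se > 0 else float("nan")
    return MREstimate(method="max_likelihood", beta=theta, se=se, pval=pval, n_snp=len(bx))


# ---------------------------------------------------------------------------
# OR <-> beta conversions


def or_to_beta(or_value: float) -> float:
    """Natural log of an odds ratio."""
    if or_value <= 0:
        raise ValueError(f"odds ratio must be positive, got {or_value}")
    return float(np.log(or_value))


def beta_to_or(beta: float) -> float:
    return float(np.exp(beta))


def ci_to_se(lower: float, upper: float) -> float:
    """SE implied by a 95% CI on the OR scale: (ln upper - ln lower)/(2*1.959964)."""
    if not (0 < lower < upper):
        raise ValueError(f"need upper > lower > 0, got ({lower}, {upper})")
    return float((np.log(upper) - np.log(lower)) / (2 * Z95))


ALL_METHODS = ("ivw_mre", "ivw_fixed", "egger", "weighted_median", "max_likelihood")


def run_all_methods(ivset: IVSet, wm_seed: int = 20_240_501) -> list[MREstimate]:
    """IVW (both modes) plus the three sensitivity estimators, where estimable."""
    out: list[MREstimate] = []
    ratios = wald_ratios(ivset)
    out.append(ivw(ratios, mode="multiplicative_random"))
    out.append(ivw(ratios, mode="fixed"))
    for fn in (mr_egger, lambda s: weighted_median(ratios, seed=wm_seed), max_likelihood):
        try:
            out.append(fn(ivset))
        except InsufficientInstrumentsError:
            pass
    for e in out:
        e.exposure_id = ivset.exposure_id
    return out
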