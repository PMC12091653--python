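"""Summary-data-based MR (SMR) with the HEIDI linkage test.

SMR tests whether a protein's plasma level and disease risk share a genetic
signal at the protein's top cis-pQTL; HEIDI (heterogeneity in dependent
instruments) asks whether the surrounding cis region is consistent with one
shared causal variant (heterogeneity absent) or with linkage of distinct
variants (heterogeneity present). Protein-level scans control the false
discovery rate with Benjamini-Hochberg.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .gwas_io import LDMatrix, SummaryRecord, SummaryTable

logger = logging.getLogger(__name__)


class NoInstrumentError(ValueError):
    """No cis variant passes the instrument threshold for this protein."""


@dataclass
class HeidiParams:
    """SNP-eligibility rules for HEIDI, following the original methodology.

    SNPs enter the test when their pQTL p-value is below ``p_include`` and
    their LD with the top SNP satisfies ``r2_min < r^2 < r2_max`` (too low
    carries no information about the same signal, too high is numerically
    unstable); at most ``max_snps`` by descending |z_qtl|, at least
    ``min_snps`` or the test is undefined.
    """

    p_include: float = 1.57e-3
    r2_min: float = 0.05
    r2_max: float = 0.9
    max_snps: int = 20
    min_snps: int = 3


@dataclass
class SMRResult:
    protein_id: str
    top_snp: str
    b_xy: float
    se_xy: float
    p_smr: float
    p_heidi: float | None = None
    n_heidi_snps: int = 0
    heidi_reason: str | None = None
    p_smr_fdr: float | None = None
    passes: bool = False

    def to_row(self) -> dict:
        return {
            "protein_id": self.protein_id,
            "top_snp": self.top_snp,
            "b_xy": self.b_xy,
            "se_xy": self.se_xy,
            "p_smr": self.p_smr,
            "p_heidi": self.p_heidi,
            "n_heidi_snps": self.n_heidi_snps,
            "p_smr_fdr": self.p_smr_fdr,
            "passes": self.passes,
        }


def top_cis_qtl(
    pqtl: SummaryTable,
    gene_pos: tuple[str, int],
    window_kb: float = 1000.0,
    p_max: float = 5e-8,
) -> SummaryRecord:
    """Smallest-p variant within +/- ``window_kb`` of the gene (inclusive).

    Ties in p-value are broken by smaller position then id.
    """
    chrom, pos = gene_pos
    window_bp = window_kb * 1000.0
    eligible = [
        r for r in pqtl
        if r.chrom == str(chrom) and abs(r.pos - pos) <= window_bp and r.pval <= p_max
    ]
    if not eligible:
        raise NoInstrumentError(
            f"{pqtl.trait_id}: no cis variant at p <= {p_max:g} within "
            f"{window_kb:g} kb of {chrom}:{pos}"
        )
    return min(eligible, key=lambda r: (r.pval, r.pos, r.variant_id))


def smr_test(
    z_qtl: float, z_gwas: float, beta_qtl: float, beta_gwas: float
) -> tuple[float, float, float]:
    """SMR chi-square test at a single SNP.

    Returns (b_xy, se_xy, p_smr) where b_xy = beta_gwas/beta_qtl,
    T_SMR = z_gwas^2 z_qtl^2 / (z_gwas^2 + z_qtl^2) ~ chi2(1) under the null,
    and se_xy = |b_xy| sqrt(1/z_gwas^2 + 1/z_qtl^2).
    """
    if z_qtl == 0:
        raise ValueError("z_qtl must be nonzero")
    b_xy = beta_gwas / beta_qtl
    if z_gwas == 0:
        return float(b_xy), float("inf"), 1.0
    t_smr = (z_gwas**2 * z_qtl**2) / (z_gwas**2 + z_qtl**2)
    p_smr = float(stats.chi2.sf(t_smr, df=1))
    se_xy = abs(b_xy) * np.sqrt(1.0 / z_gwas**2 + 1.0 / z_qtl**2)
    return float(b_xy), float(se_xy), p_smr


def _bxy_covariance(
    bq: np.ndarray, sq: np.ndarray, bg: np.ndarray, sg: np.ndarray, r: np.ndarray
) -> np.ndarray:
    """First-order covariance of the per-SNP ratio estimates b_xy = bg/bq.

    The pQTL and GWAS cohorts are independent, so covariances come separately
    from each trait's correlated marginal effects (cov ~ r_ij * se_i * se_j).
    """
    # d b_xy/d bg = 1/bq ; d b_xy/d bq = -bg/bq^2
    gq = 1.0 / bq
    gb = -bg / bq**2
    return (
        np.outer(gq, gq) * r * np.outer(sg, sg)
        + np.outer(gb, gb) * r * np.outer(sq, sq)
    )


def heidi_test(
    pqtl: SummaryTable,
    gwas: SummaryTable,
    top: str,
    ld: LDMatrix,
    params: HeidiParams | None = None,
) -> tuple[float | None, int, str | None]:
    """HEIDI: do neighbouring SNPs give the same ratio estimate as the top SNP?

    Computes d_i = b_xy(i) - b_xy(top) for eligible cis SNPs, propagates the
    LD-induced covariance of the d vector to first order, and refers
    T = sum(d_i^2/var(d_i)) to a Satterthwaite scaled chi-square matched to
    the mean and variance of the correlated quadratic form. Returns
    (p_heidi, n_snps, reason); p_heidi is None with a reason when fewer than
    ``min_snps`` SNPs are eligible. Small p indicates heterogeneity, i.e.
    linkage of distinct causal variants rather than one shared one.
    """
    params = params or HeidiParams()
    top_q = pqtl.get(top)
    top_g = gwas.get(top)
    if top_q is None or top_g is None:
        raise KeyError(f"top SNP {top!r} missing from pQTL or GWAS table")
    cands = []
    for rec in pqtl:
        if rec.variant_id == top:
            continue
        if rec.pval >= params.p_include:
            continue
        g = gwas.get(rec.variant_id)
        if g is None:
            continue
        try:
            r2 = ld.r2_between(top, rec.variant_id)
        except KeyError:
            continue
        if not (params.r2_min < r2 < params.r2_max):
            continue
        cands.append((rec, g))
    cands.sort(key=lambda pair: -abs(pair[0].zscore()))
    cands = cands[: params.max_snps]
    if len(cands) < params.min_snps:
        reason = f"only {len(cands)} eligible SNPs (< {params.min_snps})"
        return None, len(cands), reason
    snps = [top] + [rec.variant_id for rec, _ in cands]
    bq = np.array([top_q.beta] + [rec.beta for rec, _ in cands])
    sq = np.array([top_q.se] + [rec.se for rec, _ in cands])
    bg = np.array([top_g.beta] + [g.beta for _, g in cands])
    sg = np.array([top_g.se] + [g.se for _, g in cands])
    r = ld.subset(snps).r
    bxy = bg / bq
    cov = _bxy_covariance(bq, sq, bg, sg, r)
    m = len(cands)
    # d_i = bxy_i - bxy_top: contrast matrix [-1 | I]
    d = bxy[1:] - bxy[0]
    cov_d = (
        cov[1:, 1:]
        - cov[1:, [0]]
        - cov[[0], 1:]
        + cov[0, 0]
    )
    var_d = np.diag(cov_d)
    if np.any(var_d <= 0):
        return None, m, "non-positive propagated variance"
    z_d = d / np.sqrt(var_d)
    t_heidi = float(np.sum(z_d**2))
    # correlation of the standardized deviations
    corr_d = cov_d / np.sqrt(np.outer(var_d, var_d))
    mean_t = float(m)
    var_t = float(2.0 * np.sum(corr_d**2))
    # Satterthwaite: T ~ a * chi2(nu) with a = var/(2 mean), nu = 2 mean^2/var
    a = var_t / (2.0 * mean_t)
    nu = 2.0 * mean_t**2 / var_t
    p_heidi = float(stats.chi2.sf(t_heidi / a, df=nu))
    return p_heidi, m, None


def bh_fdr(pvals: Sequence[float], alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted p-values and significance flags."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("bh_fdr requires a non-empty p-value list")
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest rank down
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj, adj < alpha


def smr_scan(
    proteins: Sequence[tuple[SummaryTable, tuple[str, int]]],
    gwas: SummaryTable,
    ld: LDMatrix,
    window_kb: float = 1000.0,
    p_max: float = 5e-8,
    heidi_params: HeidiParams | None = None,
    fdr_alpha: float = 0.05,
    heidi_alpha: float = 0.01,
) -> list[SMRResult]:
    """SMR + HEIDI across proteins with BH-FDR on the SMR p-values.

    A protein passes when its BH-adjusted SMR p is below ``fdr_alpha`` and
    HEIDI does not reject a single shared causal variant
    (p_heidi >= ``heidi_alpha``). Proteins with no valid cis instrument are
    skipped with a logged reason.
    """
    results: list[SMRResult] = []
    for pqtl, gene_pos in proteins:
        try:
            top = top_cis_qtl(pqtl, gene_pos, window_kb=window_kb, p_max=p_max)
        except NoInstrumentError as exc:
            logger.info("smr_scan: %s", exc)
            continue
        g = gwas.get(top.variant_id)
        if g is None:
            logger.info("smr_scan: %s top SNP %s absent from GWAS", pqtl.trait_id, top.variant_id)
            continue
        b_xy, se_xy, p_smr = smr_test(top.zscore(), g.zscore(), top.beta, g.beta)
        p_heidi, n_heidi, reason = heidi_test(pqtl, gwas, top.variant_id, ld, heidi_params)
        results.append(SMRResult(
            protein_id=pqtl.trait_id, top_snp=top.variant_id,
            b_xy=b_xy, se_xy=se_xy, p_smr=p_smr,
            p_heidi=p_heidi, n_heidi_snps=n_heidi, heidi_reason=reason,
        ))
    if results:
        adj, sig = bh_fdr([r.p_smr for r in results], alpha=fdr_alpha)
        for res, a, s in zip(results, adj, sig):
            res.p_smr_fdr = float(a)
            res.passes = bool(s) and (res.p_heidi is None or res.p_heidi >= heidi_alpha)
    return results
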