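"""Synthetic GWAS cohorts for a lipid -> protein -> disease causal chain.

Generates a reference genotype panel with block LD structure, individual-level
traits following a configurable mediation chain (quantitative exposure ->
quantitative mediator -> binary outcome), and per-SNP marginal summary
statistics of the same shape real cohorts publish: effect, SE, Wald p, allele
frequency and sample size per variant, with LD-induced correlation between
neighbouring variants' effects and SEs that scale with sample size and
allele frequency.

Two routes to summary statistics exist:

* :func:`summary_stats` runs the per-variant marginal regression (OLS or
  logistic) on simulated individuals - the estimator real cohorts use;
* :func:`sample_summary_stats` draws marginal effects directly from their
  LD-implied multivariate normal sampling distribution - statistically
  equivalent at large n and orders of magnitude faster, used for
  replicate-heavy calibration suites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats

from .gwas_io import LDMatrix, ReferencePanel, SummaryRecord, SummaryTable, compute_ld

logger = logging.getLogger(__name__)

_BASES = ("A", "C", "G", "T")


@dataclass
class SimulationScenario:
    """Everything needed to reproduce one synthetic study.

    ``rho`` is the target Pearson correlation between *dosages* within an LD
    block (the latent haplotype correlation is calibrated upward to hit it).
    Chain coefficients: ``a`` exposure->mediator (SD per SD), ``b``
    mediator->outcome (log-OR per SD), ``c_prime`` direct exposure->outcome
    (log-OR per SD). Per-allele genetic effects attach to
    ``exposure_causal``/``mediator_causal``/``outcome_causal`` variant
    indices; outcome effects are log-ORs, letting linkage scenarios give the
    disease its own causal variants.
    """

    name: str = "custom"
    n_individuals: int = 20_000
    n_variants: int = 500
    maf_range: tuple[float, float] = (0.1, 0.5)
    ld_block_size: int = 10
    rho: float = 0.6
    a: float = 0.0
    b: float = 0.0
    c_prime: float = 0.0
    exposure_causal: tuple[int, ...] = ()
    exposure_effects: tuple[float, ...] = ()
    mediator_causal: tuple[int, ...] = ()
    mediator_effects: tuple[float, ...] = ()
    outcome_causal: tuple[int, ...] = ()
    outcome_effects: tuple[float, ...] = ()
    prevalence: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not (-1 < self.rho < 1):
            raise ValueError("|rho| must be < 1 (rho = 1 is a degenerate block)")
        if not (0 < self.prevalence < 1):
            raise ValueError("prevalence must lie in (0, 1)")
        for idx in (*self.exposure_causal, *self.mediator_causal, *self.outcome_causal):
            if not (0 <= idx < self.n_variants):
                raise ValueError(f"causal index {idx} outside [0, {self.n_variants})")
        if len(self.exposure_causal) != len(self.exposure_effects):
            raise ValueError("exposure_causal and exposure_effects lengths differ")
        if len(self.mediator_causal) != len(self.mediator_effects):
            raise ValueError("mediator_causal and mediator_effects lengths differ")
        if len(self.outcome_causal) != len(self.outcome_effects):
            raise ValueError("outcome_causal and outcome_effects lengths differ")


@dataclass
class SimulatedStudy:
    """Three independent GWAS cohorts plus an external LD reference panel.

    Each trait's summary table comes from its own cohort, matching the
    two-sample design of real lipid/protein/disease GWAS; ``panel`` is the
    reference used for LD (clumping, HEIDI, colocalization)."""

    panel: ReferencePanel
    truth: SimulationScenario
    tables: dict[str, SummaryTable]
    traits: dict[str, np.ndarray] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# genotypes


def _phi_corr(rho_latent: float, t: float) -> float:
    """Pearson correlation of two threshold-at-t indicators of a latent
    bivariate normal with correlation ``rho_latent`` (tetrachoric forward map)."""
    p = stats.norm.cdf(t)
    p11 = stats.multivariate_normal.cdf(
        [t, t], mean=[0, 0], cov=[[1, rho_latent], [rho_latent, 1]]
    )
    return (p11 - p * p) / (p * (1 - p))


def _latent_rho(target: float, t: float) -> float:
    """Invert the tetrachoric map so the thresholded indicators correlate at
    ``target``. Raises when the target is unattainable at this frequency."""
    if target == 0:
        return 0.0
    sign = np.sign(target)
    tgt = abs(target)
    hi = 0.999
    if _phi_corr(hi, t) < tgt:
        raise ValueError(
            f"within-block dosage correlation {target:g} unattainable at this MAF"
        )
    return sign * float(optimize.brentq(lambda r: _phi_corr(r, t) - tgt, 0.0, hi, xtol=1e-6))


def variant_metadata(scenario: SimulationScenario) -> tuple[list[str], list[str], list[int]]:
    """Deterministic ids, chromosomes and positions: each LD block sits on
    chromosome 1 + block // 25, variants 5 kb apart, blocks 200 kb apart."""
    m = scenario.n_variants
    b = scenario.ld_block_size
    ids, chroms, poss = [], [], []
    for j in range(m):
        blk = j // b
        chrom = str(1 + blk // 25)
        pos = 1_000_000 + (blk % 25) * 200_000 + (j % b) * 5_000
        ids.append(f"rs{j + 1:05d}")
        chroms.append(chrom)
        poss.append(pos)
    return ids, chroms, poss


def simulate_panel(scenario: SimulationScenario, rng: np.random.Generator | None = None) -> ReferencePanel:
    """Dosage panel with exchangeable within-block LD at the target level.

    Each haplotype is a latent multivariate normal per block, thresholded at
    the MAF quantile; dosage is the sum of two independent haplotypes. MAFs
    are drawn per block (shared within a block) so the tetrachoric
    calibration of the latent correlation is exact; heterogeneous frequencies
    bound the attainable correlation and would silently attenuate it.
    """
    rng = rng or np.random.default_rng(scenario.seed)
    n, m, b = scenario.n_individuals, scenario.n_variants, scenario.ld_block_size
    n_blocks = int(np.ceil(m / b))
    # MAFs are population parameters: tied to the scenario seed, not to the
    # cohort rng, so independent cohorts share allele frequencies
    maf_rng = np.random.default_rng(np.random.SeedSequence((scenario.seed, 0xAF)))
    block_mafs = maf_rng.uniform(*scenario.maf_range, size=n_blocks)
    dosages = np.empty((n, m))
    mafs = np.empty(m)
    for blk in range(n_blocks):
        j0, j1 = blk * b, min((blk + 1) * b, m)
        k = j1 - j0
        maf = block_mafs[blk]
        t = stats.norm.ppf(maf)
        rho_lat = _latent_rho(scenario.rho, t) if k > 1 else 0.0
        cov = np.full((k, k), rho_lat)
        np.fill_diagonal(cov, 1.0)
        chol = np.linalg.cholesky(cov)
        block_dos = np.zeros((n, k))
        for _hap in range(2):
            latent = rng.standard_normal((n, k)) @ chol.T
            block_dos += (latent < t).astype(float)
        dosages[:, j0:j1] = block_dos
        mafs[j0:j1] = maf
    ids, chroms, poss = variant_metadata(scenario)
    positions = {v: (c, p) for v, c, p in zip(ids, chroms, poss)}
    return ReferencePanel(ids, dosages, positions)


# ---------------------------------------------------------------------------
# traits


def _genetic_score(panel: ReferencePanel, idx: tuple[int, ...], eff: tuple[float, ...]) -> np.ndarray:
    if not idx:
        return np.zeros(panel.n_individuals)
    g = panel.dosages[:, list(idx)]
    return g @ np.asarray(eff)


def _solve_intercept(linear: np.ndarray, prevalence: float) -> float:
    lo, hi = -30.0, 30.0

    def mean_prev(alpha: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(alpha + linear)))))

    if not (mean_prev(lo) < prevalence < mean_prev(hi)):
        raise ValueError(f"target prevalence {prevalence:g} unattainable")
    return float(optimize.brentq(lambda a: mean_prev(a) - prevalence, lo, hi, xtol=1e-10))


def simulate_chain(
    panel: ReferencePanel,
    scenario: SimulationScenario,
    rng: np.random.Generator | None = None,
) -> dict[str, np.ndarray]:
    """Individual-level exposure, mediator and binary outcome.

    exposure = genetic score + noise (unit variance); mediator = a*exposure +
    genetic score + noise (unit variance); outcome ~ Bernoulli(logistic(alpha
    + b*mediator + c'*exposure + outcome genetic score)) with alpha solved by
    bisection for the target prevalence.
    """
    rng = rng or np.random.default_rng(scenario.seed + 1)
    n = panel.n_individuals
    gx = _genetic_score(panel, scenario.exposure_causal, scenario.exposure_effects)
    var_gx = float(np.var(gx))
    if var_gx >= 0.95:
        raise ValueError("exposure genetic variance >= 0.95; cannot reach unit variance")
    exposure = gx + rng.normal(0.0, np.sqrt(1.0 - var_gx), n)
    gm = _genetic_score(panel, scenario.mediator_causal, scenario.mediator_effects)
    med_sys = scenario.a * exposure + gm
    var_sys = float(np.var(med_sys))
    if var_sys >= 0.95:
        raise ValueError("mediator systematic variance >= 0.95; cannot reach unit variance")
    mediator = med_sys + rng.normal(0.0, np.sqrt(1.0 - var_sys), n)
    go = _genetic_score(panel, scenario.outcome_causal, scenario.outcome_effects)
    linear = scenario.b * mediator + scenario.c_prime * exposure + go
    alpha = _solve_intercept(linear, scenario.prevalence)
    prob = 1.0 / (1.0 + np.exp(-(alpha + linear)))
    outcome = (rng.uniform(size=n) < prob).astype(float)
    return {"exposure": exposure, "mediator": mediator, "outcome": outcome}


# ---------------------------------------------------------------------------
# marginal summary statistics


def _records_from_arrays(
    scenario: SimulationScenario,
    beta: np.ndarray,
    se: np.ndarray,
    eaf: np.ndarray,
    n: float,
    keep: np.ndarray,
) -> list[SummaryRecord]:
    ids, chroms, poss = variant_metadata(scenario)
    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    pval = np.clip(2 * stats.norm.sf(np.abs(z)), 1e-300, 1.0)
    recs = []
    for j in range(len(ids)):
        if not keep[j]:
            continue
        recs.append(SummaryRecord(
            variant_id=ids[j], chrom=chroms[j], pos=poss[j],
            effect_allele=_BASES[j % 4], other_allele=_BASES[(j + 1) % 4],
            eaf=float(eaf[j]), beta=float(beta[j]), se=float(se[j]),
            pval=float(pval[j]), n=float(n),
        ))
    return recs


def _marginal_ols(g: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant simple linear regression, vectorized over variants."""
    n = g.shape[0]
    gc = g - g.mean(axis=0)
    yc = y - y.mean()
    sxx = np.sum(gc**2, axis=0)
    beta = (gc.T @ yc) / sxx
    rss = np.sum(yc**2) - beta**2 * sxx
    se = np.sqrt(rss / (n - 2) / sxx)
    return beta, se


def _marginal_logistic(
    g: np.ndarray, y: np.ndarray, max_iter: int = 25, tol: float = 1e-8
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-variant logistic regression (intercept + dosage), Newton-Raphson
    vectorized across variants. Returns (beta, se, converged_mask); variants
    showing separation (diverging slope) come back unconverged."""
    n, m = g.shape
    b0 = np.full(m, float(np.log(y.mean() / (1 - y.mean()))))
    b1 = np.zeros(m)
    ok = np.ones(m, dtype=bool)
    for _ in range(max_iter):
        eta = b0[None, :] + g * b1[None, :]
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1 - p)
        r = y[:, None] - p
        g0 = r.sum(axis=0)
        g1 = (g * r).sum(axis=0)
        h00 = w.sum(axis=0)
        h01 = (w * g).sum(axis=0)
        h11 = (w * g**2).sum(axis=0)
        det = h00 * h11 - h01**2
        bad = (det <= 1e-12) | ~np.isfinite(det)
        det = np.where(bad, 1.0, det)
        d0 = (h11 * g0 - h01 * g1) / det
        d1 = (h00 * g1 - h01 * g0) / det
        d0[bad] = 0.0
        d1[bad] = 0.0
        ok &= ~bad
        b0 += d0
        b1 += d1
        diverged = np.abs(b1) > 15
        ok &= ~diverged
        if np.max(np.abs(np.concatenate([d0[ok], d1[ok]])) if ok.any() else 0.0) < tol:
            break
    eta = b0[None, :] + g * b1[None, :]
    p = 1.0 / (1.0 + np.exp(-eta))
    w = p * (1 - p)
    h00 = w.sum(axis=0)
    h01 = (w * g).sum(axis=0)
    h11 = (w * g**2).sum(axis=0)
    det = h00 * h11 - h01**2
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(h00 / det)
    ok &= np.isfinite(se) & (se > 0) & np.isfinite(b1)
    return b1, se, ok


def summary_stats(
    traits: np.ndarray,
    panel: ReferencePanel,
    trait_type: str,
    scenario: SimulationScenario,
    trait_id: str,
    chunk: int = 100,
) -> SummaryTable:
    """Marginal per-variant summary statistics by actual regression.

    Quantitative traits use simple OLS per variant; binary traits use
    per-variant logistic regression (Newton), with separated variants dropped
    and logged. ``eaf`` is exactly the column dosage mean / 2.
    """
    y = np.asarray(traits, dtype=float)
    m = len(panel.variant_ids)
    beta = np.empty(m)
    se = np.empty(m)
    keep = np.ones(m, dtype=bool)
    for j0 in range(0, m, chunk):
        j1 = min(j0 + chunk, m)
        g = panel.dosages[:, j0:j1]
        if trait_type == "quantitative":
            beta[j0:j1], se[j0:j1] = _marginal_ols(g, y)
        elif trait_type == "binary":
            b, s, ok = _marginal_logistic(g, y)
            beta[j0:j1], se[j0:j1] = b, s
            keep[j0:j1] = ok
        else:
            raise ValueError(f"unknown trait_type {trait_type!r}")
    n_sep = int((~keep).sum())
    if n_sep:
        logger.info("summary_stats %s: dropped %d separated/degenerate variant(s)", trait_id, n_sep)
    eaf = panel.dosages.mean(axis=0) / 2.0
    keep &= np.isfinite(beta) & np.isfinite(se) & (se > 0)
    recs = _records_from_arrays(scenario, beta, se, eaf, panel.n_individuals, keep)
    return SummaryTable(trait_id=trait_id, trait_type=trait_type, records=recs)


# ---------------------------------------------------------------------------
# analytic fast path


def true_marginal_betas(
    panel: ReferencePanel, idx: tuple[int, ...], eff: tuple[float, ...]
) -> np.ndarray:
    """Population marginal (per-SNP) effects implied by a causal score:
    beta_j = cov(g_j, sum_c eff_c g_c) / var(g_j), from the panel's empirical
    second moments."""
    score = _genetic_score(panel, idx, eff)
    gc = panel.dosages - panel.dosages.mean(axis=0)
    var_g = np.mean(gc**2, axis=0)
    return (gc.T @ (score - score.mean())) / panel.n_individuals / var_g


def analytic_se(
    panel: ReferencePanel, n: float, trait_type: str, prevalence: float | None = None
) -> np.ndarray:
    """Large-sample marginal SE: 1/sqrt(n var(g)) for a unit-variance
    quantitative trait, inflated by 1/sqrt(prev(1-prev)) for a logistic
    binary trait."""
    var_g = panel.dosages.var(axis=0)
    se = 1.0 / np.sqrt(n * var_g)
    if trait_type == "binary":
        if prevalence is None:
            raise ValueError("binary traits need a prevalence for analytic SEs")
        se = se / np.sqrt(prevalence * (1 - prevalence))
    return se


def population_marginal_betas(
    scenario: SimulationScenario, idx: tuple[int, ...], eff: tuple[float, ...]
) -> np.ndarray:
    """Exact population marginal effects of a causal score under the block
    LD model: within a block every tag correlates with the causal variant at
    ``rho`` on the dosage scale and shares its allele frequency, so a tag's
    marginal effect is rho * effect; across blocks the true correlation is
    zero. (The empirical :func:`true_marginal_betas` differs from this by
    O(1/sqrt(panel n)) LD-estimation noise.)"""
    beta = np.zeros(scenario.n_variants)
    b = scenario.ld_block_size
    for c, e in zip(idx, eff):
        blk = c // b
        j0, j1 = blk * b, min((blk + 1) * b, scenario.n_variants)
        beta[j0:j1] += scenario.rho * e
        beta[c] += (1.0 - scenario.rho) * e
    return beta


def chain_true_betas(
    scenario: SimulationScenario, panel: ReferencePanel | None = None
) -> dict[str, np.ndarray]:
    """True per-SNP marginal effects of each chain trait (population values).

    The exposure's marginal effects come from its causal score; the mediator
    adds a*exposure to its own genetics; the outcome (log-OR scale, linear
    approximation valid for modest effects) combines the direct path c', the
    mediated path a*b and its own loci: the estimands the two-sample chain
    estimators target in the analytic sampling route.
    """
    bx = population_marginal_betas(scenario, scenario.exposure_causal, scenario.exposure_effects)
    gm = population_marginal_betas(scenario, scenario.mediator_causal, scenario.mediator_effects)
    go = population_marginal_betas(scenario, scenario.outcome_causal, scenario.outcome_effects)
    exposure = bx
    mediator = scenario.a * bx + gm
    outcome = scenario.b * mediator + scenario.c_prime * exposure + go
    return {"exposure": exposure, "mediator": mediator, "outcome": outcome}


def sample_summary_stats(
    scenario: SimulationScenario,
    panel: ReferencePanel,
    ld: LDMatrix,
    true_beta: np.ndarray,
    trait_type: str,
    trait_id: str,
    rng: np.random.Generator,
    n: float | None = None,
) -> SummaryTable:
    """Draw marginal effect estimates from their sampling distribution.

    beta_hat ~ MVN(true_beta, D R D) with D = diag(analytic SEs) and R the
    dosage LD matrix - the standard large-sample distribution of marginal
    GWAS effects. Equivalent to :func:`summary_stats` on fresh individuals at
    large n, but O(m^2) per replicate instead of O(n m).
    """
    n = n if n is not None else scenario.n_individuals
    se = analytic_se(panel, n, trait_type, scenario.prevalence)
    chol = _ld_chol(ld)
    noise = chol @ rng.standard_normal(len(se))
    beta = np.asarray(true_beta) + se * noise
    eaf = panel.dosages.mean(axis=0) / 2.0
    keep = np.ones(len(se), dtype=bool)
    recs = _records_from_arrays(scenario, beta, se, eaf, n, keep)
    return SummaryTable(trait_id=trait_id, trait_type=trait_type, records=recs)


def _ld_chol(ld: LDMatrix) -> np.ndarray:
    # cached on the matrix object; the jitter keeps near-singular LD factorable
    if not hasattr(ld, "_chol"):
        ld._chol = np.linalg.cholesky(ld.r + 1e-8 * np.eye(len(ld.variant_ids)))
    return ld._chol


# ---------------------------------------------------------------------------
# whole studies and presets


#: LD reference panels are typically far smaller than the GWAS cohorts
REFERENCE_PANEL_N = 5_000


def simulate_study(scenario: SimulationScenario, ref_n: int = REFERENCE_PANEL_N) -> SimulatedStudy:
    """Three independent cohorts (one per trait) plus an LD reference panel.

    Every cohort realises the full causal chain in its own individuals, but
    only contributes the summary table of its designated trait, so effect
    estimates across tables carry no sample-overlap correlation - the
    two-sample assumption the downstream estimators make. The reference
    panel shares the genotype law but none of the individuals.
    """
    seeds = np.random.SeedSequence(scenario.seed).spawn(4)
    traits_types = [("exposure", "quantitative"), ("mediator", "quantitative"), ("outcome", "binary")]
    tables: dict[str, SummaryTable] = {}
    traits_out: dict[str, np.ndarray] = {}
    for (name, ttype), seq in zip(traits_types, seeds[:3]):
        rng = np.random.default_rng(seq)
        cohort = simulate_panel(scenario, rng)
        traits = simulate_chain(cohort, scenario, rng)
        tables[name] = summary_stats(traits[name], cohort, ttype, scenario, name)
        traits_out[name] = traits[name]
        if name == "outcome":
            n_case = int(traits["outcome"].sum())
            tables[name].case_count = n_case
            tables[name].control_count = int(len(traits["outcome"]) - n_case)
    ref_scenario = replace(scenario, n_individuals=ref_n)
    panel = simulate_panel(ref_scenario, np.random.default_rng(seeds[3]))
    return SimulatedStudy(panel=panel, truth=scenario, tables=tables, traits=traits_out)


def mediator_gene_position(scenario: SimulationScenario) -> tuple[str, int]:
    """Nominal genomic position of the mediator's encoding gene: the first
    mediator causal variant's locus (block start when none is declared)."""
    ids, chroms, poss = variant_metadata(scenario)
    j = scenario.mediator_causal[0] if scenario.mediator_causal else 0
    return chroms[j], poss[j]


def _spread(n_blocks_used: int, block_size: int, offset: int = 0) -> tuple[int, ...]:
    """One causal variant in each of the first n blocks (middle of block)."""
    return tuple(b * block_size + offset for b in range(n_blocks_used))


def scenario_presets() -> dict[str, SimulationScenario]:
    """Named deterministic scenarios, one per analysis the package supports.

    * ``mediation_chain`` - the mediation arithmetic regime: a = -0.045,
      b = -0.062, total = 0.097 (so c' = 0.097 - a*b), 12 exposure and 12
      mediator loci in distinct LD blocks.
    * ``null`` - exposure and mediator keep their genetics but no causal
      chain (a = b = c' = 0): type-I calibration.
    * ``shared_causal`` - one cis variant drives the mediator, which drives
      the disease: SMR/HEIDI pass and colocalization H4.
    * ``linkage`` - distinct causal variants in the same LD block with
      opposite-sign effects (variant 0 -> mediator, variant 5 -> disease
      directly): HEIDI rejects, colocalization favours H3.
    """
    blocks = 10  # causal loci per trait below
    common = dict(n_individuals=20_000, n_variants=500, ld_block_size=10, rho=0.6)
    a, b, total = -0.045, -0.062, 0.097
    presets = {
        "mediation_chain": SimulationScenario(
            name="mediation_chain", seed=11, **common,
            a=a, b=b, c_prime=total - a * b,
            exposure_causal=_spread(12, 10, offset=2),
            exposure_effects=(0.18,) * 12,
            mediator_causal=_spread(12, 10, offset=125),  # blocks 12..23, middle
            mediator_effects=(0.18,) * 12,
        ),
        "null": SimulationScenario(
            name="null", seed=13, **common,
            exposure_causal=_spread(blocks, 10, offset=2),
            exposure_effects=(0.18,) * blocks,
            mediator_causal=_spread(blocks, 10, offset=105),
            mediator_effects=(0.18,) * blocks,
        ),
        "shared_causal": SimulationScenario(
            name="shared_causal", seed=17, **common,
            b=0.5,
            mediator_causal=(4,), mediator_effects=(0.35,),
        ),
        "linkage": SimulationScenario(
            name="linkage", seed=19, **common,
            mediator_causal=(0,), mediator_effects=(0.35,),
            outcome_causal=(5,), outcome_effects=(-0.3,),
        ),
    }
    return presets


def study_ld(study: SimulatedStudy) -> LDMatrix:
    return compute_ld(study.panel)
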