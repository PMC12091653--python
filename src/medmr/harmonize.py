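"""Allele harmonization and instrument selection.

Exposure and outcome summary statistics are aligned to a common effect allele
(variant matching by id); palindromic SNPs are resolved by allele frequency or
dropped; variants with discordant allele frequencies are excluded. Instrument
selection applies the significance threshold, greedy LD clumping and the
per-variant F-statistic filter in that order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .gwas_io import LDMatrix, SummaryRecord, SummaryTable, LookupError_

logger = logging.getLogger(__name__)

KEPT = "kept"
DROPPED_PALINDROMIC = "dropped_palindromic"
DROPPED_ALLELE_MISMATCH = "dropped_allele_mismatch"
DROPPED_AF_DISCORDANT = "dropped_af_discordant"


class EmptyIntersectionError(ValueError):
    """Exposure and outcome share no variants."""


@dataclass(frozen=True)
class HarmonizedPair:
    """One variant's exposure and outcome effects on a shared effect allele."""

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta_exp: float
    se_exp: float
    eaf_exp: float | None
    beta_out: float
    se_out: float
    eaf_out: float | None
    pval_exp: float
    flipped: bool
    status: str = KEPT

    @property
    def kept(self) -> bool:
        return self.status == KEPT


@dataclass
class SelectionParams:
    """Thresholds for instrument selection.

    Defaults follow common two-sample MR practice: genome-wide significance
    5e-8 for proteins and the relaxed 1e-5 for polygenic lipid species,
    clumping at r^2 < 0.001 in 10,000 kb windows, F >= 10.
    """

    p_threshold: float = 5e-8
    r2_threshold: float = 0.001
    window_kb: float = 10_000.0
    f_min: float = 10.0
    palindrome_window: tuple[float, float] = (0.42, 0.58)
    max_af_diff: float = 0.2


@dataclass
class IVSet:
    """Instruments surviving selection for one exposure, with diagnostics."""

    exposure_id: str
    harmonized: list[HarmonizedPair]
    f_stats: dict[str, float]
    selection_params: SelectionParams
    empty_reason: str | None = None

    def __len__(self) -> int:
        return len(self.harmonized)

    @property
    def is_empty(self) -> bool:
        return len(self.harmonized) == 0


def _alleles_match(exp: SummaryRecord, out: SummaryRecord) -> str | None:
    """'same', 'swapped', or None for an unresolvable allele pair."""
    if (exp.effect_allele, exp.other_allele) == (out.effect_allele, out.other_allele):
        return "same"
    if (exp.effect_allele, exp.other_allele) == (out.other_allele, out.effect_allele):
        return "swapped"
    return None


def _ambiguous(eaf: float | None, window: tuple[float, float]) -> bool:
    return eaf is None or window[0] <= eaf <= window[1]


def harmonize(
    exp: SummaryTable,
    out: SummaryTable,
    params: SelectionParams | None = None,
) -> list[HarmonizedPair]:
    """Align outcome effects to the exposure's effect allele, variant by variant.

    Swapped outcome alleles negate ``beta_out`` and mirror ``eaf_out``.
    Palindromic (A/T, C/G) SNPs are kept only when both allele frequencies are
    known and both fall outside the ambiguity window; their orientation is
    inferred by frequency (minor-with-minor). Pairs whose frequencies still
    disagree by more than ``max_af_diff`` are dropped with status. All shared
    variants are returned, dropped ones carrying their drop status.
    """
    params = params or SelectionParams()
    shared = [r.variant_id for r in exp if out.get(r.variant_id) is not None]
    if not shared:
        raise EmptyIntersectionError(
            f"no shared variants between {exp.trait_id!r} and {out.trait_id!r}"
        )
    pairs: list[HarmonizedPair] = []
    for vid in shared:
        e = exp.get(vid)
        o = out.get(vid)
        base = dict(
            variant_id=vid,
            chrom=e.chrom,
            pos=e.pos,
            effect_allele=e.effect_allele,
            other_allele=e.other_allele,
            beta_exp=e.beta,
            se_exp=e.se,
            eaf_exp=e.eaf,
            pval_exp=e.pval,
        )
        rel = _alleles_match(e, o)
        if rel is None:
            pairs.append(HarmonizedPair(
                **base, beta_out=o.beta, se_out=o.se, eaf_out=o.eaf,
                flipped=False, status=DROPPED_ALLELE_MISMATCH,
            ))
            continue
        flipped = rel == "swapped"
        beta_out = -o.beta if flipped else o.beta
        eaf_out = None if o.eaf is None else (1 - o.eaf if flipped else o.eaf)
        if e.is_palindromic():
            # allele labels cannot resolve strand; use frequencies or drop
            if _ambiguous(e.eaf, params.palindrome_window) or _ambiguous(eaf_out, params.palindrome_window):
                pairs.append(HarmonizedPair(
                    **base, beta_out=beta_out, se_out=o.se, eaf_out=eaf_out,
                    flipped=flipped, status=DROPPED_PALINDROMIC,
                ))
                continue
            if (e.eaf < 0.5) != (eaf_out < 0.5):
                # frequencies on opposite sides: the outcome is strand-flipped
                beta_out = -beta_out
                eaf_out = 1 - eaf_out
                flipped = not flipped
        if (
            e.eaf is not None
            and eaf_out is not None
            and abs(e.eaf - eaf_out) > params.max_af_diff
        ):
            pairs.append(HarmonizedPair(
                **base, beta_out=beta_out, se_out=o.se, eaf_out=eaf_out,
                flipped=flipped, status=DROPPED_AF_DISCORDANT,
            ))
            continue
        pairs.append(HarmonizedPair(
            **base, beta_out=beta_out, se_out=o.se, eaf_out=eaf_out,
            flipped=flipped, status=KEPT,
        ))
    n_dropped = sum(not p.kept for p in pairs)
    if n_dropped:
        logger.info(
            "harmonize %s~%s: dropped %d of %d shared variants",
            exp.trait_id, out.trait_id, n_dropped, len(pairs),
        )
    return pairs


def clump(
    records: Sequence[SummaryRecord],
    ld: LDMatrix,
    r2_threshold: float = 0.001,
    window_kb: float = 10_000.0,
) -> list[str]:
    """Greedy LD clumping; returns retained variant ids ordered by p-value.

    Repeatedly takes the smallest-p unretired variant and retires every other
    variant on the same chromosome within ``window_kb`` (inclusive, both
    sides) whose r^2 with it meets ``r2_threshold``. Ties in p are broken by
    smaller position then lexicographic id, making the output invariant to
    input row order.
    """
    recs = sorted(records, key=lambda r: (r.pval, r.pos, r.variant_id))
    for r in recs:
        ld.index_of(r.variant_id)  # raises LookupError_ if missing
    window_bp = window_kb * 1000.0
    retained: list[str] = []
    retired: set[str] = set()
    for lead in recs:
        if lead.variant_id in retired:
            continue
        retained.append(lead.variant_id)
        for other in recs:
            if other.variant_id == lead.variant_id or other.variant_id in retired:
                continue
            if other.chrom != lead.chrom:
                continue
            if abs(other.pos - lead.pos) > window_bp:
                continue
            if ld.r2_between(lead.variant_id, other.variant_id) >= r2_threshold:
                retired.add(other.variant_id)
    return retained


def f_statistic(beta: float, se: float) -> float:
    """Per-variant instrument strength F = (beta/se)^2."""
    if se <= 0:
        raise ValueError(f"se must be positive, got {se}")
    return (beta / se) ** 2


def select_instruments(
    exp: SummaryTable,
    out: SummaryTable,
    ld: LDMatrix,
    params: SelectionParams | None = None,
) -> IVSet:
    """Threshold -> clump -> harmonize -> F-filter pipeline.

    An empty instrument set is a typed result (``IVSet.empty_reason`` set),
    never an exception, so genome-wide scans can continue past null exposures.
    """
    params = params or SelectionParams()

    def empty(reason: str) -> IVSet:
        logger.info("select_instruments %s: %s", exp.trait_id, reason)
        return IVSet(exp.trait_id, [], {}, params, empty_reason=reason)

    candidates = [r for r in exp if r.pval <= params.p_threshold]
    if not candidates:
        return empty(f"no variants at p <= {params.p_threshold:g}")
    retained_ids = clump(candidates, ld, params.r2_threshold, params.window_kb)
    try:
        pairs = harmonize(exp.subset(retained_ids), out, params)
    except EmptyIntersectionError as exc:
        return empty(str(exc))
    kept = [p for p in pairs if p.kept]
    f_stats = {p.variant_id: f_statistic(p.beta_exp, p.se_exp) for p in kept}
    strong = [p for p in kept if f_stats[p.variant_id] >= params.f_min]
    if not strong:
        return empty(f"no harmonized variants with F >= {params.f_min:g}")
    return IVSet(
        exposure_id=exp.trait_id,
        harmonized=sorted(strong, key=lambda p: (p.pval_exp, p.pos, p.variant_id)),
        f_stats={p.variant_id: f_stats[p.variant_id] for p in strong},
        selection_params=params,
    )
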