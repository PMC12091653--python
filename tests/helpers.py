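"""Builders for small hand-made summary tables used across the test suite."""

from __future__ import annotations

import numpy as np
from scipy import stats

from medmr.gwas_io import LDMatrix, ReferencePanel, SummaryRecord, SummaryTable


def rec(
    vid: str,
    chrom: str = "1",
    pos: int = 1000,
    ea: str = "A",
    oa: str = "G",
    eaf: float | None = 0.3,
    beta: float = 0.1,
    se: float = 0.02,
    pval: float | None = None,
    n: float = 10_000,
) -> SummaryRecord:
    if pval is None:
        pval = max(float(2 * stats.norm.sf(abs(beta / se))), 1e-300)
    return SummaryRecord(
        variant_id=vid, chrom=chrom, pos=pos, effect_allele=ea, other_allele=oa,
        eaf=eaf, beta=beta, se=se, pval=pval, n=n,
    )


def table(records, trait_id="trait", trait_type="quantitative", **kw) -> SummaryTable:
    return SummaryTable(trait_id=trait_id, trait_type=trait_type, records=list(records), **kw)


def identity_ld(ids) -> LDMatrix:
    return LDMatrix(list(ids), np.eye(len(ids)))


def ld_from(ids, r) -> LDMatrix:
    return LDMatrix(list(ids), np.asarray(r, dtype=float))


def tiny_panel(dosages, ids=None) -> ReferencePanel:
    d = np.asarray(dosages, dtype=float)
    ids = ids or [f"v{j}" for j in range(d.shape[1])]
    return ReferencePanel(list(ids), d)
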