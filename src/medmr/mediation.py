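"""Two-step MR mediation: product of coefficients with delta-method errors.

The indirect (mediated) effect of an exposure on the outcome through a
mediator is the product of the exposure->mediator effect ``a`` and the
mediator->outcome effect ``b``; its standard error follows from first-order
error propagation, and the proportion mediated is the ratio of the indirect
effect to the total exposure->outcome effect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .gwas_io import LDMatrix, SummaryTable
from .harmonize import SelectionParams, select_instruments
from .mr import Z95, ivw, wald_ratios

logger = logging.getLogger(__name__)


@dataclass
class MediationResult:
    """One exposure -> mediator -> outcome pathway.

    Effects are on the log-OR scale for a binary outcome; ``proportion`` is
    in percent and signed, with ``additivity_violated`` flagging pathways
    where the mediated and total effects disagree in sign (or the proportion
    exceeds 100%), under which the proportion is not interpretable as a
    share of the total effect.
    """

    pathway_id: tuple[str, str, str]
    total: float
    se_total: float
    direct_a: float
    se_a: float
    direct_b: float
    se_b: float
    mediation: float
    se_mediation: float
    p_mediation: float
    proportion: float | None
    prop_ci: tuple[float, float] | None
    additivity_violated: bool = False
    estimable: bool = True
    reason: str | None = None
    leg_estimators: tuple[str, str, str] | None = None

    def to_row(self) -> dict:
        lo, hi = self.prop_ci if self.prop_ci else (None, None)
        return {
            "exposure": self.pathway_id[0],
            "mediator": self.pathway_id[1],
            "outcome": self.pathway_id[2],
            "total": self.total,
            "se_total": self.se_total,
            "direct_a": self.direct_a,
            "se_a": self.se_a,
            "direct_b": self.direct_b,
            "se_b": self.se_b,
            "mediation": self.mediation,
            "se_mediation": self.se_mediation,
            "p_mediation": self.p_mediation,
            "proportion_pct": self.proportion,
            "prop_ci_lo": lo,
            "prop_ci_hi": hi,
            "additivity_violated": self.additivity_violated,
            "estimable": self.estimable,
        }


def mediation_effect(
    a: float, se_a: float, b: float, se_b: float
) -> tuple[float, float, float]:
    """Indirect effect a*b with first-order propagated SE and two-sided p.

    se = sqrt(a^2 se_b^2 + b^2 se_a^2); symmetric in (a, se_a) <-> (b, se_b).
    When both legs are exactly zero the SE degenerates to 0 and p is 1.
    """
    if se_a <= 0 or se_b <= 0:
        raise ValueError("leg standard errors must be positive")
    med = a * b
    se = float(np.sqrt(a**2 * se_b**2 + b**2 * se_a**2))
    if se == 0:
        return float(med), se, 1.0
    p = float(2 * stats.norm.sf(abs(med / se)))
    return float(med), se, p


def mediated_proportion(
    mediation: float,
    se_mediation: float,
    total: float,
    se_total: float,
) -> tuple[float, tuple[float, float] | None]:
    """Signed proportion mediated (percent) with an independence delta CI.

    proportion = 100 * mediation/total; its SE treats the mediated and total
    effects as independent:
    se_prop = |proportion| * sqrt((se_med/mediation)^2 + (se_total/total)^2).
    The CI is undefined (None) when the mediated effect is exactly zero.
    """
    if total == 0:
        raise ZeroDivisionError("total effect is zero; proportion undefined")
    prop = 100.0 * mediation / total
    if mediation == 0:
        return float(prop), None
    se_prop = abs(prop) * np.sqrt(
        (se_mediation / mediation) ** 2 + (se_total / total) ** 2
    )
    ci = (float(prop - Z95 * se_prop), float(prop + Z95 * se_prop))
    return float(prop), ci


def assemble(
    pathway_id: tuple[str, str, str],
    total: float,
    se_total: float,
    a: float,
    se_a: float,
    b: float,
    se_b: float,
    leg_estimators: tuple[str, str, str] | None = None,
) -> MediationResult:
    """Build a MediationResult from the three leg estimates."""
    med, se_med, p_med = mediation_effect(a, se_a, b, se_b)
    if total != 0:
        prop, ci = mediated_proportion(med, se_med, total, se_total)
        violated = (np.sign(total) != np.sign(med) and med != 0) or abs(prop) > 100
    else:
        prop, ci, violated = None, None, True
    return MediationResult(
        pathway_id=pathway_id,
        total=total, se_total=se_total,
        direct_a=a, se_a=se_a, direct_b=b, se_b=se_b,
        mediation=med, se_mediation=se_med, p_mediation=p_med,
        proportion=prop, prop_ci=ci,
        additivity_violated=bool(violated),
        leg_estimators=leg_estimators,
    )


def _ivw_leg(
    exp: SummaryTable,
    out: SummaryTable,
    ld: LDMatrix,
    params: SelectionParams,
) -> tuple[float, float, str] | None:
    ivset = select_instruments(exp, out, ld, params)
    if ivset.is_empty:
        logger.info("mediation leg %s->%s non-estimable: %s",
                    exp.trait_id, out.trait_id, ivset.empty_reason)
        return None
    est = ivw(wald_ratios(ivset), mode="multiplicative_random")
    return est.beta, est.se, est.method


def two_step(
    exposure: SummaryTable,
    mediator: SummaryTable,
    outcome: SummaryTable,
    ld: LDMatrix,
    exposure_params: SelectionParams | None = None,
    mediator_params: SelectionParams | None = None,
) -> MediationResult:
    """Full two-step MR mediation from summary statistics.

    Three IVW fits: exposure->outcome (total effect), exposure->mediator
    (leg a), mediator->outcome (leg b). A leg with no valid instruments makes
    the pathway non-estimable (flagged, not raised). ``exposure_params`` and
    ``mediator_params`` set the instrument thresholds for legs instrumented
    by the exposure and mediator respectively (e.g. 1e-5 for lipid species,
    5e-8 for proteins).
    """
    exposure_params = exposure_params or SelectionParams(p_threshold=1e-5)
    mediator_params = mediator_params or SelectionParams(p_threshold=5e-8)
    pathway = (exposure.trait_id, mediator.trait_id, outcome.trait_id)
    legs = {
        "total": _ivw_leg(exposure, outcome, ld, exposure_params),
        "a": _ivw_leg(exposure, mediator, ld, exposure_params),
        "b": _ivw_leg(mediator, outcome, ld, mediator_params),
    }
    missing = [k for k, v in legs.items() if v is None]
    if missing:
        return MediationResult(
            pathway_id=pathway,
            total=np.nan, se_total=np.nan, direct_a=np.nan, se_a=np.nan,
            direct_b=np.nan, se_b=np.nan, mediation=np.nan, se_mediation=np.nan,
            p_mediation=np.nan, proportion=None, prop_ci=None,
            estimable=False, reason=f"no instruments for leg(s): {', '.join(missing)}",
        )
    total_b, total_se, m_tot = legs["total"]
    a_b, a_se, m_a = legs["a"]
    b_b, b_se, m_b = legs["b"]
    return assemble(
        pathway, total_b, total_se, a_b, a_se, b_b, b_se,
        leg_estimators=(m_tot, m_a, m_b),
    )


def round_for_report(result: MediationResult) -> dict:
    """Report-time rounding: 3 dp on betas, 2 significant figures on percents.

    Rounding is presentation only; computations always use full precision.
    """
    def sf2(x: float | None) -> float | None:
        if x is None or not np.isfinite(x):
            return None
        if x == 0:
            return 0.0
        return float(np.format_float_positional(
            x, precision=2, unique=False, fractional=False, trim="k"
        ))

    row = result.to_row()
    for key in ("total", "direct_a", "direct_b", "mediation"):
        row[key] = round(row[key], 3) if np.isfinite(row[key]) else row[key]
    row["proportion_pct"] = sf2(row["proportion_pct"])
    row["prop_ci_lo"] = sf2(row["prop_ci_lo"])
    row["prop_ci_hi"] = sf2(row["prop_ci_hi"])
    return row
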