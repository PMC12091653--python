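"""Scan orchestration: protein SMR/coloc scan, lipid MR scan, bidirectional
MR, and mediation assembly, with config handling and reproducible reports."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from . import __version__
from .coloc import ColocPriors, ColocResult, coloc_abf
from .gwas_io import LDMatrix, SummaryTable, write_report
from .harmonize import SelectionParams, select_instruments
from .mediation import MediationResult, assemble, two_step
from .mr import MREstimate, run_all_methods
from .smr import HeidiParams, SMRResult, smr_scan

logger = logging.getLogger(__name__)

#: rows reported per exposure in the lipid scan (IVW plus sensitivity methods)
SCAN_METHODS = ("ivw_mre", "ivw_fixed", "egger", "weighted_median", "max_likelihood")


@dataclass
class ScanConfig:
    """Thresholds and priors for the full pipeline; YAML round-trippable."""

    schema_version: int = 1
    p_threshold_lipid: float = 1e-5
    p_threshold_protein: float = 5e-8
    clump_r2: float = 0.001
    clump_window_kb: float = 10_000.0
    f_min: float = 10.0
    palindrome_window: tuple[float, float] = (0.42, 0.58)
    max_af_diff: float = 0.2
    cis_window_kb: float = 1000.0
    heidi: HeidiParams = field(default_factory=HeidiParams)
    coloc_priors: ColocPriors = field(default_factory=ColocPriors)
    fdr_alpha: float = 0.05
    heidi_alpha: float = 0.01
    coloc_strong: float = 0.6
    lipid_scan_fdr: bool = False  # nominal p < .05, no multiplicity correction
    seed: int = 0

    def lipid_params(self) -> SelectionParams:
        return SelectionParams(
            p_threshold=self.p_threshold_lipid, r2_threshold=self.clump_r2,
            window_kb=self.clump_window_kb, f_min=self.f_min,
            palindrome_window=self.palindrome_window, max_af_diff=self.max_af_diff,
        )

    def protein_params(self) -> SelectionParams:
        return SelectionParams(
            p_threshold=self.p_threshold_protein, r2_threshold=self.clump_r2,
            window_kb=self.clump_window_kb, f_min=self.f_min,
            palindrome_window=self.palindrome_window, max_af_diff=self.max_af_diff,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]

    def header_meta(self) -> dict:
        return {
            "medmr_version": __version__,
            "config_hash": self.config_hash(),
            "seed": self.seed,
        }

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "ScanConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        version = raw.pop("schema_version", 1)
        if version != 1:
            raise ValueError(f"unsupported config schema_version {version}")
        heidi = HeidiParams(**raw.pop("heidi", {}))
        priors = ColocPriors(**raw.pop("coloc_priors", {}))
        if "palindrome_window" in raw:
            raw["palindrome_window"] = tuple(raw["palindrome_window"])
        raw.update(overrides)
        return cls(schema_version=1, heidi=heidi, coloc_priors=priors, **raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


# ---------------------------------------------------------------------------


def run_protein_scan(
    proteins: Sequence[tuple[SummaryTable, tuple[str, int]]],
    gwas: SummaryTable,
    ld: LDMatrix,
    config: ScanConfig | None = None,
) -> tuple[list[SMRResult], list[ColocResult]]:
    """SMR + HEIDI per protein, BH-FDR across the scan, colocalization on
    the FDR-passing proteins' cis regions. Returns (smr results, coloc
    results); an empty protein list yields empty reports, not an error."""
    config = config or ScanConfig()
    if not proteins:
        return [], []
    smr_results = smr_scan(
        proteins, gwas, ld,
        window_kb=config.cis_window_kb, p_max=config.p_threshold_protein,
        heidi_params=config.heidi, fdr_alpha=config.fdr_alpha,
        heidi_alpha=config.heidi_alpha,
    )
    by_id = {tbl.trait_id: (tbl, pos) for tbl, pos in proteins}
    coloc_results: list[ColocResult] = []
    for res in smr_results:
        if not res.passes:
            continue
        pqtl, (chrom, pos) = by_id[res.protein_id]
        window_bp = config.cis_window_kb * 1000
        region_ids = [
            r.variant_id for r in pqtl
            if r.chrom == str(chrom) and abs(r.pos - pos) <= window_bp
        ]
        region_p = pqtl.subset(region_ids)
        region_g = gwas.subset(region_ids)
        try:
            cres = coloc_abf(region_p, region_g, priors=config.coloc_priors,
                             region_id=res.protein_id)
        except ValueError as exc:
            logger.info("protein scan: coloc skipped for %s (%s)", res.protein_id, exc)
            continue
        cres.strong_threshold = config.coloc_strong
        coloc_results.append(cres)
    return smr_results, coloc_results


def run_lipid_scan(
    lipids: Sequence[SummaryTable],
    gwas: SummaryTable,
    ld: LDMatrix,
    config: ScanConfig | None = None,
) -> list[MREstimate | dict]:
    """IVW plus sensitivity estimators per lipid against the disease GWAS.

    Flags use nominal p < .05 per method with no multiplicity correction.
    Lipids with no surviving instruments are reported as non-estimable rows.
    """
    config = config or ScanConfig()
    rows: list = []
    for lipid in lipids:
        ivset = select_instruments(lipid, gwas, ld, config.lipid_params())
        if ivset.is_empty:
            rows.append({
                "exposure": lipid.trait_id, "outcome": gwas.trait_id,
                "method": None, "estimable": False, "reason": ivset.empty_reason,
            })
            continue
        for est in run_all_methods(ivset, wm_seed=config.seed + 101):
            est.outcome_id = gwas.trait_id
            rows.append(est)
    return rows


def run_bidirectional(
    lipids: Sequence[SummaryTable],
    proteins: Sequence[SummaryTable],
    ld: LDMatrix,
    config: ScanConfig | None = None,
) -> list[dict]:
    """Lipid->protein (threshold 1e-5) and protein->lipid (5e-8) MR, one row
    per (pair, direction, method) with the direction recorded."""
    config = config or ScanConfig()
    rows: list[dict] = []
    jobs = [
        ("lipid_to_protein", lipids, proteins, config.lipid_params()),
        ("protein_to_lipid", proteins, lipids, config.protein_params()),
    ]
    for direction, exps, outs, params in jobs:
        for exp in exps:
            for out in outs:
                ivset = select_instruments(exp, out, ld, params)
                if ivset.is_empty:
                    rows.append({
                        "direction": direction, "exposure": exp.trait_id,
                        "outcome": out.trait_id, "method": None,
                        "estimable": False, "reason": ivset.empty_reason,
                    })
                    continue
                for est in run_all_methods(ivset, wm_seed=config.seed + 101):
                    row = est.to_row()
                    row["direction"] = direction
                    row["outcome"] = out.trait_id
                    row["estimable"] = True
                    rows.append(row)
    return rows


def run_mediation(
    leg_estimates: Sequence[Mapping],
    config: ScanConfig | None = None,
) -> list[MediationResult]:
    """Assemble mediation rows from per-leg estimates.

    Each entry supplies pathway labels plus (total, se_total, a, se_a, b,
    se_b); pathways with a missing leg are reported non-estimable. Rows where
    the mediated and total effect disagree in sign carry the additivity flag.
    """
    results: list[MediationResult] = []
    for leg in leg_estimates:
        pathway = (leg["exposure"], leg["mediator"], leg["outcome"])
        needed = ("total", "se_total", "a", "se_a", "b", "se_b")
        if any(leg.get(k) is None for k in needed):
            missing = [k for k in needed if leg.get(k) is None]
            results.append(MediationResult(
                pathway_id=pathway, total=np.nan, se_total=np.nan,
                direct_a=np.nan, se_a=np.nan, direct_b=np.nan, se_b=np.nan,
                mediation=np.nan, se_mediation=np.nan, p_mediation=np.nan,
                proportion=None, prop_ci=None, estimable=False,
                reason=f"missing leg value(s): {', '.join(missing)}",
            ))
            continue
        results.append(assemble(
            pathway, leg["total"], leg["se_total"],
            leg["a"], leg["se_a"], leg["b"], leg["se_b"],
        ))
    return results


def run_full_pipeline(
    exposure: SummaryTable,
    mediator: SummaryTable,
    outcome: SummaryTable,
    ld: LDMatrix,
    mediator_gene_pos: tuple[str, int],
    config: ScanConfig | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Protein scan + lipid scan + bidirectional MR + two-step mediation on
    one exposure/mediator/outcome triple; optionally writes all reports."""
    config = config or ScanConfig()
    smr_results, coloc_results = run_protein_scan(
        [(mediator, mediator_gene_pos)], outcome, ld, config
    )
    lipid_rows = run_lipid_scan([exposure], outcome, ld, config)
    bidir_rows = run_bidirectional([exposure], [mediator], ld, config)
    med = two_step(
        exposure, mediator, outcome, ld,
        exposure_params=config.lipid_params(),
        mediator_params=config.protein_params(),
    )
    out = {
        "smr": smr_results,
        "coloc": coloc_results,
        "lipid_scan": lipid_rows,
        "bidirectional": bidir_rows,
        "mediation": [med],
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        meta = config.header_meta()
        for kind, results in out.items():
            if results:
                write_report(list(results), out_dir / f"{kind}.tsv", header_meta=meta)
    return out
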