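#!/usr/bin/env python
"""Lipid -> disease MR scan with the five estimators.

Instruments at p < 1e-5, LD-clumped (r2 < 0.001 in 10,000 kb windows),
F >= 10; flags use nominal p < .05 per method with no multiplicity
correction. On the mediation-chain world the lipid's total effect on disease
is 0.097 on the log-OR scale; on the null world nothing should replicate
beyond type I error.
"""

from pathlib import Path

from medmr.gwas_io import read_ld, read_summary_table, write_report
from medmr.mr import MREstimate
from medmr.pipeline import ScanConfig, run_lipid_scan

ROOT = Path(__file__).resolve().parent.parent / "results"
SYN = Path(__file__).resolve().parent.parent / "scratch" / "synthetic"


def main() -> None:
    ROOT.mkdir(parents=True, exist_ok=True)
    config = ScanConfig()
    all_rows = []
    for name in ("mediation_chain", "null"):
        d = SYN / name
        lipid = read_summary_table(d / "exposure.tsv", trait_id=f"{name}:lipid")
        gwas = read_summary_table(d / "outcome.tsv", trait_id=f"{name}:gc", trait_type="binary")
        ld = read_ld(d / "ld.tsv")
        rows = run_lipid_scan([lipid], gwas, ld, config)
        for r in rows:
            if isinstance(r, MREstimate):
                or_, lo, hi = r.or_with_ci
                flag = "*" if r.pval < 0.05 else " "
                print(f"{name:16s} {r.method:16s} n_snp={r.n_snp:2d} "
                      f"OR={or_:.3f} ({lo:.3f}-{hi:.3f}) p={r.pval:.3g} {flag}")
                all_rows.append(r)
            else:
                print(f"{name}: non-estimable ({r['reason']})")
    write_report(all_rows, ROOT / "lipid_scan.tsv", header_meta=config.header_meta())
    print(f"report: {ROOT / 'lipid_scan.tsv'}")


if __name__ == "__main__":
    main()
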