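#!/usr/bin/env python
"""Generate the four synthetic study worlds and write their cohort files.

Each preset yields three independent GWAS cohorts (quantitative lipid
exposure, quantitative protein mediator, binary disease outcome), an LD
reference panel, and a truth record. The mediation-chain preset encodes the
published discovery-phase effect sizes (a = -0.045, b = -0.062, total =
0.097); the others give a null world, a shared-causal-variant cis region and
a linkage cis region.
"""

import json
from dataclasses import asdict
from pathlib import Path

from medmr import __version__
from medmr.gwas_io import write_ld, write_panel, write_summary_table
from medmr.simulate import scenario_presets, simulate_study, study_ld

# cohort files are large generated inputs, not deliverables: they go to scratch/
OUT = Path(__file__).resolve().parent.parent / "scratch" / "synthetic"


def main() -> None:
    for name, scenario in scenario_presets().items():
        out = OUT / name
        out.mkdir(parents=True, exist_ok=True)
        study = simulate_study(scenario)
        meta = {"medmr_version": __version__, "preset": name, "seed": scenario.seed}
        write_panel(study.panel, out / "panel.tsv", header_meta=meta)
        write_ld(study_ld(study), out / "ld.tsv")
        for trait, tbl in study.tables.items():
            write_summary_table(tbl, out / f"{trait}.tsv", header_meta=meta)
        (out / "truth.json").write_text(json.dumps(asdict(scenario), indent=1))
        n_case = study.tables["outcome"].case_count
        print(f"{name}: 3 cohorts of n={scenario.n_individuals} "
              f"({n_case} cases), {scenario.n_variants} variants -> {out}")


if __name__ == "__main__":
    main()
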