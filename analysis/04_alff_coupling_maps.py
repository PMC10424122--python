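#!/usr/bin/env python
"""Per-subject ALFF and ALFF/VBM coupling maps.

For each subject: preprocess, smooth within the subject's WM (4 mm FWHM),
compute ALFF in 0.01-0.1 Hz, divide by the WM tissue density.  Writes the
group means of regional ALFF, density and coupling inside the injected
effect region to results/regional_means.tsv — the raw material for the
group ordering the inference stage should detect.

Run analysis/01_simulate_cohort.py first.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from couplemap import synth
from couplemap.pipeline import RunConfig, _process_subject

RESULTS = Path("results")
COHORT = Path("scratch/cohort")


def main() -> None:
    if not COHORT.exists():
        raise SystemExit("run analysis/01_simulate_cohort.py first")
    subjects, phenotype, cfg = synth.load_cohort(COHORT)
    run_cfg = RunConfig(cohort=cfg, tissues=("wm",), measures=("coupling",))
    region = cfg.effect_regions[0].mask(cfg.grid_shape)
    rows = []
    for s in subjects:
        maps = _process_subject(s, run_cfg)["maps"]
        alff = maps[("alff", "wm")]
        cpl = maps[("coupling", "wm")]
        sel = region & cpl.mask
        rows.append({
            "subject": s.subject_id, "group": s.phenotype_row["group"],
            "regional_alff": alff.data[sel].mean(),
            "regional_wm_density": s.tpm_wm[sel].mean(),
            "regional_coupling": cpl.data[sel].mean(),
            "mmse": s.phenotype_row["mmse"],
        })
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "regional_means.tsv", sep="\t", index=False,
                 float_format="%.4f")
    summary = table.groupby("group")[
        ["regional_alff", "regional_wm_density", "regional_coupling", "mmse"]
    ].mean().reindex(["NC", "VMCI", "MCI"]).round(4)
    print("group means inside the injected region "
          "(per-subject values in results/regional_means.tsv):")
    print(summary.to_string())
    print("\nexpected pattern: coupling increases NC -> VMCI -> MCI while "
          "density is unchanged (the effect is an amplitude shift)")


if __name__ == "__main__":
    main()
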