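#!/usr/bin/env python
"""Plasma PK of the single-ascending-dose study.

Per-subject one-compartment fits (pooled by averaging), non-compartmental
summaries per dose, and the power-model dose-proportionality assessment of
Cmax and AUC0-inf.  Writes results/pk_by_dose.csv and results/pk_fit.json.
"""

import argparse
import json
from pathlib import Path

from dotinurad_pkpd import PipelineConfig
from dotinurad_pkpd.io import read_dataset
from dotinurad_pkpd.pipeline import nca_stage, pk_stage, proportionality_stage

ROOT = Path(__file__).resolve().parents[1]


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", type=Path, default=ROOT / "results" / "data")
    parser.add_argument("--out", type=Path, default=ROOT / "results")
    args = parser.parse_args()

    sad = read_dataset(args.data / "sad")
    config = PipelineConfig()

    pooled, cv, by_subject = pk_stage(sad, config)
    by_dose, nca_subject = nca_stage(sad)
    prop = proportionality_stage(nca_subject)

    by_dose.to_csv(args.out / "pk_by_dose.csv", index=False)
    summary = {
        "pooled": {"v_f_ml": pooled.v_f, "ka_per_h": pooled.ka,
                   "ke_per_h": pooled.ke, "t_half_h": pooled.t_half,
                   "cl_f_l_h": pooled.cl_f / 1e3},
        "between_subject_cv_percent": cv,
        "n_fits": len(by_subject),
        "dose_proportionality": {
            k: {"slope": v.slope, "slope_ci90": list(v.slope_ci90)}
            for k, v in prop.items()
        },
    }
    (args.out / "pk_fit.json").write_text(json.dumps(summary, indent=2))

    print(f"pooled fit over {len(by_subject)} subjects: "
          f"V/F={pooled.v_f:.0f} mL, Ka={pooled.ka:.3f}/h, "
          f"Ke={pooled.ke:.4f}/h (t1/2={pooled.t_half:.2f} h, "
          f"CL/F={pooled.cl_f / 1e3:.3f} L/h)")
    for k, v in prop.items():
        print(f"dose proportionality ({k}): slope={v.slope:.3f} "
              f"90% CI {v.slope_ci90[0]:.3f}-{v.slope_ci90[1]:.3f}")


if __name__ == "__main__":
    main()
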