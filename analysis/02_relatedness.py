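#!/usr/bin/env python
"""Genomic relatedness inside and across open-pollinated families.

Reproduces, by simulation, the classical expectations that motivate the
marker-based kernel: maternal half-sibs average G ~ 0.25, unrelated
families ~ 0.00, dam-offspring pairs ~ 0.50; and shows how hidden shared
fathers (full_sib_fraction > 0) push the within-family mean above 0.25.
Writes results/02_relatedness.csv and the pooled histogram table
results/02_relatedness_hist.csv.
"""
import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from crossgen_gs.experiments import relatedness_study

ROOT = Path(__file__).resolve().parents[1]


def main(seed: int) -> None:
    rows, hist_rows = [], []
    for f in (0.0, 0.04, 0.25):
        study = relatedness_study(seed=seed, full_sib_fraction=f)
        rows.append({
            "full_sib_fraction": f,
            "within_family_mean": round(study["within_family_mean"], 4),
            "among_family_mean": round(study["among_family_mean"], 4),
            "dam_offspring_mean": round(study["dam_offspring_mean"], 4),
            "n_within_pairs": study["n_within_pairs"],
            "n_among_pairs": study["n_among_pairs"],
        })
        s = study["summary"]
        for scope, (counts, edges) in (("within", s.within_hist),
                                       ("among", s.among_hist)):
            for c, lo in zip(counts, edges[:-1]):
                hist_rows.append({"full_sib_fraction": f, "scope": scope,
                                  "bin_lo": round(float(lo), 3),
                                  "count": int(c)})
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    df = pd.DataFrame(rows)
    df.to_csv(results / "02_relatedness.csv", index=False)
    pd.DataFrame(hist_rows).to_csv(results / "02_relatedness_hist.csv", index=False)
    print(df.to_string(index=False))
    print("\npure half-sib families cluster at 0.25; father sharing "
          "inflates the within-family mean by ~0.25 x P(shared father).")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=20260920)
    main(ap.parse_args().seed)
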