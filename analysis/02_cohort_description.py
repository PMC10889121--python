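#!/usr/bin/env python
"""Demographic and clinical comparison of the two groups.

Reproduces the cohort-description analysis: eye- and subject-level sex
distributions compared with Pearson chi-squared, age and the clinical
covariates (BCVA, IOP, cupping, MD, PSD) compared with pooled-variance
t-tests after a Kolmogorov-Smirnov normality screen.
"""

import argparse
from pathlib import Path

from ppgrid.cohort_stats import cohort_table, ks_normality
from ppgrid.grid import read_cohort


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--results", type=Path, default=Path("results"))
    args = parser.parse_args()

    cohort = read_cohort(args.results / "cohort.csv")
    table = cohort_table(cohort)
    out = args.results / "cohort_comparison.csv"
    table.to_csv(out, index=False)

    ages = [r.age for r in cohort.records]
    ks = ks_normality(ages)
    print(f"KS normality screen on age: D = {ks.statistic:.3f}, "
          f"p = {ks.p_value:.3f} (approximate, estimated parameters)")
    for row in table.itertuples():
        if row.test == "Pearson chi-squared":
            print(f"{row.variable}: chi2 = {row.statistic:.3f}, "
                  f"p = {row.p_value:.3f}")
        else:
            print(f"{row.variable}: control {row.control_mean:.2f} "
                  f"({row.control_sd:.2f}) vs glaucoma {row.glaucoma_mean:.2f} "
                  f"({row.glaucoma_sd:.2f}), t({int(row.df)}) = "
                  f"{row.statistic:.2f}, p = {row.p_value:.3g}")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
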