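#!/usr/bin/env python
"""Equal-sensitivity/specificity cutoffs and diagnostic validity indices.

For every layer retained by the index analysis (tilted grid, mean
index), chooses the thickness cutoff at which sensitivity and
specificity are as equal and as high as possible, and reports
Se/Sp/PPV/NPV with 95% confidence intervals.  Eyes below the cutoff are
classified glaucomatous.
"""

import argparse
from pathlib import Path

from ppgrid.cutoffs import choose_cutoff, cutoff_table
from ppgrid.grid import GridOrientation, read_cohort
from ppgrid.heatmap import build_heatmap
from ppgrid.indices import IndexKind, compute_index


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--results", type=Path, default=Path("results"))
    args = parser.parse_args()

    cohort = read_cohort(args.results / "cohort.csv")
    results = []
    for seg in cohort.segmentations():
        hm = build_heatmap(cohort, seg, GridOrientation.TILTED_7)
        res = compute_index(cohort, hm, IndexKind.MEAN)
        if res.excluded:
            print(f"{seg.value:7s}: excluded ({res.exclusion_reason})")
            continue
        control, glaucoma = res.group_values(cohort)
        cut = choose_cutoff(control, glaucoma, segmentation=seg)
        results.append(cut)
        ind = cut.indices
        print(f"{seg.value:7s}: cutoff {cut.cutoff:7.2f} um | "
              f"Se {ind.sensitivity.value:5.2f}% "
              f"({ind.sensitivity.ci_low:.2f}-{ind.sensitivity.ci_high:.2f}) | "
              f"Sp {ind.specificity.value:5.2f}% "
              f"({ind.specificity.ci_low:.2f}-{ind.specificity.ci_high:.2f}) | "
              f"PPV {ind.ppv.value:5.2f}% | NPV {ind.npv.value:5.2f}%")
    out = args.results / "cutoff_diagnostics.csv"
    cutoff_table(results).to_csv(out, index=False)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
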