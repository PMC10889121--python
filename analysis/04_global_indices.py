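#!/usr/bin/env python
"""Global indices per layer and the two families of paired comparisons.

Computes the mean and AUROC-weighted indices over the selected cells of
every (segmentation, orientation), compares them with the paired DeLong
test within each grid, compares the tilted against the horizontalized
grid per layer (mean index), and ranks the layers by diagnostic ability,
flagging the excluded ones (no selectable cells or index AUROC < 0.70).
"""

import argparse
from pathlib import Path

import pandas as pd

from ppgrid.grid import GridOrientation, read_cohort
from ppgrid.heatmap import build_heatmap
from ppgrid.indices import (
    IndexKind,
    compare_mean_vs_weighted,
    compare_orientations,
    compute_index,
    index_table,
    layer_ranking,
)


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--results", type=Path, default=Path("results"))
    args = parser.parse_args()

    cohort = read_cohort(args.results / "cohort.csv")
    results = {}
    for seg in cohort.segmentations():
        for orient in cohort.orientations():
            hm = build_heatmap(cohort, seg, orient)
            for kind in IndexKind:
                results[(seg, orient, kind)] = compute_index(cohort, hm, kind)

    index_table(cohort, list(results.values())).to_csv(
        args.results / "global_indices.csv", index=False
    )

    kind_rows = []
    for seg in cohort.segmentations():
        for orient in cohort.orientations():
            m = results[(seg, orient, IndexKind.MEAN)]
            w = results[(seg, orient, IndexKind.WEIGHTED)]
            if m.excluded or w.excluded:
                continue
            cmp_ = compare_mean_vs_weighted(cohort, m, w)
            kind_rows.append({
                "segmentation": seg.value, "orientation": orient.value,
                "auc_mean": m.auroc.auc, "auc_weighted": w.auroc.auc,
                "z": cmp_.z, "p_value": cmp_.p_value,
            })
    pd.DataFrame(kind_rows).to_csv(
        args.results / "index_kind_comparison.csv", index=False
    )

    orient_rows = []
    print("tilted vs horizontalized grid (mean index, paired DeLong):")
    for seg in cohort.segmentations():
        t = results[(seg, GridOrientation.TILTED_7, IndexKind.MEAN)]
        h = results[(seg, GridOrientation.HORIZONTAL, IndexKind.MEAN)]
        if t.excluded or h.excluded:
            print(f"  {seg.value:7s}: excluded "
                  f"({t.exclusion_reason or h.exclusion_reason})")
            continue
        cmp_ = compare_orientations(cohort, t, h)
        orient_rows.append({
            "segmentation": seg.value,
            "auc_horizontal": h.auroc.auc,
            "ci_horizontal": f"{h.auroc.ci_low:.3f}-{h.auroc.ci_high:.3f}",
            "auc_tilted": t.auroc.auc,
            "ci_tilted": f"{t.auroc.ci_low:.3f}-{t.auroc.ci_high:.3f}",
            "z": cmp_.z, "p_value": cmp_.p_value,
        })
        verdict = "n.s." if cmp_.p_value > 0.05 else "significant"
        print(f"  {seg.value:7s}: tilted {t.auroc.auc:.3f} vs horizontal "
              f"{h.auroc.auc:.3f}, z = {cmp_.z:+.2f}, p = {cmp_.p_value:.3f} "
              f"({verdict})")
    pd.DataFrame(orient_rows).to_csv(
        args.results / "orientation_comparison.csv", index=False
    )

    ranked = layer_ranking([
        results[(seg, GridOrientation.TILTED_7, IndexKind.MEAN)]
        for seg in cohort.segmentations()
    ])
    rank_df = pd.DataFrame([
        {"rank": i + 1, "segmentation": e.segmentation.value,
         "auc": e.auc, "excluded": e.excluded, "reason": e.reason or ""}
        for i, e in enumerate(ranked)
    ])
    rank_df.to_csv(args.results / "layer_ranking.csv", index=False)
    order = " > ".join(
        e.segmentation.value for e in ranked if not e.excluded
    )
    excluded = ", ".join(e.segmentation.value for e in ranked if e.excluded)
    print(f"layer ranking (tilted grid, mean index): {order}")
    print(f"excluded layers: {excluded or 'none'}")


if __name__ == "__main__":
    main()
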