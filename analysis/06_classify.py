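#!/usr/bin/env python
"""Diagnostic classifiers on the measured cohort.

Three stages: (1) per-variable ROC curves with optimised cutoffs for each
group pair; (2) KNN on the six univariate features (age, CURV, IFA, DIST,
RATIO, CI) with data-driven K; (3) unsupervised hierarchical classification
(HCPC) on five features, confronted with the group labels in a confusion
matrix.  CURV dominates the univariate stage; the unsupervised clusters
recover controls and trigonocephaly well and confuse part of the
metopic-ridge group, whose age distribution is the widest.
"""

import argparse
import json
import pathlib
import sys

import pandas as pd

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from cranioshape.diagnostics import hcpc, knn_select_k, roc_with_cutoff  # noqa: E402
from cranioshape.pipeline import HCPC_FEATURES, KNN_FEATURES, ROC_VARIABLES  # noqa: E402


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--measures", default="results/measures")
    ap.add_argument("--out", default="results/classify")
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    mpath = pathlib.Path(args.measures) / "measures.csv"
    if not mpath.exists():
        raise SystemExit(f"missing {mpath}: run 03_measure.py first")
    measures = pd.read_csv(mpath)
    g = measures["group"].to_numpy()
    out = pathlib.Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    rows = []
    for var in ROC_VARIABLES:
        for a, b in (("MR", "TG"), ("MR", "C"), ("C", "TG")):
            sub = measures[measures["group"].isin([a, b])]
            r = roc_with_cutoff(sub[var].to_numpy(), sub["group"].to_numpy(),
                                positive=b)
            rows.append({"variable": var, "pair": f"{a}_vs_{b}", "auc": r.auc,
                         "sensitivity": r.sensitivity_at_cutoff,
                         "specificity": r.specificity_at_cutoff,
                         "cutoff": r.cutoff, "flipped": r.flipped})
    roc_tab = pd.DataFrame(rows)
    roc_tab.round(4).to_csv(out / "roc_table.csv", index=False)
    print("ROC (sensitivity/specificity at the optimised cutoff):")
    print(roc_tab.pivot(index="variable", columns="pair", values="auc")
          .round(3).to_string())

    knn = knn_select_k(measures[list(KNN_FEATURES)].to_numpy(), g,
                       seed=args.seed)
    print(f"KNN on {len(KNN_FEATURES)} features: K={knn.k}, "
          f"test accuracy {knn.accuracy:.3f}, recall {knn.per_class_recall}")
    knn.confusion.to_csv(out / "knn_confusion.csv")

    h = hcpc(measures[list(HCPC_FEATURES)].to_numpy(), truth=g,
             feature_names=list(HCPC_FEATURES), seed=args.seed)
    print(f"HCPC: {h.n_clusters} clusters; agreement per group "
          f"{ {k: round(v, 3) for k, v in h.confusion.per_class_agreement.items()} }")
    h.confusion.counts.to_csv(out / "hcpc_confusion.csv")
    h.axis_correlations.round(3).to_csv(out / "hcpc_axis_correlations.csv")
    with open(out / "classify_summary.json", "w") as fh:
        json.dump({"knn": {"k": knn.k, "accuracy": knn.accuracy,
                           "per_class_recall": knn.per_class_recall},
                   "hcpc": {"n_clusters": h.n_clusters,
                            "per_class_agreement": h.confusion.per_class_agreement,
                            "relative_inertia_ratio": h.relative_loss}},
                  fh, indent=1, default=str)
    print(f"wrote tables to {out}")


if __name__ == "__main__":
    main()
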