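#!/usr/bin/env python
"""Morphometric statistics on the measured cohort.

Reproduces the analysis tables: univariate permutation tests (group, age,
group-by-age) with pairwise comparisons for each descriptor, Spearman
correlations against age per group, the two-way ANOVA of age-residualised
intracranial volume on sex and group, orbital-shape GPA/PCA with a
permutation MANOVA, and within-group disparity.
"""

import argparse
import json
import pathlib
import sys
import warnings

import numpy as np
import pandas as pd

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from cranioshape.cohort import sample_cohort                    # noqa: E402
from cranioshape.stats import (age_residualize, disparity_analysis,  # noqa: E402
                               generalized_procrustes, icv_two_way_anova,
                               pairwise_perm, pca_with_threshold,
                               perm_manova, spearman_vs_age)

VARIABLES = ("CI", "CURV", "DIST", "ICV", "IFA", "RATIO")


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--measures", default="results/measures")
    ap.add_argument("--out", default="results/stats")
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-perm", type=int, default=999)
    args = ap.parse_args()

    mpath = pathlib.Path(args.measures) / "measures.csv"
    if not mpath.exists():
        raise SystemExit(f"missing {mpath}: run 03_measure.py first")
    measures = pd.read_csv(mpath)
    g = measures["group"].to_numpy()
    age = measures["age_days"].to_numpy()
    out = pathlib.Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    rows, pw_rows, sp_rows = [], [], []
    for var in VARIABLES:
        vals = measures[var].to_numpy()
        res = perm_manova(vals, g, age, n_perm=args.n_perm, seed=args.seed)
        for term, r in res.items():
            rows.append({"variable": var, "term": term, "df": r.df,
                         "F": r.F, "R2": r.R2, "p": r.p})
        for (a, b), p in pairwise_perm(vals, g, age, n_perm=args.n_perm,
                                       seed=args.seed).items():
            pw_rows.append({"variable": var, "pair": f"{a}_vs_{b}", "p": p})
        for grp in np.unique(g):
            s, rho, p = spearman_vs_age(vals[g == grp], age[g == grp])
            sp_rows.append({"variable": var, "group": grp, "S": s,
                            "rho": rho, "p": p})
    pd.DataFrame(rows).round(4).to_csv(out / "univariate_perm_tests.csv", index=False)
    pd.DataFrame(pw_rows).round(4).to_csv(out / "pairwise_tests.csv", index=False)
    pd.DataFrame(sp_rows).round(4).to_csv(out / "spearman_vs_age.csv", index=False)
    pw = pd.DataFrame(pw_rows)
    keep = pw[pw["variable"].isin(["CURV", "DIST", "IFA"])]
    print("pairwise p (CURV/DIST/IFA, age-residualised):")
    print(keep.pivot(index="variable", columns="pair", values="p").to_string())

    icv_resid = age_residualize(measures["ICV"].to_numpy(), age)
    anova = icv_two_way_anova(icv_resid, measures["sex"].to_numpy(), g)
    with open(out / "icv_anova.json", "w") as fh:
        json.dump(anova, fh, indent=1)
    print("ICV ~ sex * group (age-residualised):",
          {k: round(v["p"], 4) for k, v in anova.items() if k != "residual"})

    # orbital shape: GPA + PCA + permutation MANOVA + disparity
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        subjects, _ = sample_cohort(tuple(
            measures.groupby("group").size()[["TG", "MR", "C"]]), seed=args.seed)
    configs = [s.orbits.full_configuration() for s in subjects]
    aligned, _, _ = generalized_procrustes(configs)
    pca = pca_with_threshold(aligned.reshape(len(aligned), -1), 0.95)
    shape_res = perm_manova(pca.retained_scores, g, age,
                            n_perm=args.n_perm, seed=args.seed)
    print(f"orbital shape: {pca.n_retained} PCs (95% variance), "
          f"group p = {shape_res['group'].p:.4f}")
    disp = disparity_analysis(pca.retained_scores, g)
    pd.Series(disp.disparity).round(5).to_csv(out / "orbital_disparity.csv",
                                              header=["procrustes_variance"])
    with open(out / "orbital_manova.json", "w") as fh:
        json.dump({k: vars(v) for k, v in shape_res.items()}, fh, indent=1,
                  default=float)
    print(f"wrote tables to {out}")


if __name__ == "__main__":
    main()
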