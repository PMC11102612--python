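#!/usr/bin/env python
"""Draw the synthetic study cohort and record its composition.

Generates the three phenotype groups (trigonocephaly, metopic ridge,
controls) with the stock presets and writes the cohort metadata table.
Meshes/landmarks are regenerated deterministically from the seed by the
later scripts, so only the (small) metadata table is stored; pass
``--write-meshes DIR`` to also export STL/JSON/CSV per subject.
"""

import argparse
import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from cranioshape.cohort import DEFAULT_PRESETS, sample_cohort  # noqa: E402


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n", type=int, nargs=3, default=(30, 27, 30),
                    metavar=("TG", "MR", "C"))
    ap.add_argument("--out", default="results/cohort")
    ap.add_argument("--write-meshes", default=None)
    args = ap.parse_args()

    subjects, meta = sample_cohort(tuple(args.n), seed=args.seed,
                                   out_dir=args.write_meshes)
    out = pathlib.Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    meta.to_csv(out / "metadata.csv", index=False)
    print(f"cohort of {len(subjects)} subjects (seed {args.seed}):")
    print(meta.groupby("group")["age_days"].agg(["count", "mean", "std"]).round(1))
    print("girls fraction:",
          meta.groupby("group")["sex"].apply(lambda s: (s == "f").mean()).round(2).to_dict())
    print("presets differ in:", sorted(
        k for k in vars(DEFAULT_PRESETS["TG"])
        if getattr(DEFAULT_PRESETS["TG"], k) != getattr(DEFAULT_PRESETS["C"], k)))
    print(f"wrote {out / 'metadata.csv'}")


if __name__ == "__main__":
    main()
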