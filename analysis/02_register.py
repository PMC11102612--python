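#!/usr/bin/env python
"""Template registration demonstration: rigid landmark alignment + NICP.

Uses a noise-free control-preset vault as the template and registers one
subject per phenotype group to it, reporting the residual landmark RMS of
the rigid step and the mean surface distance after the non-rigid step.
The registered meshes share the template topology, which is what makes
dense (vertex-wise) shape statistics possible downstream.
"""

import argparse
import pathlib
import sys
from dataclasses import replace

import pandas as pd

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from cranioshape.cohort import DEFAULT_PRESETS, make_skull      # noqa: E402
from cranioshape.registration import (nicp_register,            # noqa: E402
                                      rigid_landmark_align)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", default="results/registration")
    ap.add_argument("--subdivisions", type=int, default=3,
                    help="mesh resolution for the demonstration")
    args = ap.parse_args()

    quiet = replace(DEFAULT_PRESETS["C"], vertex_noise_sd=0.0,
                    landmark_noise_sd=0.0, subdivisions=args.subdivisions)
    template = make_skull(quiet, 220.0, 0, subject_id="template")
    rows = []
    for grp in ("C", "MR", "TG"):
        preset = replace(DEFAULT_PRESETS[grp], subdivisions=args.subdivisions)
        subj = make_skull(preset, 250.0, args.seed + 17, subject_id=grp)
        tf = rigid_landmark_align(subj.landmarks, template.landmarks)
        aligned = tf.apply_mesh(subj.vault)
        deformed, info = nicp_register(template.vault, aligned)
        rows.append({"group": grp,
                     "rigid_rms_mm": tf.residual_rms,
                     "nicp_mean_distance_mm": info["mean_distance"],
                     "template_vertices": template.vault.n_vertices,
                     "output_vertices": deformed.n_vertices})
    tab = pd.DataFrame(rows)
    out = pathlib.Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    tab.to_csv(out / "registration_summary.csv", index=False)
    print(tab.round(4).to_string(index=False))
    print("every registered subject keeps the template topology "
          f"({template.vault.n_vertices} vertices)")


if __name__ == "__main__":
    main()
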