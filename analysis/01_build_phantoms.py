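"""Build the articulated spine phantoms and tabulate their ground truth.

Constructs the default nine-vertebra template (T11..L1), articulates it
through resting / flexion / extension before and after desmotomy, and
writes the exact per-space inter-DSP distances and per-phase totals to
results/phantom_ground_truth.csv.  Pass --export-meshes to also write one
STL per vertebra plus a JSON manifest under results/phantoms/.
"""

import argparse
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import numpy as np
import pandas as pd

from spinekin import synthetic_spine as ss


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--export-meshes", action="store_true")
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    template = ss.SpineTemplate()
    joints = ss.JointConfig()
    pose = ss.build_template(template)
    print(f"template: {template.n_vertebrae} vertebrae, "
          f"resting gap {template.resting_gap} mm, "
          f"T11->L1 chord {template.target_total_length} mm")

    rows = []
    for condition in ("pre", "post"):
        for phase in ("resting", "flexion", "extension"):
            articulated, gt = ss.articulate(pose, joints, phase, condition)
            rows.append(
                {
                    "condition": condition,
                    "phase": phase,
                    "mean_inter_dsp_mm": float(np.mean(gt.inter_dsp)),
                    "total_length_mm": gt.total_length,
                    **{f"space_{i+1}_mm": float(v) for i, v in enumerate(gt.inter_dsp)},
                }
            )
            if args.export_meshes:
                articulated.specimen = "template"
                ss.write_pose(articulated, args.out / "phantoms", ground_truth=gt)

    df = pd.DataFrame(rows)
    args.out.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.out / "phantom_ground_truth.csv", index=False)

    piv = df.set_index(["condition", "phase"])["mean_inter_dsp_mm"]
    rom_pre = abs(piv["pre", "flexion"] - piv["pre", "extension"])
    rom_post = abs(piv["post", "flexion"] - piv["post", "extension"])
    print(df[["condition", "phase", "mean_inter_dsp_mm", "total_length_mm"]]
          .round(2).to_string(index=False))
    print(f"mean per-space ROM: pre {rom_pre:.1f} mm, post {rom_post:.1f} mm "
          f"(desmotomy effect {rom_post - rom_pre:.1f} mm)")
    print(f"wrote {args.out / 'phantom_ground_truth.csv'}")


if __name__ == "__main__":
    main()
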