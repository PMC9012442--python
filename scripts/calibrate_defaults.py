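"""Calibrate the default joint amplitudes of the spine phantom.

Solves (by bisection on the default template) for:
  * a flexion amplitude whose mean per-space inter-DSP closure is half of
    the pre-desmotomy ROM (17.9 mm),
  * an extension amplitude whose mean opening is the other half,
  * an ISLD flexion multiplier that raises the mean per-space ROM from
    17.9 mm to 23.5 mm.

The resulting numbers are frozen as the JointConfig defaults in
``spinekin.synthetic_spine``; rerun this script to reproduce them.

Usage: python scripts/calibrate_defaults.py
"""

import numpy as np
from scipy.optimize import brentq

from spinekin import synthetic_spine as ss

ROM_PRE = 17.9  # mm, mean per-space dorsoventral ROM before desmotomy
ROM_POST = 23.5  # mm, after desmotomy at all 8 spaces


def main() -> None:
    pose = ss.build_template()
    resting = float(np.mean(ss.articulate(pose, ss.JointConfig(0, 0), "resting")[1].inter_dsp))

    def closure(theta: float) -> float:
        j = ss.JointConfig(flexion_amplitude_deg=theta, extension_amplitude_deg=0.0)
        gt = ss.articulate(pose, j, "flexion", "pre", check_interpenetration=False)[1]
        return resting - float(np.mean(gt.inter_dsp))

    def opening(theta: float) -> float:
        j = ss.JointConfig(flexion_amplitude_deg=0.0, extension_amplitude_deg=theta)
        gt = ss.articulate(pose, j, "extension", "pre", check_interpenetration=False)[1]
        return float(np.mean(gt.inter_dsp)) - resting

    half = ROM_PRE / 2.0
    theta_f = brentq(lambda t: closure(t) - half, 0.0, 20.0, xtol=1e-10)
    theta_e = brentq(lambda t: opening(t) - half, 0.0, 20.0, xtol=1e-10)

    def rom_post(mult: float) -> float:
        j = ss.JointConfig(theta_f, theta_e, isld_flexion_multiplier=mult)
        flex = ss.articulate(pose, j, "flexion", "post", check_interpenetration=False)[1]
        ext = ss.articulate(pose, j, "extension", "post", check_interpenetration=False)[1]
        return float(np.mean(np.abs(flex.inter_dsp - ext.inter_dsp)))

    mult = brentq(lambda m: rom_post(m) - ROM_POST, 1.0, 3.0, xtol=1e-10)

    print(f"DEFAULT_FLEXION_AMPLITUDE_DEG = {theta_f:.6f}")
    print(f"DEFAULT_EXTENSION_AMPLITUDE_DEG = {theta_e:.6f}")
    print(f"DEFAULT_ISLD_FLEXION_MULTIPLIER = {mult:.6f}")

    j = ss.JointConfig(theta_f, theta_e, isld_flexion_multiplier=mult)
    for cond in ("pre", "post"):
        flex = ss.articulate(pose, j, "flexion", cond)[1]
        ext = ss.articulate(pose, j, "extension", cond)[1]
        rom = float(np.mean(np.abs(flex.inter_dsp - ext.inter_dsp)))
        print(
            f"{cond}: flexion {np.mean(flex.inter_dsp):.2f} mm, "
            f"extension {np.mean(ext.inter_dsp):.2f} mm, mean ROM {rom:.3f} mm"
        )


if __name__ == "__main__":
    main()
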