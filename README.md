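# spinekin

In silico CT kinematics of the equine thoracolumbar spine around
interspinous ligament desmotomy (ISLD).

Impingement of the dorsal spinous processes (DSPs, "kissing spines") is the
most common source of back pain in horses. ISLD — surgical transection of
the interspinous ligament — relieves the pain, but its effect on spinal
*mobility* is measured post mortem: a T11–L1 segment is loaded into resting,
flexion and extension postures, CT-scanned before and after desmotomy of all
eight interspinous spaces, each vertebra is segmented, the phases are
rigidly superimposed on the T11 anchor, and mobility is quantified locally
(distances between adjacent DSP landmarks) and globally (excursion and
rotation of L1, the vertebra farthest from the anchor).

`spinekin` implements that entire measurement chain as tested code and, in
place of cadavers, provides articulated spine phantoms with exact
ground-truth kinematics, so every stage of the pipeline — CT emulation,
segmentation, registration, measurement, statistics — can be validated
end-to-end. It is an analysis project: the numbered scripts under
`analysis/` run the study; all computation lives in the `spinekin` package.

## The measurements

With +x cranial, +y left and +z dorsal, and per-vertebra craniodorsal
landmarks p₁…p₉ (the most craniodorsal vertex of each DSP — one repeatable
point per vertebra):

* inter-DSP distance per space *j*: d(j) = ‖p(j+1) − p(j)‖, and the total
  segment length ‖p₉ − p₁‖;
* per-space dorsoventral range of motion:
  ROM(j) = |d_flex(j) − d_ext(j)|, averaged over spaces and specimens;
* anchor superimposition: the rigid transform aligning each phase's T11
  onto the reference phase (ICP with Kabsch updates) is applied to all nine
  vertebrae of the phase, preserving within-phase relationships exactly;
* L1 motion between flexion and extension (composed through resting) is
  decomposed at the bone centroid into dorsoventral / craniocaudal /
  mediolateral translation magnitudes, the total rotation angle
  arccos((tr R − 1)/2), and the rotation attributable to the mediolateral
  axis; the symmetric Hausdorff distance between the two L1 surfaces is the
  "maximal excursion" reading;
* statistics: Shapiro–Wilk gates each paired pre/post comparison into a
  paired t-test (mean ± sd) or a Wilcoxon signed-rank test (median, range);
  vertebral-space effects use a two-way repeated-measures ANOVA
  (space × condition) with Tukey post-hocs; power is noncentral-t.

The phantom generator is calibrated so the template's mean per-space ROM is
17.9 mm before and 23.5 mm after desmotomy (desmotomy multiplies the
flexion amplitude only), with 39.9 mm resting spacing and a 310 mm T11–L1
chord; seven specimens per study are drawn around the template.

## Worked example

```sh
python analysis/01_build_phantoms.py      # phantom + exact ground truth
python analysis/02_image_and_segment.py   # CT emulation, segmentation accuracy
python analysis/03_run_study.py           # the full simulated study
python analysis/04_parameter_recovery.py  # effect recovery across studies
```

`analysis/03_run_study.py` (seed 1, CT at 2 mm) prints:

```
per-space ROM: 16.9 -> 22.2 mm (+5.3 mm, 31%), wilcoxon signed-rank p = 0.016
L1 excursion: dorsoventral +30.1 mm (3.2%/site), craniocaudal +22.7 mm (14.8%/site)
L1 mediolateral-axis rotation: +17.2 deg, p = 0.016
RM-ANOVA on resting inter-DSP spacing: space p = 8.6e-09, condition p = 0.67
```

Read: across the seven simulated specimens desmotomy raised the mean
per-space ROM by 5.3 mm (the generator's own value for this draw is
recovered to ~0.01 mm; the template effect is 5.6 mm), every global
mobility metric increased, resting spacing was unchanged by the (purely
flexion-phase) desmotomy effect, and the built-in spacing gradient shows up
as a strong vertebral-space effect. `analysis/04_parameter_recovery.py`
repeats the study twenty times and finds the 95% CI of the estimated ROM
increase, [5.52, 5.80] mm, covering the generating 5.6 mm.

Full tables (records, per-space ROM, effect summaries, tests, ANOVA,
Tukey) land in `results/study/`.

## Layout

```
src/spinekin/
  synthetic_spine.py   phantoms, articulation, ground truth, sampling
  volume_imaging.py    HU voxelization, NIfTI/MetaImage I/O
  segmentation.py      HU window -> labelled vertebrae -> smoothed surfaces
  registration.py      Kabsch, ICP, anchor superimposition
  kinematics.py        landmarks, distances, ROM, Hausdorff, motion split
  stats_report.py      gated paired tests, RM-ANOVA, power
  study.py             the end-to-end simulated study and its report
analysis/              numbered drivers (simulate, segment, study, recovery)
docs/methods.md        models, assumptions, parameter choices, limitations
```
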