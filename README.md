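# ctmaster

Master-protocol CT protocol management: measure patient size from localizer
radiographs, model AEC tube-current demand versus patient size, and
analytically create or customize CT protocols across image-quality levels and
scanner platforms — while guaranteeing the automatic exposure control (AEC)
stays inside the scanner's mA limits.

**Who it is for.** CT physicists and protocol-optimization teams who maintain
hundreds of clinical protocols across a multi-scanner install base and need a
systematic, auditable alternative to per-protocol trial and error.

## The model

A scanner's AEC modulates tube current (mA) along the patient to deliver a
requested noise level, but is bound by hard mA limits; an exam whose mA sits
at the ceiling or floor ("rail events") did not receive the intended image
quality. The package works from measured demand: per-image mA from axial
DICOM headers, patient size *s* = AP + LAT width (cm) from localizer
radiographs. Per-exam mA percentile statistics are fitted against size as

    mA_p10/median/p90(s) = a · e^(b·s)

and a size class's protocol mA range is read off the curves: the 90th
percentile curve at the class's upper size (100 cm for large adults) gives
`ma_max`, the 10th percentile curve at the lower size gives `ma_min`.

New protocols are derived analytically. A quality (CNR) change on the same
scanner scales the mA range by

    mA_new = mA_orig · (t_orig·P_new)/(t_new·P_orig) · (NI*_orig/NI*_new)² · F_kV · F_D

and the same protocol moved to a different scanner (equal image quality) by

    mA_new = mA_orig · (t_orig·P_new)/(t_new·P_orig) · F_kV · F_D · F_G

with *t* the rotation time, *P* the pitch, NI\* the noise index normalized to
a common slice thickness, and multiplicative factors
F_G = (SID_new/SID_orig)² (geometry), F_kV = noise_mA_factor / contrast_ratio²
(equal-CNR beam-energy change), F_D the equal-detectability dose ratio of an
iterative denoiser, plus an optional pass-through scanner-specific F_SS.
Scan duration for length *d* follows t_d = t·d/(P·N·T) for N detector rows of
z-thickness T. Candidate parameter choices are enumerated and ranked, with
any option whose scaled mA exceeds the target scanner's per-kV ceiling
flagged infeasible. Customized protocols are validated clinically by
comparing radiologist acceptance rates with a two-tailed Fisher exact test
(α = 0.005) against the reference scanner.

No clinical data ships with the package: a synthetic module generates
localizer phantoms, minimal DICOM series and exam populations with known
ground truth, so every stage is testable end to end.

## Worked example

Derive a trauma-grade protocol (NI 15.5 → 10, rotation 0.4 → 0.6 s) from the
routine abdomen–pelvis protocol (120 kV, 30–400 mA) on the built-in example
catalog:

```
$ ctmaster customize --protocol "routine abdomen-pelvis medium adult" \
      --mode within --t 0.6 --ni 10 --floor 50
routine abdomen-pelvis medium adult -> routine abdomen-pelvis medium adult (customized)
  scale factor: 1.6017
  mA range: 50-640 (kv 120, t 0.6, P 0.516, NI 10.0)
  feasible: True
```

The scale factor is (0.4/0.6)·(15.5/10)² = 1.60: the lower noise index asks
for 2.4× the tube output, partly paid for by the longer rotation. The scaled
ceiling 400·1.60 = 640.7 mA snaps to the 640 mA station and still fits under
the scanner's 800 mA limit at 120 kV, so the AEC keeps working over the whole
medium-adult size range; the floor is clamped to the 50 mA minimum-current
policy. The same command with `--mode cross --target-scanner "Optima 660"
--t 0.5 --floor 40` yields 40–320 mA — the slower-rotation platform needs
only 4/5 of the current for the same effective mAs.

The full synthetic pipeline (measure → stats → fit → limits → customize →
feasibility) runs from one config:

```
$ ctmaster fixtures --out demo --seed 3
$ ctmaster pipeline config.yaml
```

and reports, among other artifacts, the fitted growth rate b ≈ 0.055 /cm of
the generated population together with the derived size-class mA limits and a
box-whisker mA-vs-size plot.

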