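# protonrad

Analysis toolbox for **image-guided small-animal proton irradiation with
on-beam proton radiography**.  In this experimental setting, a live mouse is
imaged at the treatment beamline with a flat-panel detector (proton
radiography), the 2D treatment plan — a sagittal projection of a planning
volume with hippocampus/brain/background labels — is registered to the
radiograph through manually placed landmarks, and the motor-stage shift that
brings the target onto the beam isocenter is computed from a radiograph of
the irradiation collimator.  Afterwards, DNA double-strand-break staining
(gamma-H2AX against DAPI) is mapped tile-by-tile and correlated with the
delivered dose to verify the irradiation biologically.

`protonrad` implements the computational pieces of that workflow for
physicists and image analysts running such preclinical experiments:

* **Radiograph formation** — dark/beam background subtraction
  (`raw - I_dark - I_beam`) and salt-and-pepper-robust median stacking.
* **Image quality** — `SNR = S/sigma`, `CNR = (S_a - S_b)/sigma_b`
  (population sigma), edge-enhancement FWHM, Michelson line-pair
  resolution, and frame/time/dose detectability bookkeeping at the 8.4 Hz,
  0.05 mm-pitch detector geometry.
* **Planning agreement** — maximum-intensity and priority label
  projections, and observer agreement via Jaccard coefficients
  `J_i = |A_i ∩ F| / |A_i ∪ F|` against the majority-voted reference
  `F = majority(A_1, A_2, A_3)`.
* **Positioning** — Otsu/centroid beam-isocenter detection, closed-form
  least-squares similarity registration `x' = s R(θ) x + t` from landmark
  pairs, stage-coordinate output under named axis conventions, observer
  target-spread statistics, and the daily-QA steel-ball-shadow film check.
* **Damage mapping** — prominence-thresholded maxima detection (topographic
  prominence, 8-connectivity; thresholds 600 for DAPI, 1400 for gamma-H2AX),
  256-px tile maps of the damaged-cell fraction, alignment to a dose grid,
  and Pearson correlation of dose and damage profiles along the beam.
* **Physics helpers** — Bethe stopping powers, water-equivalent thickness
  (WET), and an analytic Bragg-curve stand-in for dose distributions.
* **Synthetic data** — generators for every input (phantoms, collimator and
  mouse radiographs, label volumes, nuclei image pairs, QA films) with
  machine-readable ground truth, so the whole pipeline is testable end to
  end without beam time.

## Worked example

Register a synthetic mouse radiograph to its plan and compute the stage
shift:

```python
import numpy as np
from protonrad import (
    AcquisitionParams, LandmarkPairs, correct_frames, detect_isocenter,
    fit_similarity, make_collimator_radiograph, make_mouse_pair,
    map_target, stack_median, stage_shift, wet_of_slab,
)

# range-shifter bookkeeping: 46.51 mm polycarbonate at 90 MeV
print(round(wet_of_slab(46.51, "polycarbonate", 90.0), 2))   # 53.16 (mm WET)

# synthetic mouse with a known plan->radiograph transform
data = make_mouse_pair(seed=7, true_transform=(1.0, 5.0, (10.0, -6.0)))
truth = data["ground_truth"].truth
radio = stack_median(correct_frames(
    data["radiograph_frames"], data["dark_frames"], data["beam_frames"]))

# beam isocenter from a collimator radiograph (3 mm aperture)
coll, _ = make_collimator_radiograph(
    (260.0, 250.0), 3.0, AcquisitionParams(n_frames=5, seed=7), shape_px=(512, 512))
iso = detect_isocenter(stack_median(coll))

# landmark registration and stage shift
pairs = LandmarkPairs(np.asarray(truth["plan_landmarks"]),
                      np.asarray(truth["radio_landmarks"]))
tr = fit_similarity(pairs)
target_radio = map_target(tr, truth["target_plan_px"])
shift = stage_shift(target_radio, iso, radio.pixel_pitch_mm)
print(iso.center, iso.radius_px)
print(tr.scale, tr.rotation_deg, tr.translation, tr.rms_residual_px)
print(shift.x_mm, shift.y_mm)
```

Output:

```
53.16
(260.01, 250.0) 30.1
1.000 5.00 (10.00, -6.00) 3.4e-14
3.018 2.064
```

Reading it: the polycarbonate range shifter is worth 53.16 mm of water at
90 MeV; the 3 mm collimator aperture is found at its true position with a
30 px (1.5 mm) radius; the landmark fit recovers the true transform (scale
1, rotation 5°, translation (10, −6) px) to machine precision; and the
target must be brought 3.018 mm in x and 2.064 mm in y onto the isocenter.

The same workflow is available from the shell:

```bash
protonrad simulate --scenario mouse --seed 7 --out sim/
protonrad simulate --scenario collimator --seed 7 --out coll/
protonrad register --plan sim/plan.tif --radio sim/radiograph.tif \
    --dark sim/dark.tif --beam sim/beam.tif --landmarks sim/landmarks.csv \
    --collimator coll/collimator.tif --target-row 235 --target-col 296 \
    --out register.json
protonrad qa --film film.tif --expected-row 150 --expected-col 150
```

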