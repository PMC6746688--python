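# mammometry

Landmark-based indirect breast anthropometry from calibrated 2-D
photographs. Given named pixel landmarks (sternal notch, umbilicus,
nipples, inframammary fold apices, upper pole apices, optional breast
borders) and an in-frame reference segment of known length (2 cm by
default), the package computes the thirteen standard linear breast
measurements, two aesthetic proportions (vertical upper:lower pole, ideal
45:55; horizontal lateral:medial, ideal 40:60), and the full
reliability/agreement statistics battery used to validate such tools
against direct tape-measure anthropometry.

Components:

- **`mammometry.geometry`** — calibrated pixel-to-cm scale, Euclidean
  distances, midline construction (sternal notch to umbilicus), orthogonal
  level projection onto the midline, perpendicular midline distances, and
  two-photo similarity binding (for ptotic subjects whose inframammary
  folds are only visible on a breasts-lifted second photo).
- **`mammometry.protocol`** — the 13-measurement panel and ratio set
  assembled from a landmark annotation, including the mixed-frame
  two-photo path (nipples from the relaxed photo, IMFA/UPA mapped in from
  the lifted photo).
- **`mammometry.stats`** — accuracy (MAD, SD of differences), ICC(2,1) /
  ICC(3,1) with exact F-based 95% CIs, SEM = SD·√(1−ICC), per-subject
  coefficients of variation, Bland–Altman limits of agreement,
  effectiveness against the 1-cm thoracic deviation bound, and
  Cicchetti / clinical interpretation bands.
- **`mammometry.synth`** — synthetic subjects (female/male presets,
  controllable asymmetry and ptosis), photo models (pixel density, camera
  roll, translation, optional perspective skew), observer click-noise
  models, and complete repeated-measures study generation.
- **`mammometry.annotation_io` / `overlay` / `report` / `cli`** — the
  versioned annotation JSON schema (shipped at
  `src/mammometry/data/annotation.schema.json`), deterministic SVG
  overlays, JSON/HTML reports, and the command-line interface.

## CLI

```sh
# measurement panel (CSV) and report for one annotated subject
mammometry measure subject.json --out out/ --report

# synthetic validation study: study.csv + example annotation files
echo '{"n_subjects": 10, "preset": "female"}' > config.json
mammometry simulate config.json --seed 7 --out study/

# reliability battery on a long-format study CSV
# (columns: subject_id, observer_id, session, measurement, value_cm[, reference_cm])
mammometry validate study/study.csv --tables out/ --bland-altman out/

# structured or printable report
mammometry report subject.json --format html --out report.html
```

All randomness is seed-controlled; identical invocations produce
identical outputs.

## Annotation file format

See `src/mammometry/data/annotation.schema.json`. Minimal example:

```json
{
  "schema_version": 1,
  "subject": {"id": "demo"},
  "photos": [{
    "photo_id": "front",
    "role": "primary",
    "calibration": {"endpoint_a": [100, 100], "endpoint_b": [170, 100], "known_length_cm": 2.0},
    "landmarks": {"SN": [600, 150], "UMB": [605, 800], "N_R": [420, 450], "N_L": [780, 460]}
  }]
}
```

Landmarks use image pixel coordinates (origin top-left, y down);
measurements whose landmarks are absent are simply omitted from the
panel. A second photo block with `"role": "secondary"` (breasts lifted)
is bound to the primary frame via the midline endpoints marked on both.
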