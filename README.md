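# tkvnet

Semi-automated **total kidney volume (TKV)** measurement from T2-weighted
abdominal MRI, aimed at autosomal dominant polycystic kidney disease
(ADPKD), where TKV is the standard imaging surrogate for disease severity
and progression. The package replaces slice-by-slice manual planimetry
with a learned pipeline:

1. read the DICOM series and its geometry tags (PixelSpacing,
   SliceThickness, SpacingBetweenSlices, Rows, Columns, orientation);
2. rasterize polygon annotations (Labelme-style JSON) of the left and
   right kidneys into binary training masks;
3. segment each slice with a **2D U-Net** (same-padding convolutions, He
   initialization, dropout 0.2 at the bottleneck, sigmoid head) trained
   with a soft **Dice loss** `1 − (2Σpt+ε)/(Σp+Σt+ε)` under Adam and a
   warm-up exponential-decay schedule, with fresh random augmentation
   (rotation ≤5°, shift ≤10%, zoom ≤10%, no flips) every epoch;
4. inpaint the predicted masks — threshold 128/255, hole-filling,
   despeckle — and split them into patient-left/right kidneys;
5. compute per-kidney planimetric volume
   `V = Σ_slices (pixel count × pixel area) × slice thickness` and
   `TKV = V_left + V_right`, plus a mid-slice comparator;
6. report agreement against a reference: Dice/Jaccard
   (`DSC = 2TP/(2TP+FP+FN)`, `J = D/(2−D)`), difference tables
   (mean ± sample SD), and Bland–Altman bias with 95% limits of
   agreement.

The network, its backpropagation, and the optimizer are implemented
directly on NumPy arrays; a built-in **phantom generator** (ellipsoidal
kidneys with optional cysts, known analytic volumes, full DICOM
round-trip) makes every stage testable without patient data. See
`docs/methods.md` for the model details and for what phantom results do
and do not demonstrate.

## Worked example

Agreement statistics on the bundled 10-subject example cohort (expert
planimetry vs automated pipeline, axial series):

```python
from tkvnet import agreement_table, bland_altman
from tkvnet.example_data import AXIAL_TKV_PAIRS

rows, s = agreement_table(AXIAL_TKV_PAIRS)
print(f"n={s.n}  truth {s.mean_truth:.1f} ± {s.sd_truth:.1f} mL  "
      f"pred {s.mean_pred:.1f} ± {s.sd_pred:.1f} mL")
print(f"difference {s.mean_diff:.2f} ± {s.sd_diff:.2f} mL "
      f"({s.mean_diff_pct:.2f} ± {s.sd_diff_pct:.2f} %)")
ba = bland_altman(AXIAL_TKV_PAIRS)
print(f"Bland–Altman bias {ba.bias:.2f}%  LoA [{ba.loa_lower:.2f}, {ba.loa_upper:.2f}]")
```

prints

```
n=10  truth 1501.8 ± 965.8 mL  pred 1536.3 ± 958.7 mL
difference 44.23 ± 58.69 mL (3.95 ± 4.37 %)
Bland–Altman bias 3.44%  LoA [-5.31, 12.18]
```

i.e. the automated measurement differs from the expert reference by
44 mL (4%) on average over these ten subjects, with a +3.4% relative
bias (pairwise-mean denominator) and 95% of differences expected between
−5.3% and +12.2%.

The same workflow from the shell, on synthetic data end to end:

```sh
tkvnet simulate --out cases --seed 7            # phantom DICOM + annotations + truth CSV
tkvnet train    --case-dir cases/phantom-7 --out run \
                --size 64 --depth 2 --base-filters 8 --epochs 50
tkvnet measure  --checkpoint run/model.npz --series cases/phantom-7/dicom \
                --out volumes.csv
tkvnet evaluate --truth truth.csv --pred pred.csv --out report
```

`measure` prints one JSON row per series, e.g.
`{"subject_id": "phantom-7", "method": "planimetric", "orientation":
"axial", "left_ml": 244.2, "right_ml": 246.1, "total_ml": 490.3}`,
to be compared with the phantom's `ground_truth.csv`.

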