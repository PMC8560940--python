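# gmaxff

Automated quantification of intramuscular fat in the gluteus maximus (GMAX)
from Dixon MRI, with the cohort statistics used to relate fat infiltration to
physical activity, hip pain, sex, BMI and age.

Intramuscular fat (IMF) is a marker of muscle health: it rises with
inactivity, ageing and hip pathology. Dixon MRI separates water and fat
signal per voxel, so the voxelwise **fat fraction**

```
FF = F / (W + F)
```

(F = fat image, W = water image) measures IMF quantitatively. `gmaxff`
averages FF over a 3D muscle label restricted to the **muscle bulk** — the
axial slab from the slice containing the lesser-trochanter (LT) tip up to the
slice at the anterior superior iliac spine (ASIS), both included — and also
reports muscle volume, lean volume `V · (1 − FF)`, and volumes normalized by
lean body mass (Boer formula, e.g. `LBM = 0.407·W + 0.267·H − 19.2` kg for
men with weight W in kg and height H in cm).

The package is aimed at researchers studying hip-muscle health who have
co-registered water/fat volumes, muscle labels and bone landmarks — plus
anyone who wants to validate such a pipeline end to end, since `gmaxff` ships
a synthetic Dixon phantom generator with exact ground truth.

## What's inside

| module | contents |
| --- | --- |
| `gmaxff.io` | NIfTI volume/label readers with strict geometry checks, landmark JSON (voxel or world-mm), metadata CSV |
| `gmaxff.quant` | FF map, bulk extraction, per-muscle metrics, Boer LBM, activity grouping (<4 / 4–8 / >8 h per week), Oxford Hip Score grading |
| `gmaxff.synthetic` | Dixon phantoms (ellipsoid muscles, constant / gradient / textured FF fields, Gaussian or Rician channel noise) and tabular cohorts with known generating coefficients |
| `gmaxff.stats` | descriptive tables, Shapiro–Wilk, Kruskal–Wallis (exact for tiny n), rank-based Tukey HSD, Wilcoxon signed-rank (exact, ties allowed), Q3 + 1.5·IQR outlier rule, hierarchical linear regression with a sequential ΔR² retention rule, logistic models with Wald CIs, power/sample-size calculators |
| `gmaxff.pipeline` / `gmaxff.cli` | `simulate`, `quantify-subject`, `run-cohort`, `stats` with config echo and seeded reproducibility |

## Worked example

Quantify a synthetic subject whose true fat fractions are known (26% left,
23% right, with per-channel Gaussian noise at 2% of proton density):

```python
from gmaxff.synthetic import PhantomSpec, FFField, generate_phantom
from gmaxff import pipeline

spec = PhantomSpec(
    ff_left=FFField(kind="constant", p=0.26),
    ff_right=FFField(kind="constant", p=0.23),
    noise_kind="gaussian", noise_sd=2.0, seed=7,
)
study, labels, landmarks, truth = generate_phantom(spec)
record = pipeline.quantify_subject(
    study, labels, landmarks,
    {"subject_id": "demo", "sex": "female", "weight_kg": 68.0,
     "height_cm": 166.0, "age_years": 52.0, "group": "Pain",
     "ohs_score": 24, "pain_side": "left"},
)
```

prints (via the obvious f-strings):

```
left  FF = 25.99%  (truth 26.00%)
right FF = 22.97%  (truth 23.00%)
side-mean FF = 24.48%
left bulk volume = 7.82 ml, lean = 5.79 ml
LBM (Boer) = 47.35 kg
normalized lean volume (left) = 0.1223 ml/kg
OHS grade = 2
```

The estimated FF sits within a few hundredths of a percentage point of the
truth because ~18 000 bulk voxels are averaged; the lean volume is
`7.82 × (1 − 0.2599)` ml; OHS 24 grades as Moderate (2).

A full cohort run from the shell:

```bash
gmaxff simulate --seed 1 --out sim/          # 70 subjects, 4 groups, with truth files
gmaxff run-cohort --cohort-dir sim/ --seed 1 --out report/
```

`report/` then contains the cohort table plus descriptive, omnibus/post-hoc,
left-right pairing, hierarchical-regression and odds-ratio tables as CSV,
with the run configuration and seeds echoed alongside.

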