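# cbcthm — CBCT Hounsfield-unit correction by deformable registration and histogram matching

Cone-beam CT (CBCT) volumes acquired on the treatment machine carry large
Hounsfield-unit (HU) errors — a global bias, smooth shading/cupping from
scattered radiation, and elevated noise — which makes them unreliable for
dose calculation in adaptive radiotherapy. A well-established remedy maps
the planning CT (pCT) onto the daily CBCT anatomy and then corrects the
CBCT intensities by cumulative-histogram matching against that deformed
pCT. The quality of the correction hinges on the deformable registration
(DR) feeding it, so this package implements the whole workflow with three
interchangeable similarity metrics and the evaluation suite needed to
compare them:

1. **Preprocessing** — automatic body-mask extraction (threshold −700 HU
   for pCT, −600 HU for CBCT; morphological closing, largest component,
   hole filling) and −1000 HU exterior fill.
2. **Rigid pre-alignment** — 6-DOF transform maximizing mutual information
   (MI).
3. **Deformable registration** — 3-level multi-resolution cubic B-spline
   free-form deformation optimized by adaptive stochastic gradient descent
   (ASGD) under one of

   - NCC: `Σ(I_F−Ī_F)(I_M(T(x))−Ī_M) / √(Σ(I_F−Ī_F)² Σ(I_M(T(x))−Ī_M)²)`
   - MI: `H(I_F) + H(I_M) − H(I_F, I_M)` (Parzen-windowed joint histogram)
   - NMI: `(H(I_F) + H(I_M)) / H(I_F, I_M)`

4. **Histogram matching (HM)** — each CBCT value is replaced by the
   deformed-pCT value of equal cumulative probability, computed inside the
   body mask as a monotone piecewise-linear lookup table.
5. **Evaluation** — `V_err = √(mean[(HU_pCT − HU_CBCT)²])`, mean absolute
   error in 20-HU bins of the reference HU (annotated with the tissue
   classes air < −400 ≤ soft tissue < 250 ≤ soft bone ≤ 600 < bone), and
   spatial-uniformity RMSD over 10×10-pixel same-tissue ROIs.

Because no patient data ship with the package, a parametric **pelvis
phantom** generates paired pCT/CBCT volumes with known ground truth: tissue
label map, B-spline deformation between the two time points, and the exact
artifact fields. The four-arm comparison (rigid-only `RR-MI` vs `DR-NCC`,
`DR-MI`, `DR-NMI`) runs end to end on phantom cohorts.

## Worked example

```python
import cbcthm as c

model = c.CbctCorrectionModel.from_phantom(
    spec=c.PhantomSpec(seed=123), config=c.PipelineConfig(seed=5)
)
results = model.fit(algorithms=("RR-MI", "DR-NCC"))
print(results.summary())
```

prints

```
CBCT Correction Results
==============================================
algorithm  V_err before HM [HU]  V_err after HM [HU]
    RR-MI                 94.97                78.65
   DR-NCC                 70.69                21.72
```

Reading: before any correction the rigid-only arm leaves a root-mean-square
HU error of ≈95 HU between the (rigidly) aligned pCT and the CBCT, and
histogram matching on that misaligned pair only brings it to ≈79 HU.
Deformable registration first reduces the residual anatomical mismatch
(70.7 HU, mostly the simulated −60 HU bias plus noise), and matching against
the *deformed* pCT then removes the intensity distortion almost entirely
(21.7 HU). The corresponding ROI uniformity RMSD for this phantom drops from
≈55 HU (fat) and ≈63 HU (muscle) to 3.3 and 4.6 HU:

```python
report = results.report("DR-NCC")
print(report.rmsd_before, report.rmsd_after)
```

A command-line interface mirrors the library
(`cbcthm generate / preprocess / register / histmatch / evaluate / run`),
e.g. a full phantom cohort:

```bash
cbcthm run --phantom --subjects 5 --algos rr-mi,dr-ncc,dr-mi,dr-nmi \
    --seed 1 --out scratch/cohort
```

## Layout

```
src/cbcthm/
  image.py         volumes, labels, ROIs, NIfTI/MetaImage I/O
  transforms.py    rigid / B-spline / composite spatial transforms
  phantom.py       synthetic pCT/CBCT pair generator with ground truth
  preprocess.py    body mask + background standardization
  metrics.py       NCC / MI / NMI and analytic gradients
  registration.py  pyramid, ASGD, rigid and B-spline stages, resampling
  histmatch.py     cumulative-histogram matching
  evaluation.py    V_err, binned MAE, ROI uniformity, reports
  pipeline.py      four-arm pair and cohort orchestration
  models.py        Model/Results API (RegistrationModel, CbctCorrectionModel)
  cli.py           command-line interface
```

See `docs/methods.md` for the modelling assumptions, parameter defaults and
known limitations.
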