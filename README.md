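# icv-sparse

Intracranial volume (ICV) estimation from sparse, linearly spaced
cross-sectional areas — and a toolkit for quantifying how valid such
estimates are.

## The problem

ICV is the standard proxy for premorbid brain size in volumetric
neuroimaging studies. Segmenting the whole intracranial vault on a
high-resolution MRI by hand takes hours per scan, so practitioners
commonly trace only a few linearly spaced intracranial areas (ICAs) and
interpolate. How much validity is lost depends on three choices this
package lets you study systematically: the spacing *n* between traced
slices, the slicing orientation (sagittal, coronal, transversal), and the
interpolation method.

Given areas A₀, A₁, … sampled every *n* mm, the three estimators are

* **piecewise constant** (Cavalieri rectangle rule): V̂ = n · Σᵢ Aᵢ
* **piecewise linear**: trapezoidal integral through the sampled areas
  plus a zero area appended one slice beyond each end of the vault
* **cubic spline**: exact integral (piecewise-polynomial
  antiderivative, no quadrature error) of the not-a-knot cubic spline
  through the same zero-padded points

For spacing *n* there are exactly *n* possible estimates per subject
(one per sampling offset), so a cohort of *m* subjects admits *n*ᵐ
combinations of estimates. Validity is assessed Monte-Carlo style: draw
one offset per subject uniformly, score the resulting estimate vector
against the true volumes — ICC(A,1) (two-way ANOVA, single measures,
absolute agreement), Pearson correlation, generalized Jaccard index
Σ min(xᵢ,yᵢ)/Σ max(xᵢ,yᵢ), and signed percentage errors — and repeat
2000 times to obtain percentile curves per (spacing, orientation,
method). A paired t-test on per-subject mean absolute percentage errors
contrasts the constant and spline interpolators.

Because segmented MRI cohorts cannot ship with a package, a calibrated
phantom generator produces synthetic cohorts (default: 62 subjects,
39 female / 23 male, gender-specific ICV distributions, sagittal extent
136 ± 5 slices, smooth sagittal/coronal but irregular transversal
profiles) on which the entire pipeline runs end to end.

## Worked example

```python
import icv_sparse as icv

cohort = icv.generate_cohort(icv.PopulationSpec(seed=42))
subj = cohort[0]                      # true ICV: 1 444 891 mm³
for method in icv.METHODS:
    est = icv.estimate(subj.profiles["sagittal"], 10, 0, method)
    print(method, est.value)

report = icv.evaluate(cohort, spacings=[10, 50],
                      orientations=("sagittal",), count=2000, seed=7)
```

At 10 mm spacing the three methods are nearly indistinguishable for this
subject (constant −0.41 %, linear −0.56 %, spline −0.24 % error). At the
cohort level the sweep prints the familiar pattern — interpolation
barely matters at small spacing but dominates at coarse spacing:

```
spacing 10   constant: median ICC 0.9999, median |err| 0.13 %
spacing 10     linear: median ICC 0.9991, median |err| 0.44 %
spacing 10     spline: median ICC 1.0000, median |err| 0.05 %
spacing 50   constant: median ICC 0.9226, median |err| 4.05 %
spacing 50     linear: median ICC 0.6318, median |err| 10.69 %
spacing 50     spline: median ICC 0.9949, median |err| 0.50 %
```

The piecewise linear interpolant systematically underestimates (chords
under a concave profile), which absolute-agreement ICC punishes even
while Pearson correlation stays high; the spline keeps median errors
near 0.5 % even when only three or four slices per subject are traced.
The paired comparison quantifies the spline's advantage:

```python
rec = icv.compare_interpolators(cohort, 50, "sagittal")
# constant − spline MAPE: +3.13 pct points (95% CI 2.91..3.35, p = 8.4e-37)
```

The same operations are available from a shell:

```bash
icv-sparse simulate --out cohort/ --seed 42
icv-sparse estimate --profile cohort/f001_sagittal.csv --spacing 10 --method spline
icv-sparse evaluate --cohort cohort/ --spacings 2:50 --combinations 2000 \
                    --seed 7 --out report/ --plots
```

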