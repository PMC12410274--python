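# afield

Attention-field modeling of population receptive field (pRF) attraction.

## The problem

Voluntary spatial attention attracts visual receptive fields toward the
attended location, and the *precision* of attention — how tightly it is
focused — controls how strong that attraction is.  `afield` is a
research toolkit for studying this mechanism end to end with fMRI-style
measurements: it simulates bar-sweep retinotopy experiments performed
under focused vs. distributed attention, fits pRFs and task-response
betas to the resulting BOLD series, computes eccentricity-binned
condition differences, and fits Gaussian attention-field models that
explain the differences.  It is aimed at visual neuroscientists who
want a fully synthetic, ground-truth-controlled replica of this class
of experiment — every stage of the analysis can be validated against
known generating parameters before being pointed at real data.

## The model

The attention field (AF) is a Gaussian gain field A(μ₁, σ₁) centered on
the attended location; a stimulus-driven pRF is a Gaussian S(μ₂, σ₂).
Multiplying them yields the measurable attention-driven pRF R(μ₃, σ₃):

    μ₃ = (μ₁σ₂² + μ₂σ₁²) / (σ₂² + σ₁²),   σ₃² = σ₁²σ₂² / (σ₁² + σ₂²)

so narrower attention (smaller σ₁) and larger pRFs (larger σ₂) both
increase attraction toward the attended locus.  The offset variant
(**AF+**) multiplies by `a·A + b` instead: the constant b bounds
attentional influence, so pRFs far from the attended locus are left
almost unchanged — small-pRF areas then show attraction differences
only near the locus, while large-pRF areas show them across the whole
eccentricity range.  The AF+ product is fit numerically with a Gaussian
to estimate μ₃ and σ₃; only centers and sizes feed the analyses.

## Worked example

Predict distributed-minus-focused eccentricity-difference curves for
three visual areas and recover the generating fields from them:

```python
import numpy as np
from afield import (AFParams, SizeEccRelation,
                    predict_difference_curve, fit_af_to_differences)

relations = {"V1":  SizeEccRelation(0.12, 0.25, "V1"),
             "hV4": SizeEccRelation(0.35, 0.55, "hV4"),
             "IPS": SizeEccRelation(0.75, 1.00, "IPS")}
ecc = np.array([0.2, 0.6, 1.2, 2.2, 3.5, 4.6])
focused = AFParams(sd=0.5, offset=0.1)      # precise attention
distributed = AFParams(sd=5.0, offset=0.1)  # attention across the display

curves = {roi: (ecc, predict_difference_curve(focused, distributed, rel, ecc))
          for roi, rel in relations.items()}
for roi, (_, d) in curves.items():
    print(roi, np.round(d, 3))

fit = fit_af_to_differences(curves, relations, variant="af_plus")
print(f"focused sd {fit.focused.sd:.3f}  distributed sd {fit.distributed.sd:.3f}")
```

```
V1 [ 0.042  0.152  0.299  0.005 -0.055 -0.1  ]
hV4 [0.11  0.379 0.846 1.654 0.897 0.243]
IPS [0.153 0.478 0.962 1.66  2.316 2.673]
focused sd 0.500  distributed sd 5.000
```

(The AF+ refit takes about a minute: each candidate field pair is
pushed through the numeric interaction at every eccentricity.)

Reading the curves: focused attention pulls pRFs toward fixation more
than distributed attention does, so the difference is positive.  In V1,
whose pRFs are small, the effect lives near the attended locus and dies
off (slightly undershooting zero) by mid-periphery; in IPS, whose pRFs
are large enough to overlap the attention field from anywhere, it
grows across the whole range.  The fit recovers the generating field
widths from the curves alone.

The behavioral side, from the shell:

```bash
$ afield behavior --n-trials 10000 --n-perm 500 --seed 7
{
  "n_trials": 10000,
  "target_fraction": 0.0834,
  "dprime": 2.6662102781831125,
  "null_mean": -0.007819679425896989,
  "p_value": 0.001996007984031936
}
```

A simulated observer at the study's operating point (d′ = 2.7, targets
on ~1 trial in 12) is recovered at d′ ≈ 2.67; the label-permutation
null is centered on zero and the observed sensitivity exceeds all 500
permutations.

Other subcommands: `afield simulate` (write a synthetic participant's
ground truth and three-condition BOLD series), `afield fit-prf` /
`afield fit-glm` (invert stored series), `afield analyze` (binning,
exponential fits with bootstrap bands, Wilcoxon + FDR), `afield af-fit`
(fit field pairs to difference-curve tables).

The full synthetic pipeline — sample populations, displace pRFs with
known fields, simulate BOLD, fit, filter, bin, and refit the fields —
is one call:

```python
from afield import RecoveryConfig, run_recovery
result = run_recovery(RecoveryConfig(n_participants=5, n_voxels=500,
                                     noise_sd=0.2, seed=11))
print(result.af_fit.focused.sd, result.af_fit.distributed.sd)
```

which recovers the generating widths (0.5, 5.0) to about 10% at this
noise level (several minutes of compute; `docs/methods.md` details the
problem sizes and estimator choices).

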