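# pose2thal

Robust 3D pose reconstruction for freely moving mice and a statistical
suite linking posture and movement to spiking in the visual thalamus
(dLGN).

Head-fixed preparations conflate locomotion with arousal and hide most of
a mouse's postural repertoire. In freely moving animals the question of
*which* aspects of behavior drive early visual-system activity needs (i) a
pose estimate robust to occlusion-induced outliers in multi-camera
tracking and (ii) estimators that can say, per neuron, whether firing is
coupled to a posture, to a movement, or to both. This package implements
that computation end to end for anyone analyzing multi-view landmark
tracks paired with sorted spike trains — and ships a synthetic-session
generator so the whole pipeline is testable without any recordings.

## The model

A **statistical shape model** (SSM) describes the 11-landmark body as

    X = (X̄ + Σᵢ bᵢ Pᵢ) R + T

with mean pose X̄, orthonormal eigenposes Pᵢ (variances λᵢ, residual noise
σ²) learned by generalized Procrustes alignment (scale = 1) followed by
probabilistic PCA. Per frame, landmarks are DLT-triangulated from the
cameras and the pose is fit by minimizing

    C(b, R, T) = σ⁻² ‖X − (X̄ + Σᵢ bᵢ Pᵢ) R − T‖²_F + α Σᵢ bᵢ²/λᵢ ,  α = 0.01

alternating a closed-form rigid alignment for (R, T) with a closed-form
ridge solve for b. Frames with C above a χ² quantile enter an outlier
loop — drop the worst landmark, refit, retest — and the final pose is
re-synthesized from the model, filling occlusions.

From the corrected poses come 14 behavioral state variables: six postures
(head elevation Hel, head left/right Hlr, body arch Bar, body left/right
Blr, body lunge Blu, rearing Re), their temporal derivatives, locomotion
Lc and overall motion OM, all z-scored. Coupling to spiking is then
quantified by:

* **cross-correlograms** (±2 s, 0.0667 s bins) with an epoch-permutation
  null (1000 permutations, [0.0005, 0.9995] band);
* **magnitude-squared coherence** with a circular-shift null (100 shifts);
* **mutual information** MI = H(R) − H(R|S) on quantile-discretized
  variables (0.67 s count bins), bias-corrected by quadratic extrapolation
  over data fractions {1, ½, ¼};
* **encoding/decoding** with gradient-boosted trees (learning rate 0.025,
  500 rounds, depth 3, γ = 1; Poisson loss for counts) on a half split,
  with a half-swap shift control;
* **unit typing**: each unit's z-scored Bar × OM firing-rate histogram is
  a node in a Spearman-correlation graph thresholded at the median;
  Newman leading-eigenvector modularity bisection splits the population
  into "look-up" and "look-down" communities;
* **condition comparison**: per-unit Pearson correlation ρcc between
  cross-correlograms in two conditions against a 10,000-shuffle
  re-pairing null.

## Worked example

Run the full pipeline on a simulated 3-minute session with 10 tuned units
(half look-up, half look-down, all motion-excited):

```bash
pose2thal run-all --seed 7 --out run/
```

or equivalently from Python:

```python
from pose2thal.pipeline import PipelineConfig, run_pipeline
summary = run_pipeline(PipelineConfig(out_dir="run", seed=7,
                                      duration_s=180.0, n_units=10))
```

`run/coupling.csv` then contains (abridged):

```
unit  cc_peak_Bar  cc_sig_Bar  cc_peak_OM  cc_sig_OM  mi2_bits  encode_acc  encode_shift_acc
u000        0.198        True       0.410       True     0.651       0.677             0.011
u001       -0.121        True       0.341       True     0.485       0.656            -0.023
u002        0.186        True       0.437       True     0.550       0.786             0.067
u003       -0.122        True       0.359       True     0.319       0.756             0.053
...
```

Units with a positive up/down coefficient show positive body-arch
cross-correlation peaks (u000, u002, ...), the look-down units negative
peaks; every unit is positively coupled to overall motion; boosted-tree
encoding from (Bar, OM) reaches r ≈ 0.7 held out while the shift control
sits at ≈ 0. `run/labels.csv` reports the community partition — here two
communities (modularity Q = 0.41) labeling all ten units correctly as
look-up/look-down — and `run/mi_matrix.csv` + `run/dendrogram.json` hold
the variable-grouping analysis whose top split separates postures from
movements.

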