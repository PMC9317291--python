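# tilscape

Spatial heterogeneity of tumor-infiltrating lymphocytes (TILs) on patch-level
TIL maps, and what it buys you as a survival predictor.

## The problem

Deep-learning classifiers turn a whole-slide H&E image into a *TIL map*: a
grid in which every cell summarises one 50×50-pixel tile, either as a binary
TIL call (0/1) or as a TIL probability (0 for negative tiles, a value in
[0.5, 1] for positive ones).  The *fraction* of TIL-positive tiles is an
established but blunt prognostic signal — two patients with identical TIL
percentages can have very different immune architectures (diffuse infiltrate
versus dense peritumoral aggregates), and that architecture carries prognostic
information of its own.

`tilscape` is a library for people who want to quantify that architecture and
test whether it predicts outcome: computational pathology researchers working
with public TIL maps, and methodologists who need a controlled synthetic
test-bed with known ground truth.  It implements the whole chain:

1. **Synthetic data** — TIL maps with planted tissue fragments, line
   artifacts, background speckle and CSR-versus-clustered (Matérn-style)
   TIL placement on both map scales; survival cohorts drawn from a Weibull
   proportional-hazards model whose hazard depends on a chosen measure.
2. **Preprocessing** — artifact-line detection (a row/column whose
   TIL-positive count exceeds the mean of its neighbours by more than 20% of
   the line length) and deletion; connected-component splitting of the
   TIL-positive mask into regions of interest (ROIs) after a 3×3 closing;
   removal of components below 10% of the slide's TIL area; tight cropping.
   Maps under 10,000 patches are excluded up front.
3. **Fourteen spatial measures + %TIL per ROI** — Ripley's F, G and L at
   radius r = 50 (L(r) = √(K(r)/π), K(r) = A·#{pairs ≤ r}/(n(n−1)));
   Moran's I over a k-NN graph (k = 6),
   I = (n/S₀)·Σᵢⱼ wᵢⱼ zᵢ zⱼ / Σᵢ zᵢ²;
   group degree/closeness centrality and average clustering of the TIL node
   set; affinity-propagation clustering of TIL coordinates with the
   Ball–Hall, Banfeld–Raftery, C-index and determinant-ratio validity
   indices; 8-level GLCM texture sums M1/M2; spatial chaos (mean
   nearest-neighbour distance among detected edge pixels); and the TIL
   fraction.  NA and ±∞ are legitimate outputs and are preserved.
4. **Cohort screens** — unweighted per-patient averaging over ROIs, the
   robust coefficient of variation |MAD/median| across ROIs (reproducibility)
   and across patients (variation), Spearman/Pearson agreement between the
   binary and probability map scales, and a configurable screen that drops
   measures with no patient-level signal or wild ROI-to-ROI swings.
5. **Survival evaluation** — per measure and cancer, 16 scenarios
   ({OS, PFI} × {original, age-only | adjusted, +%TIL} × {continuous,
   discretized} × {binary, probability}); min-max scaling; minimum-p-value
   dichotomization over 30 candidate thresholds between the 10th and 90th
   percentile; ridge-penalized Cox fits (penalty 0.1); Harrell's-C ranking
   of measures; Kaplan–Meier curves with log-rank tests.

## Worked example

`examples/04_survival_scenarios.py` builds a 300-patient cohort whose hazard
triples above the midpoint of one scaled measure, then runs the cutpoint
search and the scenario grid:

```
true cutpoint 0.50 -> recovered 0.502 (min p = 6.92e-07, 30 candidates)

scenario grid (binary map scale):
endpoint    model measure_scale  hazard_ratio  p_value  c_index
      OS original    continuous        2.5838   0.0001   0.5923
      OS original   discretized        2.0137   0.0000   0.6161
      OS adjusted    continuous        2.4892   0.0002   0.5926
      OS adjusted   discretized        1.9922   0.0000   0.6180
     PFI original    continuous        5.5244   0.0000   0.6450
     PFI original   discretized        2.7239   0.0000   0.6263
     PFI adjusted    continuous        5.5552   0.0000   0.6452
     PFI adjusted   discretized        2.7240   0.0000   0.6385

log-rank p between min-p groups: 6.49e-08
```

The minimum-p search lands one grid step from the planted cutpoint, the
discretized scenarios beat the continuous ones on concordance for OS (the
planted effect really is a step), and adding %TIL as a covariate barely moves
the hazard ratio because the driver measure is independent of %TIL here.
The other example scripts cover map simulation + preprocessing
(`01`), the measure families on clustered versus random patterns (`02`) and
the patient-level screens (`03`); each prints what it computes and says what
the numbers mean.

There is also a thin CLI mirroring the stages
(`tilscape simulate | preprocess | measure | cohort | survive | all`), and
adapters in `tilscape.io` for the public TIL-map repository layout and the
TCGA pan-cancer clinical file if you have downloaded them (nothing is
downloaded for you).

## Layout

```
src/tilscape/     types, synthetic, preprocess, graphs, measures,
                  cohort, survival, pipeline, io, plots, cli
examples/         four narrative scripts, one per capability
tests/            pytest suite with independent brute-force oracles
docs/methods.md   models, parameter choices, numerical decisions, limitations
```
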