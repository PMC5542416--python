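# megrsa — time-resolved MEG decoding and representational similarity analysis

`megrsa` implements, as a tested and reusable pipeline, the analysis chain
used to ask **when** abstract scene properties — the physical size of a
depicted space, its clutter level — become readable from MEG sensor
patterns, and **which** computational models of vision share that
representation. It is written for researchers doing time-resolved
multivariate pattern analysis (MVPA/RSA) of M/EEG data who want each stage
of such a pipeline as an importable, validated function, and it ships a
synthetic-data generator with known ground truth so every stage can be
verified by parameter recovery instead of trusting plots.

## The analysis

The experimental design crosses four binary factors — scene **size**
(small/large), **clutter** (low/high), image **contrast** and **luminance**
(adjusted to fixed RMS values: contrast 34%/50%, luminance 34%/51%) — with
3 exemplar images per combination: 48 conditions. Subjects see each image
60 times (15 runs × 4 presentations) while 306-channel MEG is recorded;
epochs span −100…+900 ms around stimulus onset.

Per subject, the pipeline computes:

1. **Preprocessing** — reject trials with peak-to-peak amplitude ≥ 8000 fT
   (with a sign-permutation check that rejections are balanced across
   factor levels), z-score each channel by its −100…0 ms baseline, smooth
   with a 20 ms sliding window.
2. **Pairwise decoding RDMs** — at every time point *t*, for every pair of
   conditions (i, j): sub-average the M=60 raw trials in random groups of
   k=5, classify the pseudo-trials with a linear SVM (C=1) under
   leave-one-pseudotrial-out cross-validation, repeat 100×. The accuracies
   form a symmetric 48×48 decoding matrix per time point — the MEG
   representational dissimilarity matrix (RDM), with 50% chance level.
3. **Factor clustering** — mean of between-level minus within-level RDM
   cells, e.g. for size: positive values mean small and large scenes form
   separable clusters in representational space (units: % decoding
   accuracy difference).
4. **Cross-classification** — train the size classifier on (say) high
   clutter scenes, test on low clutter (both directions averaged; trials
   pooled over the 12 images per cell, M=720, k=60), and likewise across
   contrast, luminance, and image identity (train on 2 of 3 exemplars,
   test on the third). Above-chance transfer means a size code tolerant to
   that factor.
5. **Model RSA** — GIST (32 Gabor filters, 4×4 grid, 512-dim) and HMAX
   (S1→C1→S2→C2) features of the stimulus images, plus externally computed
   activation tables (e.g. deep networks), each layer converted to an RDM
   by 1 − Spearman's R; explicit binary factor models (1 where two
   conditions differ in a level); Spearman RSA time courses brain↔model,
   and **partial-correlation RSA**: the size-model correlation after
   regressing all layer RDMs of a computational model out of the ranks.
6. **Inference** — one-sample sign-permutation tests over subjects with
   cluster-size correction over time (cluster-definition and corrected
   thresholds P=0.05, two-sided), bootstrap-over-subjects 95% CIs for
   cluster onsets and peaks, peak-to-peak latency difference tests,
   condition-label permutation tests for model RDM correlations with
   Benjamini–Hochberg FDR.

The synthetic generator (`megrsa.simulate`) produces the same design with
factor-level-specific multivariate patterns injected at configurable
latencies (half-cosine envelopes) over spatially correlated, AR(1)
temporally correlated sensor noise — so injected onsets, peaks and
generalization structure are known exactly and the pipeline's output can
be scored against ground truth.

## Worked example

```python
import megrsa as m

design = m.generate_design(3)                       # 48 conditions
signal = m.SignalSpec(effects=(m.EffectSpec("size", 140, 200, 300, 250.0),))
noise  = m.NoiseSpec(n_channels=30, scale=100.0)

rdms = []
for epochs in m.generate_dataset(design, signal, noise,
                                 n_subjects=8, n_trials_per_condition=20,
                                 master_seed=1, step_ms=5.0):
    kept, _ = m.reject_trials(epochs, design)
    proc = m.smooth_timecourse(m.baseline_normalize(kept), 20.0)
    rdms.append(m.pairwise_decoding_timecourse(
        proc, design, m.DecodingConfig(k=5, n_repetitions=2, time_decim=8)))

tc = m.clustering_timecourse(rdms, design, "size")
print(m.sign_permutation_cluster_test(tc, n_perm=500, seed=5).report_text())
```

On the numbered analysis run (`python analysis/02_run_pipeline.py`, ~2 min)
this configuration prints, among the 13 analyses:

```
            analysis  significant  onset_ms  peak_ms  max_effect
     clustering_size         True     180.0    220.0   38.973571
  clustering_clutter        False       NaN    860.0    0.328646
cross_size_across_identity   True     180.0    180.0   50.000000
            rsa_size         True     180.0    220.0    0.812258
```

Read: the injected size effect (true onset 140 ms, peak 200 ms, evaluated
on a 40 ms latency grid) is recovered as a significant size-clustering
cluster with ~39% peak accuracy difference, generalizes across every other
factor and across image identity, and the explicit size model correlates
with the MEG RDMs at ρ ≈ 0.81 at the same latency — while the clutter
curve stays at noise level. Occasional weak spurious clusters in the
no-effect curves are expected at the 5% family-wise level.

The full analysis sequence is `analysis/01_simulate.py` (design, stimulus
images, example epochs), `02_run_pipeline.py` (decoding → RSA →
inference), `03_feature_models.py` (GIST/HMAX RDMs vs the explicit factor
models, label-permutation tests, FDR), `04_report.py` (latency table and
peak-to-peak difference test). Tables land in `results/`.

## Layout

```
src/megrsa/        library: design, stimuli, simulate, preprocessing,
                   svm, decoding, rsa, features, inference, pipeline
analysis/          numbered narrative drivers (see above)
scripts/           acceptance.py
tests/             pytest suite (unit, property, calibration, recovery)
docs/methods.md    model assumptions, parameter choices, limitations
```
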