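# nirslayout

Designing a sparse fNIRS montage means deciding, before any optical data
exist, where a handful of sources and detectors should sit on the scalp so
that the measured signal is maximally sensitive to a cortical region of
interest. `nirslayout` implements and compares — on fully synthetic head
models and recordings — four ways of making that decision with increasing
amounts of subject-specific imaging information:

| approach | head model | ROI |
|----------|-----------|-----|
| LIT   | shared atlas | literature-style anatomical ROI |
| PROB  | subject's own | leave-one-subject-out probabilistic functional ROI |
| iFMRI | subject's own | subject's own functional ROI |
| fVASC | subject's own + vasculature | subject's own functional ROI |

It is intended for methodologists studying optode-layout optimization and
sparse-montage BCI pipelines who want every stage — photon transport,
channel selection, forward simulation, preprocessing, GLM, group
statistics — exercised end to end with a known ground truth.

## The model in brief

Voxel Monte Carlo photon transport on a layered head phantom yields, per
candidate scalp-position pair (channel), a light-sensitivity profile
(PMDF) as the adjoint product of source and detector fluences,
Φ_s(v) · Φ_d(v). A channel's scalar sensitivity to an ROI R is

    S(c, R) = 100 · Σ_{v∈R} PMDF_c(v) · w(v) / Σ_{v∈brain} PMDF_c(v)   [%]

A seeded sweep selects, per approach and task, the two channels sharing
one optode that maximize S(c₁,R) + S(c₂,R) subject to 25 ≤ d ≤ 40 mm
(exhaustive over optode-sharing pairs). Merged montages are simulated
forward: Δ[HbO](t) = Σ_task β·(boxcar ⊛ HRF), Δ[HbR] = −⅓·Δ[HbO],
superficial Mayer-wave/drift signal, AR noise and motion artifacts,
converted to two-wavelength intensity through the modified Beer–Lambert
law with an age-specific DPF. The analysis chain inverts it: OD → CV
channel rejection → motion detection → concentrations →
short-separation regression → AR(p)-prewhitened GLM with DCT confounds
(β_ROI = c·β_channel, Cov_ROI = c Cov c^T, c = (0.5, 0.5) on the layout
channels) → band-passed block averages and
CNR = |mean(dur) − mean(pre)| / √(var(dur) + var(pre)).
Approaches are compared with Friedman tests, one-sided Wilcoxon
signed-rank tests (Benjamini–Hochberg corrected), percent-significant
counts, and layout-similarity measures. See `docs/methods.md` for the
full account.

## Worked example

```python
from nirslayout import StudyConfig, run_full_study

report = run_full_study(StudyConfig(n_subjects=8), seed=2)
hbo = report.cnr[report.cnr.chromophore == "HbO"]
print(hbo.groupby("approach").cnr.median())
pw = report.pairwise
print(pw[(pw.metric == "cnr") & (pw.chromophore == "HbO")
         & (pw.grouping == "all")][["better", "worse", "p", "q"]])
```

Output (seed 2, 8 subjects):

```
approach
LIT      1.312729
PROB     3.615581
fVASC    2.019223
iFMRI    2.669813
Name: cnr, dtype: float64
   better  worse         p         q
36   PROB    LIT  0.000381  0.002289
37  iFMRI    LIT  0.001678  0.005035
38  fVASC    LIT  0.004593  0.009186
39  iFMRI   PROB  0.921094  0.966842
40  fVASC   PROB  0.963203  0.966842
41  fVASC  iFMRI  0.966842  0.966842
```

Reading: the literature-guided layout (LIT), whose ROI mislocates the true
activation site by 15 mm by default, delivers between a third and two
thirds of the median contrast-to-noise ratio of the MRI-informed layouts,
and every
informed-vs-LIT contrast survives FDR correction; iFMRI and fVASC are
statistically indistinguishable — adding vascular information changes the
selected channels very little.

A thin CLI mirrors the library (`nirslayout run-study --seed 1 --out out/`,
plus `phantom`, `photons`, `design-layout`, `simulate`, `preprocess`,
`glm`, `evaluate` subcommands).

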