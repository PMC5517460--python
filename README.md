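# nirsnet

How much resting-state fNIRS data do you need before functional connectivity
and graph-theoretical network metrics stop changing?  `nirsnet` implements
the full analysis that answers this question for multichannel optical
neuroimaging: from hemoglobin concentration time series (or raw two-wavelength
optical density) through ICA artifact rejection and band-pass filtering, to
duration-binned connectivity estimation, sparsity-thresholded graph metrics,
and stability / test-retest reliability evaluation across scanning durations.
Because public resting-state fNIRS recordings with two runs are scarce, the
package ships a first-class synthetic cohort generator with known ground
truth (generating correlation matrix, injected artifacts, true reliability),
so every pipeline stage can be validated end to end.

It is written for researchers planning resting-state fNIRS protocols
(how short can a scan be?) and for methodologists studying the reliability of
connectome metrics.

## The analysis

For each subject, run, and prefix window of duration *T* ∈ {60, 90, …, 600} s
(19 bins, 30-s steps), connectivity between channels *i*, *j* is estimated
two ways:

- **Pearson**: r(x_i, x_j) over the window;
- **max-lag cross-correlation**: max over delays d ∈ [−L, L] of the Pearson
  correlation of the overlapping segments (L = 20 s by default), which
  tolerates regional hemodynamic delays.

Each 46×46 matrix is thresholded at sparsity s ∈ {0.17, 0.18, …, 0.50}
(equal edge count round(s·1035) for every subject) into binary or weighted
graphs, and five metrics are computed:

- nodal efficiency  E_nodal(i) = (1/(N−1)) Σ_j 1/d_ij
- nodal betweenness b_i = (1/((n−1)(n−2))) Σ_{h<j} ρ_hj(i)/ρ_hj
- clustering coefficient C = (1/n) Σ_i 2t_i/(k_i(k_i−1))
- global efficiency E_glob = mean_i E_nodal(i)
- local efficiency  E_loc = (1/N) Σ_i E_glob(G_i), G_i the subgraph induced
  on i's neighbours

each summarized over the sparsity grid by its trapezoidal AUC.  Stability is
the correlation of a short-duration map with the 10-min reference map
(paired t-tests for global metric AUCs); reproducibility is the between-run
map correlation; reliability is the one-way random-effects intraclass
correlation ICC = (MS_b − MS_w)/(MS_b + (k−1)MS_w) across the two runs.

## Worked example

```python
import nirsnet as nn

spec = nn.CohortSpec(n_subjects=6, n_runs=2, n_channels=46,
                     duration_s=600.0, sampling_rate_hz=5.0, rng_seed=100,
                     artifact_params=nn.ArtifactParams.none(),
                     within_subject_sd=0.0)
cohort = nn.simulate_cohort(spec)
result = nn.DurationStabilityAnalysis(cohort).fit()

st = result.stability
fc = st[(st.metric == "fc") & (st.method == "pearson")
        & (st["mode"] == "binary")].sort_values("duration_s")
print(fc.value.round(3).tolist())
```

prints the group-mean FC stability correlation per duration bin:

```
[0.6, 0.677, 0.752, 0.791, 0.821, 0.842, 0.864, 0.884, 0.897, 0.913,
 0.927, 0.943, 0.954, 0.962, 0.969, 0.977, 0.986, 0.992, 1.0]
```

i.e. a 60-s window already correlates r ≈ 0.6 with the 10-min reference FC
map, the similarity climbs monotonically with duration, and the 600-s bin is
the reference itself (r = 1 exactly).  `result.summary()` tabulates, per
metric/method/mode, the shortest duration reaching r ≥ 0.9 and the ICC at
the reference duration with its qualitative band (low/fair/good/excellent).

The same pipeline is scriptable from a shell:

```bash
nirsnet run-all --subjects 6 --runs 2 --channels 46 --rate 5 \
    --seed 100 --no-artifacts --out-dir out/
```

which writes the recordings, `stability.tsv`, `reliability.tsv` and
`summary.tsv` (all plain TSV).  `nirsnet simulate | preprocess | connect |
metrics | evaluate` expose the individual stages; `--set section.key=value`
overrides any configuration default.

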