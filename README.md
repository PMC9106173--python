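# topogait

Topological comparison of gait trials recorded with foot-mounted inertial
measurement units (IMUs).

Clinicians following patients with progressive multiple sclerosis (MS) need
to detect subtle changes in gait that standard features (speed, step length,
step time) often miss. `topogait` implements a non-parametric method that
compares whole gait signals by their oscillation structure: it needs nothing
but the medio-lateral foot angular-velocity signal ("Gyr-Y", deg/s, 100 Hz)
of each straight-walk trial, and supports cohort-wide comparison
(healthy vs patient), severity stratification (EDSS thresholds) and
longitudinal follow-up (baseline M0 vs six-month M6), including detection of
gait asymmetry and outlier trials.

## Method

For each trial with signal *f*:

1. **Persistence barcode.** The sublevel sets
   *F*<sub>α</sub> = *f*<sup>−1</sup>((−∞, α]) grow as α sweeps upward;
   connected components are born at local minima and merge at local maxima
   (the elder rule: the younger component dies). The multiset of
   (birth, death) level pairs is the 0-dimensional sublevel-set persistence
   barcode *B*(*f*); exactly one bar has infinite death. Each gait cycle
   contributes one long bar and one medium bar; short bars encode
   oscillations and irregular movements.
2. **Step-aware trimming.** The step count *k* is taken from metadata or
   estimated from the autocorrelation function (the lag of the first
   positive-lag ACF peak is the gait-cycle duration;
   *k* = round(duration / cycle duration)). The *k* longest bars are removed
   so the comparison ignores the step count and focuses on oscillations.
3. **Bottleneck distance.** Trimmed barcodes are compared with
   *d*(*B*, *B*′) = inf<sub>γ</sub> sup<sub>b</sub> ‖*b* − γ(*b*)‖<sub>∞</sub>
   over bijections γ after augmenting both barcodes with zero-length
   diagonal bars (*x*, *x*). The solver is exact (candidate-value binary
   search + bipartite matching).
4. **Embedding.** The pairwise distance matrix is projected to 2D with UMAP
   (precomputed metric, n_neighbors = 45, min_dist = 0.3, seeded).
5. **Group features.** For any metadata-defined partition into groups
   *C*<sub>i</sub>, the package reports the pairwise silhouette
   Sil(*C*<sub>i</sub>, *C*<sub>j</sub>) = mean over *x* ∈ *C*<sub>i</sub> of
   (*b* − *a*)/max(*a*, *b*) (separability, asymmetric, in [−1, 1]), the mean
   squared intra-group distance MSD (density) and the squared diameter SD
   (outlier sensitivity) in the embedded plane.

A synthetic cohort generator with known ground truth (cycle count, severity,
left/right asymmetry, longitudinal drift) makes every stage testable without
patient data.

## Worked example

```python
from topogait import CohortSpec, EmbedConfig, PipelineConfig, analyze, generate_cohort

spec = CohortSpec(n_hs=4, n_ms=4, sessions=("M0",), trials_per_session=2, seed=1)
signals, records = generate_cohort(spec)

cfg = PipelineConfig(embedding=EmbedConfig(seed=1), experiments=("HS_MS",))
result = analyze(signals, records, cfg)

print(f"{len(result.records)} trials, "
      f"step counts {sorted(set(e.k for e in result.steps.values()))}")
print(result.tables["HS_MS"].round(2).to_string(index=False))
```

prints

```
32 trials, step counts [5]
 Sil(HS,MS)  Sil(MS,HS)  MSD(HS)  MSD(MS)  SD(HS)  SD(MS)
       0.61        0.54     2.16     2.83    7.61   12.39
```

The 8 subjects (4 healthy, 4 patients of increasing severity) walked 2
trials each, both feet recorded: 32 signals. The ACF correctly recovers 5
gait cycles per trial. Both silhouettes are clearly positive — healthy and
patient trials form separable clusters in the embedding — and the patient
group is sparser (higher MSD/SD), reflecting its heterogeneous severity.

The same pipeline is available from the shell:

```bash
topogait simulate --out cohort --n-hs 4 --n-ms 4 --seed 1
topogait run-all --config pipeline.yaml     # barcodes, distances, embedding, tables, plots
topogait report output/
```

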