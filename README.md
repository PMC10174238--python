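# trsc — time-resolved spectral coupling for fMRI component time courses

Resting-state fMRI dynamics are usually summarized by sliding-window
*time-domain* correlations between component time courses. Two signals can
be almost uncorrelated in the time domain — a pair of equal-frequency
oscillations a quarter-cycle apart is the canonical example — while their
power spectra are essentially identical. `trsc` implements the
complementary *spectral* view: how strongly the short-time power spectra of
two brain components co-vary across a scan, and whether that coupling
differs between clinical groups.

It is written for neuroimaging researchers who already have per-subject
component time courses (e.g. back-reconstructed group-ICA components) and
want a window-resolved spectral-coupling analysis with group statistics,
plus a synthetic cohort generator for method validation.

## Method

For each component time course of `T` samples at repeat time `TR` (defaults
mirror a typical protocol: `T = 159`, `TR = 2 s`):

1. **Windowed spectra.** Overlapping windows of `W = 50` TRs shifted by 1 TR
   (window count `Tw = T − W`, i.e. 109; the last timepoint is unused by
   this convention). Each window is demeaned and Fourier-transformed; power
   is kept at the `S = W/2 = 25` positive-frequency bins. One `S × Tw`
   spectrogram per component.
2. **Window-by-window (WW) coupling.** For every unordered component pair
   `(i, j)` — `C(C−1)/2 = 1081` pairs at `C = 47` — the `Tw × Tw` matrix
   `r[a,b] = corr(PSD_i(window a), PSD_j(window b))` (Pearson, across
   frequency bins).
3. **Global quartiles and occupancy.** The 25/50/75th percentiles of all WW
   cells pooled over every subject and pair split each map into four binary
   masks (Q1 `v ≤ q25` … Q4 `v > q75`). Per mask: the **cell count** and
   the **average 4-connected cluster size** (horizontal/vertical adjacency
   only; singletons count; empty mask → 0).
4. **Group statistics.** Per (pair, quartile, measure), OLS of the subject
   summary on diagnosis (SZ = 1), sex (M = 1) and their interaction;
   two-sided t-tests per contrast; Benjamini–Hochberg FDR within each
   displayed matrix. Results are rendered as `C × C` signed `−log10(p) ·
   sign(t)` matrices (upper triangle: uncorrected `p ≤ α`; lower triangle:
   FDR-passing; negative = HC/F dominance).

A cohort simulator (`trsc.synthetic_data`) generates 2-diagnosis × 2-sex
cohorts whose network blocks share narrowband oscillators; amplitude
envelopes mix a block-shared and a private component, and the mixing weight
can differ by diagnosis in one block — planting exactly the kind of group
difference the pipeline is designed to detect.

## Worked example

```
trsc simulate --out data --n-per-cell 2 --n-components 6 --n-timepoints 159 --seed 7
trsc run --manifest data/manifest.tsv --metadata data/metadata.tsv \
         --labels data/network_labels.tsv --out out
trsc report out
```

prints (values from this exact invocation):

```
trsc run summary (out)
  subjects: 8  components: 6  timepoints: 159
  pairs: 15  windows: 109  bins: 25
  global quartile thresholds: q25=-0.0183, q50=0.1031, q75=0.3280
  FDR rejections per (quartile, measure, contrast):
    Q1 avg_cluster_size  diagnosis    0
    Q1 avg_cluster_size  interaction  0
    ...
    Q2 cell_count        diagnosis    1
    Q2 cell_count        interaction  1
    ...
    Q4 cell_count        sex          1
```

8 subjects × 6 components give 15 component pairs, each with a 109 × 109 WW
map cut at the pooled quartile thresholds shown. No effect is planted here,
yet three scattered rejections appear: with only two subjects per design
cell the per-pair tests sit at the regression's minimum sample size and are
unstable — a deliberate illustration that cohorts this small are only
useful for smoke-testing. At validation scale (ten subjects per cell) the
null family rejection rate is controlled at the nominal level; see
`docs/methods.md`. The same workflow scales to a real cohort by pointing
`--manifest` at exported component time-course matrices (one TSV per
subject, rows = components) with a matching metadata table.

The Python API mirrors the CLI: `simulate_cohort(SimulationConfig(...))`,
`analyze_cohort(dataset, metadata)` and the per-stage functions in
`trsc.pipeline`.

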