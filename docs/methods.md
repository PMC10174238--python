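# Methods

## Signal model and pipeline

The package analyses `n_subjects × n_components × n_timepoints` arrays of
component time courses sampled at repeat time `TR` (seconds). Nothing in
the pipeline assumes how the components were obtained; in practice they are
group-ICA back-reconstructed resting-state components.

**Windowing.** Windows of even length `W` TRs are shifted by `step` TRs.
The window count is `Tw = (T − W) // step`, *not* the conventional
`(T − W) // step + 1`: the configuration `T = 159, W = 50, step = 1` yields
109 windows and leaves the final timepoint unused. This convention is fixed
because all downstream matrix dimensions (and the package's own dimension
checks) are built on it; both counts differ by one window only. At least
two windows are required.

**Per-window spectra.** Each window is mean-subtracted (removing the DC
term exactly) and transformed with an unnormalized FFT; power is the
squared magnitude at bins `k = 1 … W/2` (DC excluded, Nyquist included), so
a spectrogram has `S = W/2` rows. Bin `k` sits at `k/(W·TR)` Hz. The
default window is rectangular — the minimal choice, and the sharpest for
the narrowband signals this method targets; a Hann taper is available
(`taper="hann"`) for data with strong spectral leakage. Power is
correlated on a linear scale by default; `log_power` and per-time-course
`zscore` options exist but are off, since the coupling statistic is
scale-invariant per window (Pearson correlation is affine-invariant).

**WW maps.** For components `i < j`, entry `(a, b)` of the `Tw × Tw` map is
the Pearson correlation across the `S` bins between `i`'s spectrum in
window `a` and `j`'s spectrum in window `b`. Implementation: spectrogram
columns are centred and normalized to unit norm, so a map is a single
`Z_iᵀ Z_j` product; values are clipped to `[−1, 1]` to remove floating-point
overshoot. Maps are stored as float32 — at study scale the WW stack is by
far the largest intermediate (≈ 51 MB per subject at `C = 47`), and the
quartile assignment of a correlation is insensitive at that precision. A
spectrally constant window has no defined correlation: strict mode (the
default, and correct for simulated data) raises; lenient mode marks the
affected row/column NaN, and such cells are excluded from pooling, counts
and clusters.

**Quartiles and occupancy.** Thresholds are the 25/50/75th percentiles of
the pooled multiset of every finite WW cell over all subjects and pairs,
with NumPy's default linear interpolation between order statistics (the
"type 7" rule). Bins are `Q1: v ≤ q25`, `Q2: q25 < v ≤ q50`,
`Q3: q50 < v ≤ q75`, `Q4: v > q75` — boundary values fall to the lower bin,
which makes the degenerate all-equal input land wholly in Q1 and keeps the
four masks an exact partition under ties. Cluster statistics use
4-connectivity (no diagonal adjacency); isolated cells are clusters of size
1; an empty mask has average cluster size 0 (keeping regression inputs
finite). Internally all four quartile masks of a map are labelled in one
pass by connected-component labelling of the bin-index image, which is
equivalent to labelling each mask separately because regions of different
bin values can never merge. Subgroup matrices average each pair's per-map
value over the subgroup's subjects (per map, then across subjects);
diagonals are NaN (self-pairs are undefined).

**Group regression.** Each (pair, quartile, measure) response is fitted by
OLS on `[1, dx, sex, dx·sex]` with `SZ = 1, M = 1`; contrasts are the
marginal t-tests of the three non-intercept coefficients with `n − p`
degrees of freedom. All responses share one design, so the package solves
the multi-response least-squares problem in a single vectorized pass — a
run involves hundreds of identical-design fits and the validation suites
run hundreds of replicate cohorts; the fit is verified against
statsmodels OLS in the tests. Every design cell must be occupied (else the
interaction is collinear and the error names the empty cell). Extra
covariate columns can be appended to the design. Cell counts are treated
as continuous responses (values are in the thousands). BH-FDR is applied
within each (quartile, measure, contrast) family of pairs by default —
matching how difference matrices are displayed — with an optional pooled
family. Difference matrices carry `−log10(p)·sign(t)`: upper triangle
masked at uncorrected `p ≤ α`, lower at the FDR decision; negative values
mean HC/F dominance under this coding.

## Synthetic cohorts

The simulator's purpose is validation: it must generate data whose
*windowed spectral coupling* — the statistic this pipeline measures —
differs between groups in a controlled block, while everything else is
exchangeable between groups.

Per subject, each network block owns `K = 4` oscillators with frequencies
drawn uniformly in 0.01–0.1 Hz (the resting-state BOLD band; frequencies
are shared within a block, which is what makes within-block spectra
comparable bin-by-bin). Component `c` in a block contributes
`Σ_k e_{c,k}(t) · sin(2π f_k TR t + θ_{c,k})` plus white noise of standard
deviation `noise_sd = 0.5`. The envelope is the convex mixture
`e_{c,k} = λ·E_k + (1−λ)·P_{c,k}` of a block-shared and a private envelope;
`λ` is `coupling_hc`/`coupling_sz` in the designated effect block (default
VIS) and `base_coupling = 0.5` elsewhere.

Envelopes are softplus-rectified moving-average-smoothed Gaussian noise.
Two parameters matter and are deliberate:

- **Timescale (`envelope_smooth_tr = 60`).** The envelope must vary
  *slower than the analysis window* (50 TRs): windowed power is an average
  of the squared envelope over the window, so a fast envelope averages out
  and leaves nothing for the coupling statistic to detect. Measured on
  single pairs, a 20-TR envelope gives a coupled-vs-uncoupled gap in mean
  WW correlation of ≈ 0.02; at 60 TRs the gap is ≈ 0.1.
- **Modulation depth (`envelope_gain = 2`).** The latent Gaussian is scaled
  before the softplus; deeper modulation makes the relative heights of the
  spectral peaks vary more across windows, which is the variation that
  shared envelopes synchronize.

Seeding: each subject's stream is a `SeedSequence` keyed by
`(master seed, design cell, index within cell)`, so enlarging the cohort
never changes existing subjects' data, and everything downstream is
bit-deterministic given the configuration.

Default dimensions mirror the study setup (47 components in 7 domains —
SC 5, AUD 2, VIS 9, SM 9, CC 11, DM 7, CB 4, a split chosen once to sum to
47 with plausible proportions — 159 timepoints, TR 2 s), reproducing the
printed pipeline dimensions: 109 windows, 25 bins, 1081 pairs, 11 881
cells per map. What the simulator does **not** emulate: 1/f background
structure, hemodynamic smoothing, head motion, scanner/site effects, and
spatial structure of any kind. Passing the validation suite therefore
shows the pipeline recovers *spectral-coupling* group differences under
clean conditions; it does not certify robustness to acquisition artifacts.

## Validation problem sizes

The statistical checks run on reduced cohorts chosen to keep the suite
fast while leaving the tested quantities well-estimated: null calibration
uses 12-component, 40-subject cohorts (200 replicates in the test suite,
100 in the acceptance script), and planted-effect recovery uses
10-component, 80-subject cohorts with a 6-component coupled block
(50 and 25 replicates respectively). The planted effect is large
(`λ = 0.9` vs `0.3`) by design: the recovery check asks whether the
pipeline finds an unmistakable effect in the right place with the right
sign, not what its detection threshold is.

## Numerical and interface decisions

- Window-count convention `(T − W) // step`, as above.
- Quantile rule: type 7 (linear interpolation); frozen by tests.
- Boundary rule: upper-closed bins; exact threshold values fall downward.
- WW maps float32; all statistics float64.
- Tables are TSV, UTF-8, `.` decimal, floats at 12 significant digits
  (round-trips to < 1e−9 relative); row order sorted by keys, so outputs
  are byte-reproducible.
- Subject and component order is manifest order everywhere; pairs are
  lexicographic `(i, j)`, `i < j`.
- Fisher-z transforming WW values before quartiling is *not* done (the
  quartile binarization is rank-invariant, so it would only move the
  threshold values, not the masks).

## Known limitations

- The slow-envelope default (~2.7 independent envelope epochs per 159-TR
  scan) makes subject-level occupancy summaries noisy: even a large planted
  coupling difference is occasionally split across Q3 and Q4 when the pooled
  q75 lands inside the coupled group's correlation distribution, costing
  per-pair power in the Q4 family for a minority of simulated cohorts.

- Exact pooled quantiles require the WW values of the whole dataset; the
  pipeline gathers them across subjects (float32). At much larger scales a
  streaming quantile sketch would be needed.
- OLS treats summaries as homoscedastic across subjects; no site/age/motion
  covariates are included by default (the design accepts extra columns).
- Lenient-mode missing cells are excluded from pooling and counts but the
  per-map partition total then varies by map; group comparisons of counts
  implicitly assume similar missingness across groups.
- The strict/lenient distinction only matters for pathological inputs
  (constant windows); BOLD-like data never triggers it.
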