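# Methods

This note documents the models and procedures implemented in `memdkit`, the
choices made where the literature leaves details open, and what the
synthetic test conditions do and do not demonstrate.

## Empirical mode decomposition (`memdkit.sift`)

A signal is represented as x(t) = Σ_m c_m(t) + r(t), where each intrinsic
mode function (IMF) c_m is obtained by sifting: cubic-spline envelopes are
fitted through the local maxima and minima, and their pointwise mean is
subtracted until the candidate satisfies

* **criterion (a)** — the numbers of extrema and zero crossings differ by at
  most one, and
* **criterion (b)** — the envelope mean is zero.

Criterion (b) is unattainable exactly in floating point; it is enforced as
RMS(envelope mean) / STD(current component) < `envelope_mean_tol`
(default 0.05, dimensionless). `max_sift_iters` (default 100) caps the loop
on pathological inputs. Extraction stops when the residual no longer has
two maxima and two minima (it is then monotone or a single hump), or at
`max_imfs` (default ⌈log2 T⌉ + 2, the dyadic plausibility bound).

Numerical conventions:

* **Extrema.** Strict interior extrema; a plateau of equal samples flanked
  by lower (higher) values contributes one maximum (minimum) at its
  midpoint — a deterministic tie-break.
* **Zero crossings.** A sample exactly at zero counts as one crossing when
  its neighbours have opposite signs; runs of zeros collapse to one
  crossing; leading/trailing zeros (no second neighbour) never count.
* **Boundaries.** `boundary_mirror_count` (default 2) extrema are mirrored
  about each end of the record before spline fitting. Mirroring is the
  least-biased common treatment; without it the spline swings freely at the
  edges and leaks energy into every IMF.
* **Envelope degeneracies.** With exactly two knots the "spline" is the
  straight line through them; with fewer the component is a residual.

### Ensemble EMD (EEMD)

EEMD decomposes `n_realizations` (default 50) copies of the signal, each
perturbed with white Gaussian noise of STD `noise_amplitude` × STD(x)
(default 0.2 — the noise level is a free parameter of the method; 0.2 is
the conventional choice), and averages same-indexed IMFs. Realizations can
produce different IMF counts; stacks are aligned by index, zero-padded to
the maximum observed count, averaged, and trailing averaged IMFs with
energy below 1e−12 of the input's are folded into the residual. Note a
consequence: the EEMD IMF count equals the *maximum* count over the
ensemble, a very stable statistic. Per-realization noise streams come from
a generator seeded with the pair `(seed, realization_index)`, so ensembles
are reproducible and extensible.

EEMD's averaged output reconstructs the input only up to the averaged
noise (which shrinks as amplitude/√N); exact reconstruction holds for EMD,
MEMD and NA-MEMD.

## Multivariate EMD (`memdkit.memd`)

For a P-channel signal, envelopes cannot be defined channel-by-channel
without losing cross-channel coupling. MEMD projects the signal onto V
quasi-uniform unit vectors on the (P−1)-sphere (default V = 64, a standard
compromise between envelope stability and cost for P ≤ 8). For each
direction, the time instants of the *projection's* maxima are found and the
full P-dimensional signal is interpolated there (one cubic spline per
channel, shared knots, mirrored boundaries); the local mean M(t) is the
average of these directional envelopes.

**Direction set.** Coordinate k of point i is the van der Corput radical
inverse of i in the k-th prime base (2, 3, 5, …); coordinates are mapped
through the inverse normal CDF and normalised to unit length. Every point
is paired with its antipode, making the set exactly symmetric under
negation. This matters because envelopes are interpolated at projection
*maxima* only: the antipodal partner of each direction covers the
corresponding minima, and the symmetry cancels the envelope mean exactly on
noise-free common modes. The construction is deterministic, so direction
sets are bit-reproducible for given (V, P).

**Stoppage.** Sifting of one multivariate IMF stops when

mean_t [ (‖M(t)‖₁ / P) / e(t) ] < γ,  e(t) = (1/P) Σ_p |c_p(t) − M_p(t)|,

with e floored at 1e−12 and γ = 0.2, a threshold calibrated on lower-limb
surface EMG. The source description of this rule reads as "continue when
satisfied", which cannot terminate; the conventional stop-when-below-γ
reading is implemented. The per-sample ratio is reduced over time by the
mean (a max reduction is available via `MvStopParams.reduction`).

Directions whose projection has fewer than two maxima are skipped for that
pass; when no direction is usable the residual has been reached. Because
all channels are sifted against the shared M(t), every channel receives the
same number of IMFs — the structural guarantee that makes same-index
cross-channel comparison meaningful.

### Noise-assisted MEMD (NA-MEMD)

K extra channels (default 4) of independent white Gaussian noise are
appended, the (P+K)-channel composite is decomposed with MEMD, and the
noise channels' IMFs are discarded. The noise power defaults to the
average of the per-channel STDs of the input — the standard choice for
EMG. Noise channels are drawn once per call (a single composite, not
per-IMF redraws). The broadband noise keeps every dyadic band populated
with extrema, which stabilises the filter-bank behaviour and empirically
reduces mode mixing in the signal channels. With K = 0 the wrapper is
exactly MEMD.

## Quality metrics (`memdkit.metrics`)

All metrics operate on STD-normalised IMFs (division by the sample STD;
zero-variance IMFs are excluded and logged). PSDs come from a Welch
estimator — Hann window, 50% overlap, segment length min(1024, T) — whose
density integrates to the sequence variance within the usual estimator
bias (~10%).

* **Mode-alignment.** For IMF index i, the PSDs of that IMF in all channels
  are correlated pairwise (Pearson); c(i, j) is the mean correlation of
  channel j against the other channels, row means summarise each index, and
  the scalar per recording is the mean of row means over retained IMFs.
  The pairing rule makes row-averaging reproduce the intended "average
  correlation across channels" reading; rank correlation was never in play.
* **Mode-mixing.** Each IMF's 20%- and 80%-cumulative-energy frequencies
  (f2, f8) delimit its band, width D = f8 − f2. Adjacent IMFs i, i+1 score
  MM = |band_i ∩ band_{i+1}| / min(D_i, D_{i+1}) ∈ [0, 1]; an empty
  intersection scores 0 (the formula is undefined there), and two
  zero-width bands score 0 with a warning. The per-channel value
  aggregates adjacent-pair scores by the *mean* (default); a sum rule is
  available behind `aggregate_rule="sum"`. The defining formula is written
  as a sum but the accompanying procedure says "averaging"; the mean
  matches the reported magnitudes (all ≤ 0.33 over up to ~15 pairs).
* **Band edges.** f_q is the first frequency bin at which the cumulative
  per-bin energy reaches q of the total. This step-inverse makes a
  one-bin spectrum yield a zero-width band at that bin, which the linear
  interpolation of a trapezoid cumulative cannot do.
* **20 Hz rule.** Surface EMG energy lives roughly in 20–500 Hz. IMFs whose
  spectral centroid (configurable to peak frequency) falls below 20 Hz are
  excluded from the metrics and summed into one low-frequency remainder
  trace, so retained IMFs + remainder + residual still reconstruct the
  channel exactly.
* **Counts.** IMF-count tables report mean ± sample STD (ddof = 1).

In the study pipeline, the alignment scalar uses the IMF indices retained
in *every* channel (relevant for EEMD, whose per-channel retention can
differ); mixing is computed per channel on that channel's own retained
IMFs and averaged over the channels.

## Synthetic surrogates (`memdkit.synthetic`)

`gen_surrogate` emulates a 4-channel lower-limb surface-EMG montage:

* each shared mode is unit-STD band-limited Gaussian noise (white noise
  band-passed with a zero-phase 4th-order Butterworth filter) mixed into
  channels by a coupling-weight matrix — default centres 30/120/480 Hz
  (two octaves apart, inside the 20–500 Hz EMG band), bandwidth half the
  centre;
* a periodic motion/rest gate (2 s motion, 2 s rest — one 4 s exercise
  cycle) with 100 ms cosine ramps, because hard gating edges inject
  broadband energy unrelated to the phenomena of interest;
* independent per-channel white noise (default STD 0.2), left ungated
  because measurement noise does not pause during rest;
* sampling rate 1000 Hz (the source recordings' rate is not documented;
  1 kHz covers the EMG band at Nyquist).

`gen_heterogeneous_surrogate` additionally randomizes mode centres,
bandwidths and coupling weights per draw and gives each channel, with
probability 0.5, its own baseline-wander component (Gaussian noise
low-passed at 2 Hz, amplitude 0.5–2 × the mode STD). Baseline wander is an
electrode-specific artifact, so channels genuinely differ in low-frequency
content — the realistic mechanism by which channel-by-channel
decompositions disagree on IMF counts.

`segment_motion` uses a fixed-window scheme (cycle period × active
fraction, plus offset); the original study's segmentation procedure
(manual vs. threshold) is not documented, so fixed windows aligned with the
generator's gate are a stand-in.

What the surrogates do **not** model: motor-unit action-potential shapes
and firing statistics, amplitude non-stationarity within a motion,
movement artifacts, power-line interference, ECG crosstalk, or
subject-level variability. Passing the synthetic checks therefore shows
the decompositions behave correctly on signals with the EMG band structure
and shared-mode coupling, not that clinical conclusions transfer.

## Statistical pipeline (`memdkit.study`)

The comparison study decomposes each (subject, program) recording with
EEMD (channel-by-channel), MEMD and NA-MEMD (jointly), applies the 20 Hz
rule, and collects IMF counts, the alignment scalar and the
channel-averaged mixing value into a long-format table.

* **Two-way ANOVA** (program × method, subjects as replicates): classical
  between-cell sums of squares via OLS (type 2; the design is balanced, so
  types coincide). Saturated designs (one replicate per cell) are
  rejected.
* **One-way repeated-measures ANOVA** on per-subject program-averaged
  values: the condition effect is tested against the subject × condition
  interaction, sphericity assumed. Implemented with explicit balanced
  sums of squares so the full SS/df/MS/F/p table is available; it is
  cross-checked in the tests against `statsmodels` `AnovaRM`. No
  Greenhouse–Geisser correction is applied (out of scope); published
  fractional degrees of freedom produced by such corrections are therefore
  not reproduced.
* **LSD post-hoc**: unadjusted pairwise t statistics
  (mean_a − mean_b)/√(2·MS_err/n) on the repeated-measures error degrees
  of freedom.

The packaged reference tables (11 subjects × 3 programs × 3 methods, mode
alignment and mode mixing, rounded to two decimals as printed) ship as
CSVs. Statistics recomputed from them agree with the originally reported
values to a few percent — exact agreement is impossible because the inputs
are rounded: program SS 0.0656 (reported 0.063), method SS 0.4262
(reported 0.417), repeated-measures F 34.0 (reported 32.0).

## Problem sizes

Default analysis sizes were chosen so a complete comparison runs on a
laptop core in minutes: 2 s motion segments at 1 kHz (T = 2000), V = 64
directions, 50 EEMD realizations, 20-seed ordering studies, 50-fixture
count studies and 10-seed filter-bank checks on T = 4096. The method
ranking (alignment NA-MEMD > MEMD > EEMD; mixing reversed) is a statement
about seed-averaged means under these conditions; the EEMD–MEMD alignment
gap in particular is small because the surrogates' common modes are strong.

## Known limitations

* Instantaneous-frequency (Hilbert) analysis is out of scope; metrics are
  purely PSD-based.
* The stoppage threshold γ = 0.2 is an EMG-calibrated value, not a
  universal constant; very low-SNR inputs may over- or under-sift.
* EEMD's IMF count is the maximum over the ensemble (a consequence of
  index-wise averaging with zero-padding); other count conventions exist
  and would change count statistics but not the alignment/mixing metrics.
* The two-way ANOVA treats subjects as independent replicates within
  cells, which ignores the repeated-measures structure; the
  repeated-measures route is the one used for method comparisons.
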