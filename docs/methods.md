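# Methods

`bhnet` estimates the coupling between the moment-to-moment organization of
EEG-derived brain networks and time-varying cardiac autonomic activity. This
note describes the model and estimators, the choices made where the design
was genuinely open, what the synthetic benchmark does and does not
demonstrate, and the known limitations.

## Cardiac sympathetic and vagal indices

Heartbeats are reduced to the interbeat-interval (IBI) series; all cardiac
quantities derive from the Poincaré plot, the scatter of each interval
against the next. With `IBI'` the first difference of the interval series
and `std` the sample (n−1) standard deviation,

    SD01 = sqrt( 1/2 · std(IBI')² )
    SD02 = sqrt( 2 · std(IBI)² − 1/2 · std(IBI')² )

are the whole-condition minor/major ellipse ratios: SD01 captures fast,
beat-to-beat (vagally mediated) variability, SD02 slower drifts (dominated
by sympathetic modulation). Their fluctuating versions SD1(t), SD2(t)
evaluate the same formulas on beats inside a trailing window
Ω_t = [t − T, t], with T = 15 s, on a 1-s output grid. The cardiac vagal
and sympathetic index series re-anchor the demeaned fluctuations to the
global values:

    CVI(t) = SD01 + (SD1(t) − mean_t SD1)
    CSI(t) = SD02 + (SD2(t) − mean_t SD2)

so mean_t CVI = SD01 and mean_t CSI = SD02 by construction.

Numerical choices: the `std` convention is the sample (n−1) estimator,
matching common HRV practice; windows holding fewer than three intervals
are marked missing rather than zero (three intervals are the minimum for a
sample standard deviation of the differences); a negative SD02 radicand —
possible for strongly alternating rhythms — yields a missing sample with a
warning in the sliding estimator and a typed error in the global one. The
demeaning is taken per condition (per call), so concatenated conditions
should be analyzed separately. Note the trailing window makes the index
series a delayed, smoothed readout of the underlying autonomic state: the
group delay is roughly half the window (~7 s).

## Time-varying brain networks

EEG channels are band-pass filtered (zero-phase forward–backward
Butterworth, default order 4, 0.5–45 Hz) and re-referenced to the common
average. The pipeline expects artifact-cleaned EEG; ocular/cardiac-field
component removal is an upstream responsibility and deliberately outside
this package's scope.

Spectral connectivity uses a Hann-tapered short-time Fourier transform
with 2-s windows at 50% overlap, giving window centers on a 1-s grid.
Coherence between channels i and j,

    COH_ij[f] = |P_ij[f]| / sqrt(P_i[f] · P_j[f]),

is only informative after spectral averaging (a single segment gives
COH ≡ 1), so auto- and cross-spectra are averaged over a trailing block of
`smooth_K = 3` windows (≈3 s of unique data) before the ratio. This
preserves the 1-s resolution of the downstream metric series at the cost
of a high estimation variance and a noise floor — for independent signals
E[COH²] ≈ 1/K, so the expected floor is ≈0.57 in magnitude. `smooth_K` is
configurable; raising it trades temporal resolution for stability. This
single-window-coherence ambiguity is the central estimation choice of the
connectivity stage.

Coherence is averaged within alpha (8–12 Hz), beta (12–30 Hz) and gamma
(30–45 Hz), with band edges inclusive and bin membership by bin center.
The gamma ceiling matches the 45-Hz filter edge and is configurable.

Each weighted matrix is binarized by efficiency–cost optimization (ECO):
edges enter in descending weight order and the retained density ρ*
maximizes J(ρ) = (E_global + E_local)/ρ, swept in steps of one edge with
ties broken toward lower density. The optimum is sparse (mean degree ≈ 3),
which removes network density as a confound between conditions.

On each binary graph four global metrics are computed per second:

* global efficiency E = (1/n) Σ_i (1/(n−1)) Σ_{j≠i} d_ij⁻¹ with
  shortest-path distances; unreachable pairs contribute zero (standard
  convention);
* clustering, measured as transitivity: 3 × triangles / connected
  triples; zero when no connected triples exist;
* degree assortativity (Pearson correlation of degrees over edge
  endpoints); regular graphs have an undefined (0/0) value and yield a
  missing sample;
* modularity Q of the best partition found by a seeded local search that
  alternates three passes to a fixed point: greedy community merging
  (maximal positive Q gain, ties broken uniformly at random), single-node
  best moves, and exhaustive two-way community splits (the split gain is
  the negative merge gain, enumerable for communities up to 12 nodes —
  splits escape the compound-move local optima that merging plus single
  moves cannot leave). Eight seeded restarts — strictly greedy,
  randomized-greedy, and random-initial-partition — are scored with an
  exact Q evaluator and the best kept. Fixed seed ⇒ bit-identical output.
  On graphs small enough to enumerate every partition the search attains
  ≥95% of the exhaustive optimum (verified in the test suite over
  hundreds of random graphs).

Missing or degenerate samples propagate as gaps, never zeros, and are
removed pairwise at the coupling stage.

## Coupling: the maximal information coefficient

Dependence between a metric series X and a cardiac index series Y (paired
on the common 1-s grid, gaps deleted pairwise) is quantified by the
maximal information coefficient:

    MIC(X,Y) = max over grids (n_x × n_y < B = N^0.6) of
               I_g / log2 min(n_x, n_y)

where I_g is the empirical mutual information of the joint histogram
induced by an axis-aligned n_x × n_y grid and N the number of pairs. MIC
lies in [0, 1], is symmetric, and depends only on sample orderings, hence
is invariant under strictly monotone transforms of either series.

The exact maximization is exponential. For N ≤ 25 (where B confines grids
to 2×2 and 2×3) the implementation enumerates every cut placement exactly;
beyond that it uses the MINE search: equipartition one axis into q
mass-balanced bins, optimize the other axis by dynamic programming over
clump-based candidate cuts (at most `clumps_c = 15` times the bin budget),
and take the better of the two axis orientations. The exponent 0.6 and the
clump factor are configurable. Equality ties share bins; candidate cuts
never split runs of equal values.

Significance of a single MIC value is assessed against circular time-shift
surrogates: the cardiac series is rotated by a random offset, excluding
offsets within `min_shift = 35` samples of zero (mod N) so surrogates are
genuinely decorrelated. Circular shifts preserve each series'
autocorrelation, which is essential here — the 1-s series are strongly
autocorrelated, and an i.i.d. shuffle null would dramatically overstate
significance. The exclusion window should exceed the dominant
autocorrelation time of the series; 35 s suits the default benchmark
driver (25-s correlation time).

## Group statistics

Paired and unpaired comparisons use Wilcoxon signed-rank and rank-sum
tests. The reported Z statistic is the signed, tie-corrected normal
approximation (Z > 0 means condition 2 > condition 1); the p-value is
exact (distribution enumeration) for small tie-free samples and the
normal approximation otherwise, mirroring the defaults of the common
statistical environments. Spearman correlations report the rank-Pearson ρ
with the Student-t approximation on n − 2 degrees of freedom. Any
significant result can be confirmed by a Monte Carlo permutation test:
p_mc is the fraction of `n_perm = 1000` permuted |effect| values at least
as large as the observed one, with sign-flips for paired designs, group
label shuffles for unpaired ones, and pair shuffles for correlations;
p_mc = 0 is conventionally reported as p < 0.001. Exceedance is defined on
the statistic's magnitude, not on the p-value (the two can differ under
ties). No multiple-testing correction is applied by default across the 24
couplings — the permutation confirmation plays that gatekeeping role — but
a Benjamini–Hochberg helper is provided.

## The synthetic benchmark

The generator plants brain–heart coupling through a shared latent driver
rather than direct signal mixing, so any dependence the pipeline recovers
is genuinely cross-system. The driver is an Ornstein–Uhlenbeck process
with a 25-s correlation time mapped through the normal CDF to [0, 1]. Its
monotone exponential autocorrelation was a deliberate choice: periodic or
band-limited drivers keep time-shifted copies of themselves dependent, and
the circular-shift null would be structurally inflated.

RR series: baseline 0.85 s plus a slow LF-band (0.1 Hz) oscillation of
amplitude 30 ms, a beat-to-beat alternating component of 20 ms, and 5-ms
Gaussian jitter. In sympathetic-coupled modes the slow amplitude follows
the driver (so SD2/CSI track it); in vagal modes the alternating amplitude
does (SD1/CVI).

EEG: twelve channels in two six-channel communities at 128 Hz (the rate of
common preprocessed emotion-EEG releases; a deliberately reduced montage —
full 32-channel layouts are supported but cost proportionally more in the
ECO sweep). Channels within a community share a band-limited source whose
mixing gain (default 2.0) follows the driver when coupling is active;
between-community sources are independent. The gain default sits below
coherence saturation: pushed much higher, within-community coherence stays
pinned near 1 across the driver's whole range and the binarized topology
stops fluctuating. The cortical modulation follows the driver with a 7-s
lag, emulating afferent (heart-to-brain) transmission latency; this also
places the measured series in near-synchrony, since the trailing 15-s
Poincaré window delays the cardiac readout by ~7–9 s while the 3-window
spectral smoothing delays the metric series by only ~2 s.

ECG: a biphasic QRS-like template at the cumulative RR times plus baseline
wander and white noise at a configurable SNR, with ground-truth peak times
retained for detector validation.

What passing the benchmark shows: that the full pipeline recovers a
planted, physiologically-scaled cross-system dependence from 3-minute
recordings with realistic estimator noise, and stays quiet when none is
planted. What it does not show: robustness to real EEG artifacts, volume
conduction, non-stationary rhythms, ectopic beats, or montage effects —
the generator's sources are band-limited Gaussians with a clean community
structure, far simpler than cortical dynamics. Per-second binarized
metrics carry an irreducible estimation-noise floor (coefficient of
variation ≈0.2–0.6 depending on the metric even with a static gain), so
single-sample metric values should never be interpreted; only their slow
co-fluctuations carry signal.

Problem sizes: the end-to-end recovery suite and the acceptance script
both use 20 coupled plus 20 uncoupled 180-s scenarios with 99
circular-shift surrogates each; either completes on a single CPU in
minutes.

## Known limitations

* Coherence is undirected and volume-conduction-prone; no attempt is made
  at source reconstruction or lagged/imaginary connectivity.
* MIC is symmetric and zero-lag; directionality and time-lagged coupling
  are out of scope.
* The ECO sweep is O(edges) efficiency evaluations per time step; for
  dense montages (64+ channels) consider the `sweep_step` option.
* The sliding-mean smoothing utility (default 6 s) exists for display
  only and is never part of the analysis path.
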