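# Methods

`restflow` implements a resting-state HD-EEG analysis chain that asks
whether the directed-connectivity profile of the brain region containing
the seizure onset zone (SOZ) differs between epilepsy-surgery patients who
became seizure-free and those who did not. Because the clinical recordings
such an analysis targets are confidential, the package pairs the analysis
chain with a synthetic-cohort generator with known directed ground truth;
every stage is validated by parameter/direction recovery rather than by
re-deriving clinical numbers.

## Analysis model

**Sensor conditioning.** Recordings are high-pass filtered at 0.5 Hz with a
4th-order Butterworth applied forward-backward (zero phase, effective 8th
order) — phase preservation matters because all downstream quantities are
directional. Bad channels are flagged by a robust z-score (> 4) on the
per-channel log variance, combined with an absolute floor of 0.4 on the
log-variance deviation (the MAD itself is noisy when channels are few, and
genuinely bad channels deviate by far more than 1.5x), plus a flatline
rule. Flagged channels are dropped, not interpolated: interpolation creates
rank deficiency that breaks the MVAR fit. Blink- and cardiac-like artifacts
are removed by FastICA (at most 20 components): any component whose
absolute temporal correlation with a supplied reference trace exceeds 0.7
is subtracted from the data; if nothing crosses the threshold the input is
returned unchanged. FastICA's convergence flag is advisory here: on data
whose non-artifact subspace is close to Gaussian the residual rotations
never settle and the iteration cap is routinely reached, while the
high-kurtosis artifact directions stabilize early — so the implementation
ignores the convergence warning and errors only on numerically invalid
output. Ten disjoint 5 s epochs are then cut from the earliest fully clean
windows (deterministic; the study this mirrors selected epochs visually).

**Source imaging.** The inverse is the weighted minimum-norm kernel
K = R Gᵀ (G R Gᵀ + λ²C)⁻¹ with depth weighting R_ii = ‖g_i‖^(−2γ), γ = 0.5
by default. With λ unspecified, R is trace-normalized against the sensor
noise covariance C (identity by default) and λ = 1/3, i.e. an assumed power
SNR of 3 — the common minimum-norm convention. λ = 0 with square full-rank
mixing is the exact-inverse limit used as a correctness check. Source
courses are aggregated into region courses as the *sign-aligned signed
mean*: each source is flipped to correlate nonnegatively with the region's
first principal temporal component (polarity anchored so the majority of
sources, first source on ties, keep their sign). A mean of magnitudes would
rectify the signal and destroy the phase information the MVAR model needs;
the signed mean without alignment can cancel oppositely oriented sources
exactly. A packaged 104-fine-region → 12-macro-region mapping table
(`aal_macro_map_synthetic.tsv`, a synthetic stand-in assembled from
standard atlas nomenclature; users supply their own for real data) defines
the 12 regions: frontal, temporomedial, temporolateral, parietal,
occipital, thalamus, each left/right.

**MVAR + PDC.** One MVAR of order 40 is fitted per 5 s epoch with the
Nuttall-Strand (multichannel Burg) lattice. At each stage the partial
cross-covariance Δ between forward and delayed backward errors minimizes
the sum of error powers normalized by the previous-stage covariances, which
yields the Sylvester equation R_ff Σf⁻¹ Δ + Δ Σb⁻¹ R_bb = 2 R_fb; all
empirical covariances use the unbiased normalization (division by the
number of summed lag products). The lattice guarantees stationary
estimates, which least squares does not at order 40 on 1250 samples.
Partial directed coherence is the original column-normalized magnitude
π_ij(f) = |Ā_ij(f)| / √(Σ_k |Ā_kj(f)|²) with
Ā(f) = I − Σ_r A_r e^(−i2πfr/fs) (generalized and squared variants are
config switches). |π| is averaged over a 0.5 Hz grid (0.5–45 Hz) within the
closed bands delta 1–4, theta 5–8, alpha 9–12, beta 13–30 Hz — grid points
between band edges belong to no band — then over the 10 epochs. Inflow and
outflow of a region are the means of the band matrix over its off-diagonal
row and column respectively (means, not sums, so values stay in [0, 1]
independent of region count).

Order 40 at 1000 Hz spans only 40 ms, marginal for delta; the default
pipeline therefore decimates region series to 250 Hz (zero-phase FIR
anti-aliasing) before fitting, keeping order 40 (160 ms of memory). A
`literal_fs` switch fits at the native rate instead.

**Graphs.** Band matrices are symmetrized by the elementwise max of the two
directions and binarized at a fixed edge density of 0.15 (proportional
threshold; deterministic tie-break by weight desc, then indices). Per node:
degree, cost = degree/(n−1), clustering coefficient, Latora–Marchiori local
efficiency on the neighbor-induced subgraph, betweenness normalized by
(n−1)(n−2)/2, and average path length over reachable nodes only with the
reachable fraction reported (never infinities). Density is a sweep
parameter (the threshold is the one genuinely unconstrained choice in the
chain; findings should be checked across 0.05–0.5).

**Statistics.** For each of the 8 measures × 4 bands, the SOZ-region values
of the two groups are compared with the two-sided Mann-Whitney/Wilcoxon
rank-sum test for independent samples: exact p by full enumeration of the
null rank distribution when the data are tie-free and both groups have ≤ 12
patients (always true at the target 10 vs 10 for the continuous measures;
integer-valued degree falls back to the tie-corrected normal approximation
with continuity correction). P-values are reported uncorrected, matching
the reporting convention the analysis mirrors; quartiles use linear
interpolation (type 7), boxplots the Tukey 1.5·IQR rule.

## Synthetic cohorts

Each patient is a 12-region MVAR(2) ground-truth network. Diagonal blocks
are damped AR(2) resonators (pole radius 0.90) tuned round-robin to 2.5,
6.5, 10.5, 21.5 Hz, so every analysis band has spectral content; the SOZ
(and, for the isolated archetype, its cluster) is tuned to 2.5 Hz so the
SOZ-related contrast lives in the delta band. Cross-couplings are lag-1
edges in one of two archetypes:

* `isolated_soz` ("seizure-free"): one weak edge into the SOZ (gain 0.08),
  strong edges from the SOZ into two cluster members (0.30), and a dense
  tournament among the SOZ-adjacent cluster (0.35) — a structured,
  well-clustered epileptic network;
* `diffuse_soz` ("non-seizure-free"): strong edges into the SOZ from every
  feeder region (0.35) and out to every receiver (0.30), no cluster — an
  extensive, scattered network.

A sparse random background (density 0.15, gain 0.10) connects non-SOZ
regions. Two construction choices matter and were made for structural
reasons:

1. **Acyclic coupling graphs.** All couplings respect a random topological
   order with the SOZ in the middle (feeders before, receivers after). The
   companion spectrum of an acyclically coupled system equals the diagonal
   oscillator poles exactly, so stationarity holds by construction and the
   configured gains survive verbatim. This is not cosmetic: low-frequency
   AR(2) resonators have nearly defective pole pairs whose eigenvalues move
   like √ε under a feedback coupling of size ε, so cyclically coupled
   versions of these networks are only stable after couplings are scaled
   down to the point of erasing the group contrast. (The spec'd geometric
   down-scaling loop — factor 0.95, margin 0.97, 200 iterations — remains
   as a guard for user-supplied cyclic configurations.)
2. **Innovation-scale coupling injection.** Each coupling coefficient is
   g/σ_j, where σ_j is the source's stationary standard deviation (from the
   companion-form discrete Lyapunov equation, three fixed-point passes), so
   each edge injects at the same scale as the receiver's unit innovations.
   Unnormalized resonator chains amplify variance multiplicatively (three
   hops reach 10⁹×), after which no single sensor-noise level is fair to
   all regions. The alternative — renormalizing the finished model to unit
   channel variances — provably cancels the inflow contrast itself, since
   it divides all edges into a region by exactly the variance its inflow
   created.

Region series are mixed to 64 sensors (256 available by config) through a
synthetic lead field — i.i.d. Gaussian topographies with random depth
factors in [0.5, 1.6] and random orientation signs, three sources per
region sharing the region course up to sign — plus white sensor noise at
10 dB SNR by default. Blink-like (1 Hz Gaussian bumps) and ECG-like (1.2 Hz
biphasic spikes) transients are injected on fixed random topographies in
two flagged one-epoch segments, with the reference traces stored alongside,
so artifact removal can be tested against known ground truth. Per-patient
seeds spawn deterministically from the cohort seed; a cohort is a pure
function of its spec.

**What the generator does not emulate.** Real head geometry and volume
conduction (the lead field is statistical, not biophysical), 1/f broadband
background, non-Gaussian neural dynamics, interictal discharges, nonlinear
or nonstationary coupling, and realistic artifact topographies. Passing
tests demonstrate that the estimation chain recovers known linear directed
structure through mixing and noise — not that the clinical effect itself is
reproduced.

## Verification studies and problem sizes

Three seeded studies exercise the full chain end to end; their sizes are
the package's desk-scale choices (single core, minutes):

* **Direction recovery**: bivariate truth, both channels tuned to the band
  center, one lag-1 coupling 2→1 (0.25); 10 epochs × 5 s at 250 Hz, order
  40; 100 replicates. Success = band-averaged PDC(2→1) > PDC(1→2).
* **Type-I calibration**: 200 null cohorts (isolated archetype in both
  groups) at reduced settings — 128 Hz, 24 sensors, 2 sources/region,
  order 8 — 10 vs 10 patients, 10 × 5 s epochs. The rank-sum test is
  distribution-free, so its size does not depend on the spectral settings;
  the reduction buys replicates.
* **Group contrast**: 100 cohorts at the target shape — 12 regions, 10 vs
  10, 10 × 5 s, 64 sensors, order 40 — generated directly at the 250 Hz
  analysis rate (all signal content lies below 45 Hz; generating at
  1000 Hz and decimating is spectrally equivalent here). Recorded: the
  rate of significantly lower delta-band SOZ inflow in the seizure-free
  archetype, and the direction of the delta clustering / local-efficiency
  contrast.

## Numerical choices

* Nuttall-Strand innovation covariance: symmetrized, with eigenvalues
  clipped at 1e-10 of the largest — at order 40 the recursion can leave
  eigenvalues a hair negative.
* PDC normalization is exact by construction; the identity Σ_i π_ij² = 1 is
  asserted to 1e-8 over random stable models.
* Proportional thresholding breaks ties deterministically (weight desc,
  then row, then column index); nested-threshold monotonicity holds for
  distinct weights.
* Exact rank-sum enumeration is used up to group size 12 (C(24,12) ≈ 2.7M
  assignments via scipy's exact method); beyond that, or under ties, the
  tie-corrected continuity-corrected normal approximation.
* EDF output uses the standard affine 16-bit mapping; round-trip error is
  bounded by (physical range)/65535 per sample.
* MVAR simulation discards 500 burn-in samples; identical seeds give
  bit-identical cohorts.

## Known limitations

* PDC magnitudes are column-normalized shares of outflow, not coupling
  strengths; inflow contrasts therefore depend on how many edges feed a
  region and on the source regions' other outflows. The archetypes are
  designed with this in mind (see above).
* Order-40 fits on 1250 samples are heavily overparameterized; off-diagonal
  PDC has a nonzero noise floor (visible as the seizure-free group's inflow
  level in the contrast study, whose medians the acceptance script
  reports). Group contrasts must clear this floor; weak-coupling regimes
  will not.
* The wMNE inverse is evaluated with well-conditioned synthetic lead
  fields; realistic EEG crosstalk between neighboring cortical regions (and
  thalamic sources in particular) is far less benign.
* Observation noise biases MVAR estimates toward weaker apparent coupling
  (a VAR plus additive noise is an ARMA process, which a pure AR fit can
  only approximate); sensor SNR therefore compresses estimated group
  contrasts, and very low SNR would erase them.
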