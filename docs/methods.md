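# Methods

`calnet` analyses somatic calcium time series recorded from acute cortical
slices (neuron × frame fluorescence matrices sampled at a few Hz, each
neuron annotated with a normalized cortical depth) and infers how the
functional network among those neurons evolves around a hyperexcitability
stimulus. This note documents the model behind each stage, the tunable
parameters and their defaults, what the synthetic-data generator does and
does not emulate, and the numerical choices that shape edge cases.

## Preprocessing

Raw fluorescence `F` is converted to a relative change
`ΔF/Fmin = (F − Fmin)/Fmin` per neuron, with `Fmin` the trace minimum
(a lower percentile, e.g. the 5th, is available for noisy data where the
minimum is a noise excursion). Traces whose `Fmin` is non-positive cannot
be expressed as a relative change and are excluded with a named error —
never silently shifted.

The normalized trace is low-pass filtered with a third-order Bessel filter
(unit DC gain, −3 dB at the cutoff). The default cutoff is **0.5 Hz** at
the 3.3 Hz frame rate: somatic calcium transients with ~0.3 s rise and
~2 s decay concentrate their energy well below 0.5 Hz, while frame-rate
noise sits above it. The filter is applied forward–backward by default
(zero phase), so transient onsets are not delayed at the cost of squaring
the magnitude response; a causal single pass is available. Photobleaching
is then removed by fitting an ordinary least-squares line over the whole
trace and subtracting the slope term (the intercept is preserved, so an
exactly linear trace becomes constant at its intercept). An option
restricts the fit to baseline plus late-washout frames for recordings
whose stimulus response is large enough to bias the global fit.

A note on re-application: this pipeline is not idempotent, and cannot be.
Re-normalizing a processed trace is undefined (its minimum is ~0), and any
smooth filter re-attenuates whatever transition-band energy survived the
first pass (|H|² ≠ |H|); only the detrending step is truly idempotent.
The test suite asserts exactly that decomposition.

### Neuron selection

A neuron enters the network analysis only if it reacts to both stimuli and
is active throughout. Band power (see below) is computed over sliding
baseline sub-segments whose length matches the 30-s stimulus (50 %
overlap), giving a per-neuron baseline power distribution with mean, SD
and max. Under the default rule a neuron is *responsive* to a stimulus if
its stimulus-interval band power exceeds `baseline mean + k·SD` with
`k = 2`. The source description of this threshold ("two standard
deviations from the maximum power value") is ambiguous about the anchor;
the literal maximum-anchored variant (`baseline max − k·SD`) is available
via configuration and the applied rule is recorded in the selection
report, because this silent gate shapes every downstream result. Retained
neurons are responsive to both the pilocarpine and the KCl stimulus and
have non-zero variance in every stage (baseline, stimulus, washout, KCl);
per-neuron exclusion reasons are logged.

## Spectral analysis

Per-neuron power spectra use Welch's method: 256-sample Hann-tapered
segments with 50 % overlap, one-sided density convention (parameters
configurable and echoed into outputs). The scalar summary is **total band
power** — the integral of the PSD over the band — expressed in dB re
1 (ΔF/F)², i.e. `10·log10(∫PSD df)`; peak PSD is available as an
alternative summary. A zero trace is reported as silent (−∞ dB sentinel)
and excluded from maps with a count.

Recordings are split at the stimulus onset into a basal and a
post-stimulus period; the post period can be subdivided into consecutive
150-s windows (`floor(duration/150)` of them). Depth-resolved power is a
2-D histogram over (normalized depth, dB power) with 0.1 depth bins and
1 dB bins by default, normalized to the number of contributing neurons so
cells read as proportions. Group contrasts on dB values use two-sided
two-sample t-tests.

## Connectivity inference

The recording is cut into five consecutive 150-s windows starting at
frame 0 (495 frames each at 3.3 Hz); the first is the pre-stimulus
"before" window. Interval labels are half-open frame ranges, resolving the
1-s inconsistency in the usual "0–150 s / 151–300 s" bookkeeping.

Within a window, pairwise coupling is Spearman's ρ (average ranks for
ties). Significance is assessed against **spectral surrogates**: synthetic
signals that keep each trace's Fourier amplitude spectrum bin for bin but
draw each inner frequency bin's phase, with replacement, from the pooled
empirical phases of all the window's real signals at that bin (DC and
Nyquist kept verbatim; conjugate symmetry by construction, so surrogates
are real, of identical length, amplitude spectrum and variance). Pooling
is per frequency bin — pooling across bins would bleed low-frequency
phase structure into other bands. Because both endpoints draw from the
same empirical pool, surrogate pairs carry a structural positive
correlation bias of order `1/N_pool`; it is absorbed by centring on the
null mean and is negligible at study-scale populations (N ≳ 100).

Each pair gets a null of `n = 1000` correlations between the k-th
surrogate of each endpoint (paired mode). A pooled mode shares one
window-wide null across pairs for very large populations; the mode is
recorded in the output. A pair is a *candidate* connection when
`|ρ − μ_null| > 2·σ_null` (two-sided: strong negative co-fluctuations
count; a positive-only mode exists for sensitivity analysis). Candidates
are refined by Benjamini–Hochberg FDR at `q = 0.05` over all `N(N−1)/2`
pairs of the window; the final mask is always a subset of the 2-SD mask.

The p-value fed to BH defaults to the two-sided Gaussian tail of the null
z-score `(ρ − μ_null)/σ_null`. The add-one empirical tail proportion
`(1 + #{|null−μ| ≥ |ρ−μ|})/(n+1)` is also computed and stored, but its
resolution floor of `1/(n+1) ≈ 10⁻³` makes step-up correction degenerate
for small populations: with 40 neurons (780 pairs) BH at `q = 0.05` can
never reject fewer than 16 simultaneous discoveries at that floor. The
Gaussian-tail default matches the mean/SD summary the 2-SD rule itself
uses; `p_mode="empirical"` restores the literal empirical p.

A connection is a pair surviving FDR; the per-window functional network is
the resulting unweighted undirected graph with the signed ρ kept as edge
metadata and the neuron depth as a node attribute.

## Network metrics and group statistics

Per window: mean local clustering coefficient (nodes with degree < 2
contribute 0), global efficiency (mean inverse shortest-path length over
ordered pairs, 0 for unreachable — the standard concrete reading of
"efficiency of communication"), and degree assortativity (Pearson
correlation of endpoint degrees over edges). Assortativity of degenerate
graphs (all endpoint degrees equal, e.g. cycles) is reported as missing,
never as zero, and excluded from models.

Node degree is resolved along depth in 0.1 steps, **relative to the basal
window as a difference** `k − k_basal` (a ratio mode exists but basal
zero-degree bins make ratios unstable, hence the default). Inter-layer
contrasts count significant connections per unordered depth-bin pair per
subject — raw counts, with mean bin occupancy reported alongside rather
than dividing by it — and compare groups with two-sample t-tests and
Cohen's d (pooled, (n−1)-weighted SD). Group-level tests always aggregate
to one value per subject first to avoid pseudo-replication across
neurons; pooled-cell tests appear only where noted in morphometry.

Metric evolution over windows is compared between groups with a linear
mixed model: fixed effects for group and window, a random intercept per
subject, maximum-likelihood fits, and likelihood-ratio tests of the full
model against the model without the effect in question (statistic referred
to χ² with df = number of dropped fixed-effect parameters). Two numerical
caveats: (1) the optimizer walks a fallback chain
(lbfgs → bfgs → powell → cg → nm) because the default optimizer's post-fit
Hessian inversion can fail after the likelihood has converged; only if all
fail does the test fall back to a flagged ordinary-least-squares
comparison. (2) The χ² reference is asymptotic in the number of subjects:
at 6 subjects per group the LRT is mildly anticonservative (empirical
α ≈ 0.10 at nominal 0.05), approaching nominal by ~12 per group. The test
suite calibrates type-I error at 12 subjects/group and power at 6.

## Morphometry

A soma outline polygon is reduced to its moment-equivalent ellipse: the
area is the shoelace area (exact) and the axes derive from the eigenvalues
of the interior's central second-moment matrix (for a solid ellipse these
are (semi-axis)²/4). Shape is summarized as
**roundness = 4·area/(π·major²)**, the convention of the common ROI
analysis tools, which equals minor/major for an exact ellipse; circularity
`4π·area/perimeter²` is offered but never default, and the convention used
is recorded in output metadata. Normalized depth projects the centroid
between two annotated boundary polylines (white matter → 0, pia → 1) via
nearest-point distances, `d_wm/(d_wm + d_pial)`; centroids outside the
band are clamped to the boundary they lie beyond and flagged. Density
profiles are per-subject depth histograms summarized as across-subject
mean ± SE. Zone comparisons t-test area and roundness over the pooled
cells of each group within Zone I (depth 0.7–0.9) and Zone II (0.2–0.5);
a subject-level alternative is provided for users worried about
pseudo-replication in pooled tests.

## The synthetic-data generator

The generator exists so that every stage above is testable against a known
ground truth. It emulates: several hundred neurons spanning the full
depth axis; a 750-s session at 3.3 Hz with 3 min of baseline, a 30-s
stimulus at 180 s and a 30-s KCl stimulus placed at 700 s (compressed into
the analysed segment so the KCl responsiveness gate is exercisable);
transients as Poisson events convolved with a unit-peak
difference-of-exponentials kernel (rise 0.3 s, decay 2 s — typical somatic
indicator kinetics); per-neuron amplitudes drawn unimodally or as a
two-component mixture (component stored in ground truth); linear
photobleaching (−0.002 units/frame on a baseline of 100); additive
Gaussian noise (SD 1). Defaults: baseline event rate 0.05 events/s, a ×6
rate gain inside stimulus intervals (scalar or per-neuron so depth-varying
phenotypes can be emulated). All randomness descends from one seed through
`SeedSequence` spawning; sub-seeds are logged in the ground truth, and
fixed seeds give bit-identical outputs.

**Connectivity ground truth is defined at the co-fluctuation level**: a
true edge is a per-edge common Poisson stream (default rate = the baseline
rate) injected into both endpoints with amplitude scaled by the edge
strength. This matches what correlation-based inference can possibly
recover. Two consequences matter for recovery experiments. First, a neuron
carrying several edges splits its co-fluctuation among partners, so such
edges are weaker than their nominal strength; the planted-edge recovery
experiment therefore plants a *matching* (disjoint edges). Second, at the
baseline rate a 150-s window holds only ~7 shared events and Poisson
thinning can leave 2–3 — undetectable by any method; "strong drive" in the
recovery experiment means strength 10 with a 0.2 events/s common stream.
Layered networks come from a stochastic block model over equal-width depth
bands (`p_intra` within, `p_inter` across); real laminar widths are out of
scope.

The ROI generator produces ellipse outlines (24 vertices, random
orientation) with lognormal area (mean 120 µm², log-SD 0.2) and clipped
normal roundness (0.7 ± 0.12), centroids uniform in depth inside a
500 × 1000 µm field bounded by straight white-matter and pial lines.
The log-SD of 0.2 reflects the within-region spread of soma areas and
makes a +15 % Zone-I area effect correspond to d ≈ 0.7 — detectable at
p < 0.01 with ~120 cells per zone per group with power ≈ 0.998, so the
planted-effect recovery property is testable at 600 cells/group.

What the generator does **not** emulate: biophysical membrane dynamics,
spatially structured (pixel-level) imaging, neuropil contamination, motion
artefacts, non-linear indicator saturation, non-linear bleaching, or
realistic laminar density profiles. Passing tests therefore demonstrate
that the analysis recovers what it claims under its own data model — not
that the model captures every property of real recordings.

## Problem sizes used in verification

The shipped verification suite runs at desk scale: null calibration uses
60-neuron windows over 20 replicates (10 in the acceptance script), edge
recovery 40 neurons with 10 planted edges, morphometry 600 cells/group
(100 planted-effect replicates in tests, 50 in the script), mixed-model
calibration 200 null and 100 power replicates. These sizes give
Monte-Carlo standard errors comfortably inside the asserted bounds while
keeping a full run in minutes on one core.

## Known limitations

- The surrogate null conditions on each trace's amplitude spectrum but not
  on higher-order structure; heavy-tailed transient trains make the null
  wider than an i.i.d. null (a feature — it protects against
  autocorrelation-induced false positives — but it costs sensitivity for
  weak edges).
- The empirical-p mode is only meaningful when the expected number of true
  connections is large relative to `n_pairs·q/n_surrogates`.
- Bleach correction is linear; strong non-exponential bleaching leaves
  residual trends.
- The mixed model assumes a random intercept only; random slopes over
  windows are out of scope.
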