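# Methods

This note documents the models, estimators, parameter choices, and known
limitations of `meiohic`. It covers what each stage computes, what the
synthetic generator does and does not emulate, and the numerical decisions
taken where the underlying methodology was genuinely open.

## Contact maps, balancing, and expected profiles

A contact map is a symmetric matrix of raw counts over a uniform bin grid
(0-based, half-open coordinates; BED semantics at all interfaces), stored
upper-triangular. Balancing is iterative correction (ICE): per-bin weights
`w` are iterated until every valid bin's balanced marginal
`w_i · Σ_j w_j c_ij` equals 1 within a relative tolerance (default 1e-5,
max 500 iterations). Bins with zero marginal, or with a nonzero marginal in
the bottom 2 % (`min_coverage_quantile`), are flagged invalid (NaN weight)
and excluded from every downstream mean. The quantile filter was chosen
over MAD-style filtering because it is simpler, monotone, and directly
testable on synthetic data; real Hi-C pipelines differ in this filter and
results near the coverage cutoff will too.

The cis expected profile is the per-chromosome mean balanced value over all
valid bin pairs at each bin distance (zeros included; no pooling across
chromosomes; no chromosome-arm splitting — mouse chromosomes are
acrocentric). The trans expected is a scalar per chromosome pair: the mean
balanced value over all valid cross pairs. Observed/expected views divide
element-wise and produce NaN (never infinity) at zero-expected distances
and invalid bins.

## Synthetic generator

The generator is an estimator test-bed, not a polymer model: every pixel is
an independent Poisson draw around an analytic expectation, scaled so each
chromosome (cis) or block (trans, homolog) carries a controllable expected
total ("depth"). All randomness flows from one seed; identical seeds give
byte-identical outputs.

**Cis kernel.** For a pair at separation s whose bins share compartment
class c,

    k_c(s) = s^α · (1 + A · exp(−(ln s − ln L_c)² / 2σ²)),

with mixed-class pairs taking the geometric mean of the two class kernels
and a plaid factor multiplying same-class pairs by (1+ε) and cross-class
pairs by (1−ε). The log-normal hump makes the log-log slope rise to an
interior maximum — the planted loop-array signature. Defaults: α = −1.2
(the long-range fractal-globule decay), A = 2.0, σ = 0.6. With this shape
the slope sits near −0.6 below the loop scale, reproducing the shallow
loop-array regime, and the slope maximum falls at ≈ 0.45 · L_c.

The **loop-size truth** is defined as the argmax of d log k / d log s
computed by dense evaluation on a 400-point log grid over 10 kb–10 Mb —
never as L_c itself, and never via the estimator under test.
`loop_scale_for_truth(target)` inverts the (scale-invariant) argmax/L_c
ratio so regimes can be specified by their planted loop size. Default hump
centers plant ≈ 560 kb (A) and ≈ 730 kb (B), the early-prophase regime in
which transcriptionally active regions carry shorter loops.

**Genome layout.** Alternating A/B segments with exponential lengths
(mean 3 Mb, minimum one bin). DSB hotspots are a per-class Poisson process
(defaults 6/Mb in A, 2/Mb in B); each DSB independently becomes a CO with
class-dependent probability (0.12 in A, 0.05 in B, giving a CO:DSB fraction
near the observed ≈ 0.1).

**Trans kernel.** With u, v the CEN→TEL normalized positions on two
chromosomes (CEN = coordinate 0, the acrocentric convention),

    p(u, v) ∝ μ · [1 + a · e^(−|u−v|/w) · (g_f(min(u,v)) + g_f(min(1−u,1−v)))],

where g_f(x) = 1 for x ≤ f and decays exponentially (scale 0.02) beyond.
This plants a diagonal alignment band confined to a fraction f of the
chromosome length at each end. Defaults a = 2, w = 0.05; f = 0.20 for the
wild-type-like regime and 0.05 for the LINC-mutant-like regime in which
only the chromosome tips stay associated.

**Inter-homolog kernel.** p(i, j) ∝ base + ρ_class(i) · e^(−s/100 kb) with
ρ_A = 2, ρ_B = 1, base = 0.01. The enrichment follows the row (homolog-1)
bin's class; inter-homolog blocks relate two distinct molecules and are not
forced symmetric.

**Planted-boundary maps.** A separate helper plants block domains on a
power-law background (cross-domain pairs depleted by a constant factor) for
insulation/boundary benchmarking.

What the generator does **not** emulate: loop-extrusion dynamics, coverage
bias and mappability structure, restriction-fragment granularity,
translocations, single-cell heterogeneity, or distance-dependent noise
beyond Poisson counting. Passing recovery tests therefore demonstrates
estimator correctness under the stated statistical model, not robustness to
every artifact of real libraries.

## P(s), slopes, and loop size

P(s) uses geometric distance bins with factor 1.12 starting at the bin
size; each bin's P is the mean balanced value over all valid pairs
(pair-count weighted across chromosomes) and its s is the pair-weighted
mean separation — exact for bins holding a single diagonal, which removes
midpoint bias from slope fits. Region-restricted curves (used for
compartment-class loop sizes) keep only pairs with **both** anchors inside
one and the same region, matching the > 2 Mb same-region restriction used
for class-resolved curves.

The slope is the centered finite difference of log P against log s on the
log-binned grid (no resampling), then loess-smoothed (local linear, tricube
weights, no robustifying iterations) at a configurable span. The span
default is 0.3; loop-size recovery holds across 0.2–0.4. The loop size is
the slope argmax within a search window, default 100 kb–5 Mb — below
100 kb the first distance bins carry discretization artifacts, above 5 Mb
pair counts thin out. A no-peak flag fires when the argmax sits on a window
edge or rises less than 0.02 above either window-edge slope value (pure
power laws otherwise register spurious maxima from numeric wobble).

## Insulation and boundaries

The insulation square for bin t covers rows [t−w, t) × cols [t, t+w) (w =
window / bin size, default window 500 kb at 10 kb bins). Including column t
makes the insulation minimum at a sharp two-domain junction unique. The
index is log2(square mean / chromosome mean of square means); squares with
more than 50 % invalid pixels, or within one window of a chromosome end,
are missing. Boundaries are local minima with prominence ≥ 0.1 (the noise
threshold used to retain prominent boundaries); prominence doubles as the
boundary strength. Prominence-based calling is this package's explicit
substitute for upstream callers' unstated defaults.

## Compartments

E1 is the leading eigenvector (Lanczos, k = 1) of the per-chromosome
observed/expected cis matrix minus its mean, with invalid bins removed.
The decomposition target was an open choice; the mean-centered obs/exp
matrix is the standard convention and is stated here as such. Signs are
fixed per chromosome so corr(E1, orientation) ≥ 0; the orientation track is
user-supplied (planted labels for synthetic data; transcription coverage or
GC content for real data). Constant matrices are flagged degenerate and
left uncalled.

Segmentation takes maximal same-sign runs (missing bins break runs) and
filters by strict length (> 1 Mb or > 2 Mb depending on the analysis).
A1/A2/A3 stratification ranks A segments > 1 Mb by their mean balanced
contact at exactly 500 kb separation (both anchors in-segment), ties broken
by genomic order, and cuts into three near-equal-count groups with
remainders assigned to the earlier (higher) groups. Saddle plots rank
defined bins into E1 quantile groups and average cis obs/exp per group
pair; the corner summary is (mean AA + mean BB)/(2 · mean AB).

## Pileups

Pairwise pileups average obs/exp windows centered on same-chromosome site
pairs separated by 500 kb–2 Mb; shifted controls (default 10 per pair)
translate both anchors by a uniform ±[flank, 10·flank] shift, preserving
separation and chromosome, rejection-sampled to stay on-chromosome, and the
normalized pileup is the element-wise ratio. Local pileups average
on-diagonal windows. Window quantifications sum balanced signal over the
square window ("total") or over the pairs between the site bin and every
bin within ±flank ("centerline": each site–partner pair counted once, so a
5 × 5 window of ones scores 5). Sites snap to the bin containing their
midpoint; missing pixels are excluded from means, never zero-filled.

## Hotspots and rank tests

DSB-containing 10 kb bins are CO-DSBs when they contain a CO hotspot
midpoint, NCO-DSBs when the nearest CO midpoint is > 100 kb away
(midpoint-to-midpoint — the anchor choice is symmetric and was otherwise
unspecified), and excluded in between. Shuffling preserves interval lengths
and chromosomes, places uniformly, and rejects overlaps. Region densities
count hotspot midpoints (avoiding edge double-counting) per Mb; CO/DSB
ratios are missing, not zero, for DSB-free regions. The negative-control
bin set can be derived by shuffling either the CO-containing bins or all
DSB bins; both are exposed because the convention is ambiguous.

The Mann–Whitney test uses midranks; p is exact (full enumeration of group
assignments, correct under ties) for combined n ≤ 20 and otherwise a
normal approximation with tie and continuity corrections. Enumeration
beyond n ≈ 20 is combinatorially infeasible, which fixed the switch point.

## Trans alignment and homolog scores

Sub-telomeric statistics average balanced trans signal per bin over 5 Mb
end windows for each autosome pair; CEN-TEL pools both cross orientations
(A-CEN×B-TEL and A-TEL×B-CEN — the aggregation was unspecified and pooling
is symmetric). Π = (CEN·CEN + TEL·TEL)/(2·CEN·TEL), missing when the
denominator is zero.

Averaged trans maps orient every pair's obs/exp block CEN→TEL, rescale to
500 × 500 by bilinear interpolation (cell-center convention, edge-clamped),
and average with equal pair weight, excluding missing pixels per-pixel.
The diagonal profile is the mean of the 21 × 21 square centered at each
diagonal bin (edge-truncated, not dropped), loess-smoothed at span 1/20.

The tract extent operationalizes "how far from the end does alignment
persist": baseline b = median of the central 20 % of the profile, end peak
p = max over the outer 5 %, threshold b + (p − b)/2, extent = largest
fraction of indices contiguously above threshold from that end (0 when
p ≤ b). The half-max-over-baseline construction is this package's
estimator for the qualitative end-tract readout; its parameters are
exposed. On the synthetic kernel it overestimates f by the half-max point
of the exponential shoulder, ≈ 0.014 + window smoothing, well inside the
±0.05 recovery tolerance.

The inter-homolog alignment score is the 21 × 21-windowed diagonal mean of
a homolog-pair block at 50 kb, normalized per pair so the mean defined
score is 1. A variant (`band100k`) scores each bin by its total signal to
partner bins within the diagonal band instead, since both definitions are
in circulation; the windowed form is the default. When recovering planted
per-class enrichment ratios, class means should be taken over bins whose
full window lies inside one class (`interior_margin` = window half-width):
windows straddling a class boundary mix the two enrichments and bias the
ratio toward 1, which is a property of the windowed score, not of the
underlying classes.

## Problem sizes and determinism

Recovery tests run at the regimes the estimators target: cis maps of
3 × 60 Mb chromosomes at 10 kb bins and 10⁷ contacts per chromosome for
loop-size recovery (5 seeds, truths 500 kb and 1.4 Mb); 50 kb bins and
plaid ε = 0.3 for compartment recovery; 5-chromosome genomes at 10⁷
contacts per trans block for tract extents f ∈ {0.20, 0.05}; a 60 Mb
homolog block at 10⁷ for score-ratio recovery; 24 Mb at 10 kb with
boundaries every 400 kb for insulation. These sizes make every stage's
statistical error small relative to its acceptance tolerance while keeping
the full suite to a few minutes. All stochastic stages take explicit seeds;
reruns are byte-identical.

## Known limitations

- Estimator behavior on real libraries (coverage bias, mappability holes,
  trans noise structure) is outside what the Poisson generator can
  certify.
- The loop-size estimate is quantized to the ×1.12 log grid (~12 %
  spacing); sub-grid precision would require curve interpolation, which is
  deliberately not done to keep the estimator faithful to the binned
  derivative definition.
- E1 sign orientation needs an informative orientation track; on
  chromosomes where the track is flat the sign is arbitrary.
- `stratify_A_regions` requires ≥ 3 A segments and near-equal-count groups;
  value-tertile splitting is not offered.
- The exact rank test enumerates group assignments and is limited to
  combined n ≤ 20; above that the normal approximation is used even under
  heavy ties.
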