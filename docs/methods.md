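# Methods

This note documents the statistical procedures implemented in `camtrapnet`,
the choices made where the methods literature leaves latitude, and what the
synthetic data generator does and does not emulate.

## Independence filtering

Camera traps re-trigger on a lingering animal, so raw records overcount
visits. Within each (site, species) group sorted by time, the first record
opens an event and each later record is merged into the current event if it
falls strictly inside 30 minutes of the *event's first photograph*; a record
at or beyond the boundary opens a new event (half-open window
`[start, start + 30 min)`). Measuring from the event start — rather than
from the previous record — keeps the rule order-deterministic and prevents a
slow stream of records from chaining into one indefinite event. Timestamps
are naive local time at minute precision; no time-zone or daylight-saving
arithmetic is applied (a single-locale study design). Species labels are
compared after whitespace normalisation and case folding; no taxonomic
resolution is attempted.

## Abundance screen

`RAI_i = 100 · n_i / Σ n_i` over independent events. The screen keeps
species *strictly above* the community mean (100/S): "exceeding the mean"
reads as strict, and the strict form makes the all-equal community select
nobody rather than everybody. No survey-effort (camera-day) correction is
applied; all sites are treated as equal sampling units. The bundled
community table's printed RAI column does not equal this percent-of-total
recomputation (its denominator is not recoverable from the table); the
package therefore treats that column as data and recomputes Eq-style RAI
only from counts.

## Breadth and overlap

Usage shares `P_ij` are computed from independent-event counts, since every
downstream analysis is defined on independent detections. Levins breadth
`B_L = 1/Σ P_ij²` ranges over `[1, r]` and Shannon breadth
`B_S = −Σ P_ij ln P_ij` over `[0, ln r]`, both maximised exactly at uniform
site usage; `0·ln 0` is taken as 0. Zero-event species are reported as
missing rather than zero. The Pianka index is the cosine of two usage
vectors, so it is scale-invariant and raw counts may be passed directly.

## Community variance ratio

`V_R = [(1/N) Σ_j (T_j − t̄)²] / [Σ_i p_i(1 − p_i)]`, the ratio of the
observed variance of per-site richness to its expectation if species
occurred independently; `W = V_R · N` is compared to the two-sided band
`(χ²_{0.95}, χ²_{0.05})`. The squared deviation in the numerator is part of
the definition (a variance); the statistic is non-negative and equals the
literal two-pass computation to machine precision (tested). The band's
degrees of freedom default to `N` (the number of sites), exposed as an
override: conventions in the applied literature vary (bands computed at
`N − k` for small k appear in published work without explanation), and the
choice shifts the band but not `V_R` itself. Species present at every site
or absent everywhere contribute zero to the denominator; a fully degenerate
matrix is an error.

## Pairwise association

From the 2 × 2 presence table, `φ = (ad − bc)/√((a+b)(a+c)(b+d)(c+d))`, and
the Yates-corrected chi-square with the numerator clamped at zero when
`|ad − bc| ≤ n/2`. The clamp is standard continuity-correction semantics:
without it the correction would *inflate* near-null tables. The
implementation matches `scipy.stats.chi2_contingency` (with and without
correction) to 1e-9 on random tables, and `φ²·n` equals the uncorrected
statistic identically. Significance classes use the df = 1 critical values
3.841 and 6.635 with strict inequalities; a statistic exactly at a boundary
falls to the lower class. Tables with a zero margin (a species everywhere
or nowhere) are reported as undefined with the cause, not silently dropped.
Association sign is the sign of `ad − bc`. No multiple-testing adjustment
is applied by default, matching the analysis design this package
implements; the pairwise table carries everything needed to apply one
downstream.

## Asymmetric lambda

Directional predictability uses the Goodman–Kruskal lambda: the
proportional reduction in error when predicting species B's presence state
from species A's, `λ_{B|A} = (max(a,b) + max(c,d) − max(a+c, b+d)) /
(n − max(a+c, b+d))`. Lambda is zero whenever knowing A does not change the
*modal* prediction of B — so it is deliberately insensitive to weak
marginal shifts and highlights genuine one-way dependence. The prediction
rate limits `L_B` (upper) and `λ_BO` (lower) come from a 1000-replicate
site-resampling bootstrap using the **basic** (reversed-percentile)
interval, widened if necessary to bracket the point estimate. The basic
form is the one whose lower limit can be negative for weak associations —
the behaviour reported in the applied literature for this quantity — which
a plain percentile interval of a [0, 1] statistic cannot produce. A
significant one-way dependence is declared when `λ_BO > 0`. A p-value from
the Yates chi-square of the same table is attached for reference; the
lambda bootstrap and the chi-square test answer different questions and
both are emitted.

## Diel activity

Clock times map to radians (`fraction of day × 2π`). Densities are von
Mises kernel mixtures. The kernel concentration follows Taylor's (2008)
plug-in rule `κ_bw = [3 n κ̂² I₂(2κ̂) / (4√π I₀(κ̂)²)]^{2/5}` on a
maximum-likelihood von Mises fit of the sample with the fitted κ̂ capped at
3 — the convention of the Ridout & Linkie overlap estimators — and an
`adjust` multiplier divides `κ_bw` (larger adjust = smoother). Scaled
Bessel functions (`ive`) keep the rule overflow-free at large κ.

The overlap coefficient is `Δ = ∮ min(f̂₁, f̂₂)`, evaluated by trapezoidal
quadrature on a 512-point equispaced circular grid (on an equispaced
periodic grid the trapezoid rule reduces to the mean); doubling the grid
changes Δ by < 0.005 on test pairs. The small-sample estimator Δ1
(adjust 0.8) is used when the smaller sample has fewer than 75 events, Δ4
(adjust 1.0) otherwise, following the estimators' source convention; the
threshold is exposed in the module. Both estimators here are grid-quadrature
forms differing in the adjust multiplier.

Confidence intervals use a smoothed bootstrap: each replicate redraws both
samples from their fitted kernel densities (data point plus von Mises
kernel noise) and recomputes Δ; the 2.5/97.5 percentile interval is
recentred by the bootstrap bias (basic-type correction) and clipped to
[0, 1]. Rhythm equality is assessed by a label-permutation test with
statistic `1 − Δ`, p = fraction of permuted statistics at or above the
observed one. No canonical equality test exists for this statistic; the
permutation test is a documented stand-in and is labelled as such in the
run manifest. All stochastic routines take explicit seeds and are
reproducible bit-for-bit.

## Network assembly

Nodes are the abundance-screened species with RAI, occupancy and breadth as
attributes. Undirected edges are pairs whose Yates chi-square reaches at
least the p = 0.05 class, carrying φ, χ², class and sign; significant
negative edges are retained and flagged rather than dropped. Directed edges
are lambdas with `λ_BO > 0`. Edges carry raw statistics only — layout is
presentation, not data. A config switch admits all tested pairs instead of
significant-only. Edge species missing from the node set raise an error
naming the offenders.

## Synthetic communities

The generator emulates a systematic camera grid observed over a study
window, in three layers:

* **Presence** — a Gaussian copula: one latent multivariate normal vector
  per site, species *i* present where its coordinate exceeds
  `Φ⁻¹(1 − ψ_i)`. Pairwise targets are specified either as latent
  correlations or as target φ values (inverted through the copula by root
  finding; unattainable targets — beyond the Fréchet bound for the given
  occupancies — are rejected). Jointly infeasible target matrices receive a
  nearest-PSD repair with a warning.
* **Counts** — per occupied site, a zero-truncated negative binomial
  (inverse-CDF truncation; size k, mean μ). Truncation guarantees every
  occupied cell yields at least one event, so the realized presence matrix
  equals the simulated one and planted associations are not eroded by
  zero-count cells. Large k recovers the Poisson limit.
* **Times** — event dates uniform over the study window, times of day from
  the species' von Mises mixture, all at minute precision. Event starts
  within a (site, species) are rejection-resampled to sit ≥ 31 min apart,
  so the 30-min independence filter provably recovers the planted events
  exactly; each event then receives Poisson-many extra records 1–29 min
  after its start to exercise the filter nontrivially.

The `paper_like` preset encodes a 67-site, 365-day, 12-species design with
heterogeneous occupancies (ψ 0.10–0.90), a bimodal crepuscular focal
species (activity peaks near 06:00 and 18:30), one strongly co-occurring
pair (muntjac–wild boar, target φ = 0.8, reflecting the near-total spatial
coincidence reported for the most-associated herbivore pairs in elephant
communities), one commensal pair (squirrel nested in the elephant's range:
ψ 0.75/0.55, latent ρ = 0.95), and an independent remainder. The commensal
strength was designed, via a replicate study, as the weakest configuration
whose one-way dependence is expressed (`λ_BO > 0`) in essentially all
67-site replicates while the reverse direction stays at λ ≈ 0; real
commensal signals can be much sparser (e.g. a squirrel occupying 14 of 67
sites) and would *not* be recoverable by lambda at this survey size — a
limitation of the statistic at small n, not of the generator.

What the generator does **not** emulate: spatially explicit landscapes and
autocorrelation between neighbouring cameras, imperfect detection
(occupancy-model style), seasonal or lunar structure in activity
(time-of-day is independent of date), and survey-effort variation between
sites. Passing tests on synthetic data therefore validate the statistical
machinery under the stated model, not robustness to those field realities.

## Calibration facts worth knowing

* Under independence the variance ratio averages 1 (tested, 500
  replicates), and the `W` band at df = N covers roughly 93–95% of null
  replicates at N = 67 — the chi-square reference for `W` is itself an
  approximation.
* The Yates-corrected pairwise test is intrinsically conservative at
  moderate sample sizes: at 67 sites its null rejection rate at the 3.841
  threshold is at most ≈ 2.8% (at balanced occupancy; lower for skewed
  occupancies), not the nominal 5%. That is the continuity correction
  doing its documented job, and it is why the `null_community` preset
  places all species at ψ = 0.5, the least-conservative operating point.

## Problem sizes

Default analysis settings: 512-point quadrature grid, 1000 bootstrap
replicates, 1000 permutations. The validation suites use 100–500 simulation
replicates at the study's 67-site scale, 200 random tables for oracle
comparisons, r = 200–5000 sites for parameter-recovery checks, and n = 500
events per species for density-accuracy checks — sizes at which Monte Carlo
noise is well inside the asserted tolerances.
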