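# Methods

`smdiv` estimates the secondary-metabolite (SM) potential of a fungal clade
from genome-mining summaries. Its inputs are outputs of upstream tools: a
BGC→GCF clustering table (BiG-SCAPE style), a BGC→genome/species map, a
bipartite BGC–SM link table (MIBiG style), and binary molecular
fingerprints. This note documents the models, the parameters that matter,
the numerical choices, and what the synthetic data can and cannot show.

## Incidence construction (`smdiv.incidence`)

The sampling unit defaults to the **species**; each GCF is scored
present/absent per unit, and multiple BGC copies of one family within a
unit collapse to a single presence. When several genomes share a species,
the lexicographically smallest `genome_id` is kept and the rest are logged —
a deterministic, reproducible deduplication. The only built-in record
filter is optional removal of contig-edge (truncated) clusters, off by
default: upstream filtering conventions vary, and inventing criteria here
would silently change richness. GCF identity must come from a single
clustering run at a single cutoff; mixing cutoffs changes the family
definition and hence every count downstream. Class labels are tallied as
opaque strings and never interpreted.

## Richness estimation (`smdiv.richness`)

Classical sample-based (incidence) machinery over T units with occupancy
counts Y_i and uniques/duplicates counts Q1/Q2:

* **Interpolation** uses the exact hypergeometric expectation
  E[S(t)] = S_obs − Σ_i C(T−Y_i, t)/C(T, t). Binomial coefficients are
  evaluated as log-gamma differences because quantities like C(135, 60)
  overflow direct floating-point evaluation.
* **Undetected richness** uses Chao2 with the (T−1)/T small-sample factor,
  switching to the bias-corrected branch Q1(Q1−1)/2 when Q2 = 0 (avoids
  division by zero; standard practice).
* **Extrapolation** to T + t* units uses
  S_obs + Q0̂·[1 − (1 − Q1/(Q1 + T·Q0̂))^t*], which is continuous with
  interpolation at t* = 0 and approaches the asymptote S_obs + Q0̂ from
  below. With Q1 = 0 the curve is flat at S_obs (saturation), not an error.
* **Confidence intervals** are percentile bootstrap, default 200
  replicates: the T sampling units are resampled with replacement, empty
  GCF columns are dropped, and the full curve is recomputed per replicate.
  This is assumption-light and treats the unit as the exchangeable object;
  analytic variance formulas for Chao2 exist but assume the frequency
  counts are the only source of noise. A seed is a required argument on
  every bootstrap path; identical seeds give bit-identical curves. For
  single-point estimates the percentile interval is clamped to bracket the
  point estimate, since at small replicate counts resampling bias can push
  both percentiles to one side of it.

Chao2 is a lower-bound-type estimator: it is approximately unbiased when
detectability is homogeneous across families and increasingly conservative
as detection becomes heterogeneous. Tests verify interpolation against
exhaustive subset enumeration (T ≤ 6) to 1e-9 and estimator recovery on the
homogeneous synthetic model below.

## Effective SMs per BGC (`smdiv.effective_sm`)

One SM linked to k BGCs contributes 1/k to each of them, so
effective(b) = Σ_{s∈SMs(b)} 1/k_s. **This down-weighting scheme is an
interpretation**: the intent (shared SMs should not be double-counted) is
clear, but other weightings exist. This one is the simplest and carries an
exact identity — the effective counts sum to the number of distinct SMs,
so the mean equals distinct SMs / BGCs — which makes it auditable from two
directions. Structural-variant compounds are distinct only if the input
lists them under distinct identifiers; no name normalisation is attempted
(that is curation, not computation).

## Projection (`smdiv.projection`)

The chain is B · N · r · m (BGCs per species × species × discovery ratio ×
effective SMs per BGC). Three choices make the printed scenario table
reproducible to the integer:

1. discovery ratios are carried as exact count pairs (4,463/6,972 and
   9,808/28,696), never as the rounded percentages 64%/34.2%;
2. all intermediates are exact `fractions.Fraction` rationals, with m
   parsed from its decimal string (1.57 means 157/100, not the nearest
   binary float);
3. rounding is half-away-from-zero and applied only to final display
   values, and the SM display value is always derived from the *unrounded*
   GCF value — rounding the GCF count first shifts the (B=50,
   Aspergillus-ratio) SM cell by one.

Defaults: B ∈ {30, 40, 50}, N = 85,000, both ratios, m = 1.57. No
uncertainty is propagated through the chain; the scenarios are point
projections by design.

## Structural diversity (`smdiv.chemdiv`)

d = 1 − mean Tanimoto similarity over all unordered distinct compound
pairs. Self-pairs are excluded: including the diagonal of 1s would deflate
d. The main path vectorises via one integer matrix product
(|A∪B| = |A| + |B| − |A∩B|); tests check equivalence with a brute-force
double loop. Empty fingerprints are rejected rather than scored — 0/0
similarity is undefined and silent conventions would corrupt d. The metric
is fingerprint-agnostic; the optional SMILES adapter (rdkit, Morgan radius
2, 2048 bits) is isolated and swappable because no particular fingerprint
is canonical for this statistic.

A subtle point: *adding an exact duplicate compound does not always lower
d*. Duplicating compound x adds one pair of similarity 1 plus copies of
x's existing similarities; if x is a structural outlier the dilution
outweighs the self-pair and d rises slightly. The provable monotonicity —
asserted in the tests — is for duplicating a compound whose total
similarity to the rest is at least the set average.

## Synthetic data (`smdiv.synthetic`)

Two incidence generators:

* **Truncated-Zipf model** (default): each of `s_true` families draws an
  occupancy from Zipf(α) truncated to {1..T} (heavy tail: few families in
  many species, most in one), occupied units chosen uniformly, each
  presence expanded to 1 + Poisson(λ) BGC records. The defaults are the
  observed *Aspergillus* summary conditions: T = 135 units, s_true = 4,463
  families, α solved by bisection so P(Y=1) equals the observed singleton
  fraction 3,607/4,463 (α ≈ 2.8389), and λ solved in closed form so the
  expected GCF:BGC ratio equals 4,463/6,972 (λ ≈ 0.0694, i.e. ~7% of
  presences carry a within-genome duplicate cluster). These two knobs are
  independent: α controls occupancy shape, λ the copy count, which is why
  both targets can be hit at once (mean ≈ 51.6 BGCs per species follows).
  Every family in this model has Y ≥ 1, so it exercises data *shape*, not
  detectability.
* **Homogeneous detection model**: each of `s_true` families is present in
  each unit independently with probability p; families missed by all T
  units are genuinely undetected. This is the regime where Chao2 is
  approximately unbiased, so it is the recovery target for estimator
  tests (T = 40, pool 300, p = 0.05 in the acceptance suite; the
  replicate-mean estimate must land within 5% of the pool and each
  estimate below 1.2× the pool — an asymmetric band, reflecting the
  estimator's lower-bound character).

The SM-table generator assigns each BGC 1 + Poisson(mean−1) compounds,
reusing a pooled compound with probability `sharing_prob`; the fingerprint
generator builds families around disjoint bit cores with per-member noise
controlled by `within_family_overlap`. All generators are pure functions of
their parameters and seed, and every emitted file re-read through the
package reproduces the recorded ground truth exactly.

**What passing these tests does not show:** real incidence data are
phylogenetically autocorrelated (close relatives share families), detection
is heterogeneous across BGC classes and assembly qualities, and real
occupancy need not be Zipf. The Zipf choice is a one-parameter stand-in
able to match the observed singleton fraction and heavy tail, nothing
more. Calibration tests therefore check realized summary statistics, not
distributional fit; estimator tests use the homogeneous model where the
estimator's own assumptions hold.

## Problem sizes in the default runs

The test suite uses T ≤ 6 matrices for the enumeration oracle (exhaustive
subsets are exact there), T = 40/pool 300 × 100 replicates for recovery,
and 20 seeds of the full default model (T = 135, s_true = 4,463) for
calibration; the whole suite runs in well under a minute. These sizes are
the package's chosen test conditions: the enumeration oracle is only
feasible at tiny T, and the calibration check at the full default size is
what the defaults claim to achieve.

## Known limitations

* Chao2 is a lower bound under heterogeneous detection; extrapolations far
  beyond ~2–3× the observed sample size lean on the asymptote and should
  be read as order-of-magnitude statements.
* The 1/k down-weighting is one defensible reading of "shared SMs count
  once"; the multiplier m changes under other schemes.
* The projection chain multiplies point estimates; no CI is attached to
  the projected totals.
* d depends on fingerprint type and length; comparisons are only
  meaningful within one fingerprint convention.
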