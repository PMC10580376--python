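# Methods

## Model and procedure

`airrshare` treats a repertoire as a set of unique receptors, each
identified by the triple (amino-acid junction, V call, J call). A cohort's
sharing structure is summarised by each sequence's *population incidence*
— the fraction of repertoires carrying it — and modelled conditionally on
*generation probability* (p_gen), the chance that V(D)J recombination
produces that sequence.

### Incidence models

An incidence model is a row-normalised table: rows are p_gen bins, columns
are incidence-fraction bins, entries the probability that a public sequence
of that p_gen class is shared at that level. Two components are kept:
`signal` (immune-state-associated sequences; incidence fractions computed
against the positive-class repertoire count) and `public` (all remaining
public sequences; fractions against the whole cohort). All bins are
half-open [left, right), the top incidence bin closed at 1; p_gen values
outside the binned range clamp to the first/last row.

Calibration places each unique public sequence (observed in ≥ 2
repertoires) into exactly one cell of exactly one component and normalises
rows. Sampling inverts this: draw an incidence bin from the row, a fraction
uniformly within the bin (maximum entropy; only the bin-level distribution
is modelled), convert to a repertoire count by rounding half up, clip the
count so its incidence fraction stays inside the drawn half-open bin
whenever the cohort size can represent that bin, and clamp to
[2, denominator] (a public sequence is by definition shared). The
within-bin clip matters: without it the top ~1/(2·width·denominator) sliver
of each bin rounds onto the next bin's left-closed edge, which both
violates the bin semantics and biases re-calibration; with it, the
calibrate∘simulate round trip is exact up to multinomial noise. It also
guarantees the cap invariant count ≤ floor(max_incidence_fraction ×
denominator) by construction. Queries against a p_gen row with no training
data borrow the nearest non-empty lower-p_gen row (conservative: lower
p_gen carries lower sharing), with a logged warning.

### Simulation stages

**Feasibility.** `required = round_half_up(n_positive × witness_rate)`
signal placements are demanded; each pool sequence can contribute at most
`floor(max_incidence_fraction(p_gen) × n_repertoires)` placements.
Infeasibility is reported with per-sequence caps and guidance before any
expensive stage runs. Sequences with p_gen = 0 under the active engine are
allowed in the pool but flagged with a zero cap — they can never be made
public under the model.

**Baseline.** Each repertoire is an i.i.d. sample from the recombination
engine with duplicates dropped until the target unique depth is reached;
inter-repertoire sharing arises only from convergent recombination.

**Public-component correction.** This stage generates its own fresh,
globally deduplicated sequence stream (it does not consume the baseline
artifact). Each new unique sequence becomes public with probability
`public_fraction`; public sequences get a carrying-repertoire count from
the public incidence model (denominator: cohort size) and are placed into
that many distinct repertoires; private sequences fill one slot each.
Per-repertoire depth is preserved exactly: public copies occupy slots
private sequences would otherwise take. Placement assigns each public
sequence to the repertoires with the greatest remaining capacity, breaking
ties uniformly at random. The greedy choice guarantees every sequence
receives its full drawn count (uniform random placement can strand
capacity at the end of the fill); because private slots provide slack,
ties dominate and the realized assignment is effectively uniform.

**Signal implantation.** `round(positive_fraction × n)` repertoires are
labeled positive uniformly at random. Pool sequences are visited in uniform
random order; each receives an incidence count from the signal model
(denominator: positive repertoires) and is placed into that many distinct
positive repertoires, replacing a private receptor in each so depth is
conserved. If the model draws fall short of the witness-rate budget, counts
are topped up round-robin toward the feasibility caps — the reading under
which a feasible report always implies the budget is reachable (model draws
alone expect far fewer instances than the cap-based achievable total).
Negative repertoires receive no implants and are deliberately not screened
for chance occurrences of signal sequences. Every placement is recorded in
the manifest. The realized total is expected within ±5% of the budget
(tolerance of this package's choosing).

A `naive_implant` mode provides the biased contrast: labels assigned the
same way, each positive repertoire receiving `round(witness_rate)` pool
sequences uniformly, no public correction.

### Audit statistics

For each public sequence: `p_obs = 1 − (1 − p_gen)^n_trials` (evaluated via
expm1/log1p; `n_trials` is the rounded arithmetic-mean unique repertoire
size), `p_count = P(X ≥ c)` for `X ~ Binomial(N, p_obs)` with N the
positive-class count (configurable to the whole cohort), and the outlier
score `−log10(p_count)`. Occurrences are counted over all repertoires
irrespective of label, so c can exceed N; the tail is then evaluated at
c = N (the score saturates at the all-N value). The survival probability is
computed by direct summation — first term from exact integer binomial
coefficients (largest factor multiplied first so intermediates never go
subnormal before the result does), remainder by recurrence — which holds
~1e-14 relative error in tail regimes where incomplete-beta routines drift
above 1e-12; cohorts beyond 10,000 repertoires fall back to the library
routine. Tails below ~1e-290 are recomputed fully in log space
(gammaln + logsumexp), so scores stay finite and exact far past double
underflow. The likelihood ratio is `(c_P/P)/(c_N/N)` with 0/∞ conventions
at zero counts and an optional ±0.5 pseudocount mode. Decision rules use
strict inequality (score > t).

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `n_repertoires` | — | cohort size (individuals) |
| `depth` / `depth_spread` | — / 0 | unique receptors per repertoire, ± uniform spread |
| `positive_fraction` | 0.5 | share of repertoires labeled positive |
| `public_fraction` | 0.10 | share of unique sequences made public (matches experimental cohorts) |
| `witness_rate` | 0 | mean signal sequences per positive repertoire; also reported per 10⁵ receptors |
| `n_signal_pool_used` | all | cap on pool sequences drawn |
| `engine` | `"toy"` | `"toy"`, a toy-model YAML path, or an external-engine model name |
| `seed` | 0 | master seed; every stage draws from a named substream |

Default p_gen bin edges are log10 = (−12, −9, −6), four bins of three
log-decades covering the dynamic range of receptor generation
probabilities; default incidence edges (0, 0.02, 0.05, 0.1, 0.2, 0.3, 1).
Both are configuration, not code.

## The toy engine and the bundled models

The toy generative model gives each receptor exactly one generation path —
junction = V prefix + i.i.d. middle + J suffix — so
`p_gen = p(V)·p(J)·p(len)·∏p(residue)` is exact and the full support is
enumerable, making every downstream contract testable without an external
engine. The default parameterisation (8 V prefixes, 4 J suffixes, middle
lengths 2–10, skewed residue usage) spreads sampled junctions over roughly
log10 p_gen −14…−4 so that all default p_gen bins are populated and rare
(low-p_gen) signal candidates exist.

The bundled incidence models in `airrshare/data/` are **synthetic**
fixtures, not calibrations on any experimental cohort. Their shapes mimic
what calibration on an antigen-experienced TCRβ cohort produces: the public
component concentrates below 2% incidence with a small highly shared tail,
and the signal component is shifted upward but never exceeds 30% incidence
(so the feasibility worked example's 30% cap holds in every p_gen row).
The public tail is the mechanism that makes corrected cohorts carry
non-signal outliers.

What the toy engine and fixtures do *not* emulate: nucleotide-level
recombination and true multi-path generation probabilities, biological
V/J usage and junction-length distributions, clonal frequencies (all
receptors are written with duplicate_count 1), somatic hypermutation and
BCR clonal lineages, paired chains, and dependence between signal or
outlier sequences within a repertoire. Passing tests therefore demonstrate
the correctness of the sharing/implantation/audit machinery and the
direction and approximate magnitude of the discordance-bias contrast — not
quantitative agreement with any experimental cohort; for that, calibrate
incidence models on real data and plug in the external engine.

## Numerical and design choices

- **Rounding**: fraction-to-count conversions round half up; publicness
  clamps counts to ≥ 2. Bin-edge products are snapped to integers within
  1e-9 before ceiling/floor, so edges like 0.02 × 500 behave exactly.
- **Randomness**: one master seed; each stage (baseline, public
  correction, labels/implantation, pools) uses a named CRC32-keyed
  substream, so stage reruns are independently reproducible and identical
  seeds give byte-identical output trees (provenance timings aside).
- **Determinism**: writers emit rows in sorted order; audit records sort
  by descending score with identity tie-break.
- **Degenerate inputs**: empty signal pools are valid at witness rate 0;
  incidence bins narrower than 1/denominator fall back to plain rounding;
  a signal sequence already present in a chosen repertoire is a no-op
  placement and the allocator draws another repertoire.
- **n_trials** is the arithmetic mean (simplest reading of "average")
  of unique repertoire sizes, rounded to nearest.
- **Stage iii input**: the public-component correction generates a fresh
  sequence pool rather than re-using the baseline artifact; the two-stage
  reading ("generate a large number of sequences, then make a share
  public") is the one implemented, and the baseline stage remains
  available as its own workflow mode.
- **Open denominator choice**: signal incidence uses the positive-class
  denominator by default; both calibration and audit expose a whole-cohort
  option.

## Problem sizes used in tests

The suite exercises the pipeline at desk scale, chosen to make sampling
noise small relative to the asserted tolerances: calibration recovery on a
500-repertoire × 2,000-sequence cohort (per-row total-variation distance
< 0.05 on rows with ≥ 500 training sequences); sharing/cap/depth
invariants on 200-repertoire cohorts (public share within ±1 percentage
point of the configured 10%); and the naive vs incidence-aware precision
ordering at 50 repertoires × 5,000 sequences over 10 seeds (≥ 9 must
preserve the ordering; the acceptance script reports the same contrast
over 5 seeds). The full-scale naive-bias demonstration at experimental
cohort size ships as `scripts/full_scale_naive_bias.py` and requires the
external recombination engine.

## Known limitations

Beyond the emulation gaps above: the incidence model treats sequences
independently given p_gen (no co-occurrence structure); calibration on
small cohorts inflates incidence estimates (the ≥ 2-repertoire publicness
floor truncates the low-incidence bins — visible in the test suite as a
monotone effect of cohort size), so models should be learned on as large a
cohort as available; the cap-based top-up during implantation means
realized signal incidence can sit between the signal model's draw and the
feasibility cap when witness-rate budgets are tight; and similarity-based
public-clonotype definitions (e.g. 85% identity for BCR) are out of scope —
identity is exact-match on (junction, V, J).
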