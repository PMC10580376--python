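"""Binomial outlier statistics and likelihood ratios for public sequences.

The audit quantifies "generation probability discordance": a public sequence
observed in far more repertoires than its generation probability warrants is
an outlier. The chain of computation per public sequence is

  p_obs   = P(seen at least once in a repertoire of ~n_trials unique
            sequences) = 1 - (1 - pgen)^n_trials
  p_count = P(X >= observed count) for X ~ Binomial(n_repertoires, p_obs)
  score   = -log10(p_count)

with the likelihood ratio LR = (c_P / P) / (c_N / N) comparing incidence
between the positive and negative class. In naively simulated cohorts, the
implanted signals are the only sequences with extreme scores — a shortcut
an ML model can exploit; in experimental (and incidence-corrected) cohorts,
many non-signal public sequences score just as high.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

from scipy.special import gammaln, logsumexp
from scipy.stats import binom

from .dataset import NEGATIVE, POSITIVE, RepertoireDataset
from .errors import ValidationError
from .receptors import Receptor

#: Tail probabilities below this are recomputed in log space to avoid
#: reporting an infinite score on underflow.
_UNDERFLOW = 1e-290

LN10 = math.log(10.0)


def prob_observed_in_repertoire(pgen: float, n_trials: int) -> float:
    """P(at least one success in *n_trials* Bernoulli(pgen) trials).

    Evaluated as ``-expm1(n * log1p(-pgen))``, which is accurate when
    ``pgen * n_trials`` is far below 1 (the typical regime for receptor
    generation probabilities against sequencing depth).
    """
    if not (0.0 <= pgen <= 1.0):
        raise ValidationError(f"pgen outside [0, 1]: {pgen}")
    if n_trials < 1:
        raise ValidationError(f"n_trials must be >= 1, got {n_trials}")
    if pgen == 0.0:
        return 0.0
    if pgen == 1.0:
        return 1.0
    return -math.expm1(n_trials * math.log1p(-pgen))


def outlier_tail_prob(p_obs: float, n_repertoires: int, observed_count: int) -> float:
    """Exact binomial survival probability P(X >= observed_count).

    X ~ Binomial(n_repertoires, p_obs): the null probability of seeing a
    public sequence in the same or higher number of repertoires than it was
    observed in. Deterministic; may underflow to 0.0 for extreme tails —
    use :func:`log10_tail_prob` in that regime.
    """
    if not (0.0 <= p_obs <= 1.0):
        raise ValidationError(f"p_obs outside [0, 1]: {p_obs}")
    if n_repertoires < 1:
        raise ValidationError(f"n_repertoires must be >= 1, got {n_repertoires}")
    if not (0 <= observed_count <= n_repertoires):
        raise ValidationError(
            f"observed_count {observed_count} outside [0, {n_repertoires}]"
        )
    if observed_count == 0:
        return 1.0
    if p_obs == 1.0:
        return 1.0
    if p_obs == 0.0:
        return 0.0
    n, k = n_repertoires, observed_count
    if n > 10_000:
        # large cohorts: the library's incomplete-beta evaluation is fine
        return float(binom.sf(k - 1, n, p_obs))
    # direct summation: the first term from exact integer binomials, the
    # rest by recurrence; this holds ~1e-14 relative error even in tails
    # where incomplete-beta implementations drift
    q = 1.0 - p_obs
    c = math.comb(n, k)
    if c > 1e306:
        return float(binom.sf(k - 1, n, p_obs))
    # multiply the large coefficient first: intermediates then never dip
    # into the subnormal range unless the final term itself does
    t = float(c)
    for _ in range(k):
        t *= p_obs
    t *= q ** (n - k)
    if t == 0.0:
        return 0.0
    terms = [t]
    ratio = p_obs / q
    for j in range(k, n):
        t *= (n - j) / (j + 1) * ratio
        terms.append(t)
        if t < terms[0] * 1e-20 and j + 1 > n * p_obs:
            break
    return float(min(math.fsum(terms), 1.0))


def log10_tail_prob(p_obs: float, n_repertoires: int, observed_count: int) -> float:
    """log10 P(X >= observed_count), evaluated fully in log space.

    Survives tails far below the smallest positive float (p_count < 1e-300).
    Returns ``-inf`` when the tail is exactly zero (p_obs = 0, count >= 1).
    """
    if not (0.0 <= p_obs <= 1.0):
        raise ValidationError(f"p_obs outside [0, 1]: {p_obs}")
    if not (0 <= observed_count <= n_repertoires):
        raise ValidationError(
            f"observed_count {observed_count} outside [0, {n_repertoires}]"
        )
    if observed_count == 0:
        return 0.0
    if p_obs == 0.0:
        return -math.inf
    if p_obs == 1.0:
        return 0.0
    n, k = n_repertoires, observed_count
    log_p = math.log(p_obs)
    log_q = math.log1p(-p_obs)
    terms = [
        gammaln(n + 1) - gammaln(j + 1) - gammaln(n - j + 1) + j * log_p + (n - j) * log_q
        for j in range(k, n + 1)
    ]
    return float(logsumexp(terms)) / LN10


def outlier_score(p_count: float) -> float:
    """-log10 of the binomial tail probability; 0 for p_count = 1.

    For tails that underflow to exactly 0.0 in double precision, compute the
    score from :func:`score_from_counts` instead of passing 0 here.
    """
    if not (0.0 < p_count <= 1.0):
        raise ValidationError(f"p_count must be in (0, 1], got {p_count}")
    return -math.log10(p_count)


def score_from_counts(p_obs: float, n_repertoires: int, observed_count: int) -> float:
    """Outlier score computed end-to-end in log space.

    Matches ``outlier_score(outlier_tail_prob(...))`` where the tail is
    representable, and stays finite (instead of overflowing to infinity)
    when it underflows. Counts are clamped to *n_repertoires*: occurrences
    are tallied over all repertoires while the null uses the positive-class
    denominator, so the observed count can exceed it.
    """
    k = min(observed_count, n_repertoires)
    p = outlier_tail_prob(p_obs, n_repertoires, k)
    if p > _UNDERFLOW:
        return -math.log10(p)
    lg = log10_tail_prob(p_obs, n_repertoires, k)
    return math.inf if lg == -math.inf else -lg


def likelihood_ratio(
    c_P: int, P: int, c_N: int, N: int, pseudocount: bool = False
) -> float:
    """Incidence-rate ratio (c_P / P) / (c_N / N) between the two classes.

    ``c_N = 0`` with ``c_P > 0`` returns +infinity (default mode);
    ``c_P = 0`` returns 0. With ``pseudocount=True``, 0.5 is added to both
    occurrence counts, keeping the ratio finite.
    """
    if P <= 0 or N <= 0:
        raise ValidationError("class sizes P and N must be positive")
    if not (0 <= c_P <= P) or not (0 <= c_N <= N):
        raise ValidationError("occurrence counts must lie in [0, class size]")
    if pseudocount:
        return ((c_P + 0.5) / P) / ((c_N + 0.5) / N)
    if c_P == 0:
        return 0.0
    if c_N == 0:
        return math.inf
    return (c_P / P) / (c_N / N)


@dataclass(frozen=True)
class AuditRecord:
    """Outlier statistics for one public sequence."""

    receptor_identity: tuple[str, str, str]
    pgen: float
    count_positive: int
    count_negative: int
    p_obs: float
    p_count: float
    outlier_score: float
    likelihood_ratio: float

    @property
    def count_total(self) -> int:
        return self.count_positive + self.count_negative


@dataclass
class AuditResult:
    """Audit records plus the header quantities they were computed against."""

    records: list[AuditRecord]
    n_trials: int
    n_repertoires: int  # the binomial denominator actually used
    n_positive: int
    n_negative: int
    denominator: str  # "positive" or "total"

    def to_rows(self) -> list[dict]:
        return [
            {
                "junction_aa": r.receptor_identity[0],
                "v_call": r.receptor_identity[1],
                "j_call": r.receptor_identity[2],
                "pgen": r.pgen,
                "count_positive": r.count_positive,
                "count_negative": r.count_negative,
                "count_total": r.count_total,
                "p_obs": r.p_obs,
                "p_count": r.p_count,
                "outlier_score": r.outlier_score,
                "likelihood_ratio": r.likelihood_ratio,
            }
            for r in self.records
        ]


def audit_dataset(
    dataset: RepertoireDataset,
    pgen_of=None,
    positive_label: str = POSITIVE,
    denominator: str = "positive",
) -> AuditResult:
    """Compute outlier statistics for every public sequence of a labeled cohort.

    Sequences are audited irrespective of their immune-state label:
    occurrences are counted over all repertoires, while the binomial
    denominator is the positive-class repertoire count (``denominator=
    "positive"``, the default) or the full cohort (``"total"``).
    ``n_trials`` is the arithmetic-mean unique receptor count per
    repertoire, rounded to the nearest integer.
    """
    if denominator not in ("positive", "total"):
        raise ValidationError(f"denominator must be 'positive' or 'total': {denominator}")
    positives = {r.repertoire_id for r in dataset.repertoires if r.label == positive_label}
    n_pos = len(positives)
    n_neg = dataset.n_repertoires - n_pos
    if n_pos == 0:
        raise ValidationError("dataset has no positive-labeled repertoires")
    n_trials = int(round(dataset.mean_unique_per_repertoire()))
    n_binom = n_pos if denominator == "positive" else dataset.n_repertoires

    counts_all: Counter = Counter()
    counts_pos: Counter = Counter()
    for rep in dataset.repertoires:
        counts_all.update(rep.receptors)
        if rep.repertoire_id in positives:
            counts_pos.update(rep.receptors)

    def lookup_pgen(rec: Receptor):
        if pgen_of is None:
            return rec.pgen
        if callable(pgen_of):
            return pgen_of(rec)
        return pgen_of.get(rec, pgen_of.get(rec.identity))

    public = [rec for rec, c in counts_all.items() if c >= 2]
    missing = [rec.identity for rec in public if lookup_pgen(rec) is None]
    if missing:
        raise ValidationError(
            f"{len(missing)} public sequences lack a generation probability; "
            f"first offenders: {missing[:5]}"
        )

    records = []
    for rec in public:
        pgen = float(lookup_pgen(rec))
        c_tot = counts_all[rec]
        c_p = counts_pos[rec]
        c_n = c_tot - c_p
        p_obs = prob_observed_in_repertoire(pgen, n_trials)
        k = min(c_tot, n_binom)
        p_count = outlier_tail_prob(p_obs, n_binom, k)
        score = score_from_counts(p_obs, n_binom, c_tot)
        lr = likelihood_ratio(c_p, n_pos, c_n, max(n_neg, 1)) if n_neg else math.inf
        records.append(
            AuditRecord(rec.identity, pgen, c_p, c_n, p_obs, p_count, score, lr)
        )
    records.sort(key=lambda r: (-r.outlier_score, r.receptor_identity))
    return AuditResult(records, n_trials, n_binom, n_pos, n_neg, denominator)


@dataclass(frozen=True)
class PrecisionRecall:
    """Confusion counts and derived rates for one score threshold."""

    precision: float
    recall: float
    tp: int
    fp: int
    fn: int
    n_calls: int
    truth_empty: bool


def threshold_precision_recall(
    records: list[AuditRecord],
    truth: set,
    threshold: float,
) -> PrecisionRecall:
    """Evaluate the decision rule "call iff outlier_score > threshold".

    *truth* holds receptor identities (triples) of true signal sequences.
    Recall is taken over ``truth`` intersected with the audited sequences;
    precision is 0 when nothing is called, recall is 1 when that
    intersection is empty (flagged via ``truth_empty``).
    """
    if not math.isfinite(threshold):
        raise ValidationError("threshold must be finite")
    truth = {t.identity if isinstance(t, Receptor) else tuple(t) for t in truth}
    audited = {r.receptor_identity for r in records}
    truth_in_scope = truth & audited
    calls = [r for r in records if r.outlier_score > threshold]
    tp = sum(1 for r in calls if r.receptor_identity in truth_in_scope)
    fp = len(calls) - tp
    fn = len(truth_in_scope) - tp
    precision = tp / len(calls) if calls else 0.0
    recall = tp / len(truth_in_scope) if truth_in_scope else 1.0
    return PrecisionRecall(
        precision, recall, tp, fp, fn, len(calls), not truth_in_scope
    )
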