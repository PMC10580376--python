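# airrshare

Simulation of adaptive immune receptor repertoire (AIRR) cohorts with
realistic interindividual receptor sharing, and auditing of the
*generation-probability discordance* bias that naive simulations leave in
machine-learning benchmark datasets.

## The problem

Benchmarking repertoire-level immune-state classifiers needs simulated
cohorts with known receptor-level ground truth. The common recipe — sample
repertoires from a V(D)J recombination model, then plant signal sequences in
the positive class — produces *naive* cohorts in which public sequences
(those shared by more than one individual) arise only through convergent
recombination, so their population incidence is fully explained by their
generation probability (p_gen). The implanted signals then stand out as the
cohort's **only** statistical outliers, and a classifier can reach
benchmark-winning scores by keying on that artifact instead of the intended
signal — shortcut learning. Real antigen-experienced cohorts do not look
like this: they carry many highly shared sequences whose incidence far
exceeds what p_gen predicts.

`airrshare` is for researchers building or evaluating AIRR-ML methods. It
(i) simulates cohorts whose public-sequence sharing follows empirically
calibrated distributions of population incidence conditional on p_gen,
separately for signal and background sequences, and (ii) quantifies the
bias with the statistics that expose it.

## The statistics at the core

For every public sequence, with generation probability p_gen and the
average unique repertoire size n as the number of trials:

- probability of being seen at least once in one repertoire:
  `p_obs = 1 − (1 − p_gen)^n`
- probability of appearing in at least the observed number of repertoires
  under binomial sharing across the N positive-class repertoires:
  `p_count = P(X ≥ c), X ~ Binomial(N, p_obs)`
- **outlier score** `= −log10(p_count)` (computed in log space; survives
  p_count far below 1e-300)
- **likelihood ratio** `LR = (c_P / P) / (c_N / N)` comparing incidence
  between the positive and negative class.

The simulator runs in four stages: (i) *feasibility* — with
`required = round(P × witness_rate)` signal placements demanded and each
pool sequence capped at `floor(max_incidence_fraction(p_gen) × n_repertoires)`
placements, is the witness rate reachable at all; (ii) *baseline
generation* from a recombination engine; (iii) *public-component
correction* — a configurable share (default 10%) of unique sequences is
made public with carrying-repertoire counts drawn from the incidence model;
(iv) *signal implantation* into positive repertoires under the signal
incidence model, with every placement recorded in a ground-truth manifest.

A built-in toy recombination engine with exactly enumerable generation
probabilities makes the whole pipeline testable hermetically; an adapter
exposes the same contract for the external `olga` engine (models humanTRB,
humanTRA, humanIGH, mouseIGH) when installed. The bundled incidence models
are synthetic fixtures shaped like calibrations on antigen-experienced
TCRβ cohorts; `airrshare.calibrate` learns real ones from your data.

## Worked example

Feasibility first (`examples/01_feasibility_check.py`): a pool of 3 signal
sequences, 200 repertoires of which 100 are positive, witness rate 5:

```
required signal instances:   500
achievable signal instances: 180
feasible: False

INFEASIBLE: short by 320 instances. Supply a larger signal pool (roughly 9
sequences at similar pgen) or lower the witness rate.
```

500 is 100 positives × 5 per repertoire; 180 is 3 sequences × floor(0.3 ×
200) placements each under the 30% incidence cap — so this design can never
reach its witness rate, reported before any expensive stage runs.

The bias contrast (`examples/03_audit_discordance_bias.py`), same cohort
conditions (50 repertoires × 5,000 unique sequences, witness rate 5,
matched 25-sequence low-p_gen pool) under both simulation modes, rule
"signal iff outlier score > 35":

```
naive           :  10628 public sequences audited, score>35 precision 1.0000, recall 0.60 (15 calls, 15 true)
incidence-aware :  21840 public sequences audited, score>35 precision 0.0400, recall 0.72 (450 calls, 18 true)
```

In the naive cohort every called sequence is an implanted signal
(precision 1.00): the outlier score alone recovers the ground truth, which
is exactly the shortcut a model can exploit. In the incidence-aware cohort
hundreds of background public sequences score just as high and precision
collapses to 4% at similar recall — as in experimental cohorts, being an
outlier no longer identifies the signal.

Other entry points: `examples/02_simulate_cohort.py` (full pipeline to
AIRR TSVs on disk), `04_build_signal_pool.py` (reference-pool generation
and k-mer pattern queries), `05_calibrate_incidence_models.py` (learning
incidence models from a cohort). A thin CLI mirrors the stages:
`airrshare feasibility|baseline|public-correct|full|audit|pool-query|calibrate`.

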