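"""Assess whether a desired witness rate is achievable before simulating.

Builds the illustrative small-numbers scenario: a pool of 3 candidate signal
sequences, a 200-repertoire cohort with 100 positives, and a desired witness
rate of 5 signal sequences per positive repertoire. Under an incidence model
that caps any signal sequence at 30% population incidence, only
3 x floor(0.3 x 200) = 180 signal instances can ever be placed, against the
100 x 5 = 500 the witness rate demands — infeasible, with guidance printed.
"""

import airrshare as a

config = a.SimConfig(
    n_repertoires=200, depth=100_000, positive_fraction=0.5, witness_rate=5,
)
pool = [
    a.Receptor("CASSWKDYQETQYF", "V01", "J01", pgen=3e-11),
    a.Receptor("CASRYREVGNEQFF", "V02", "J02", pgen=8e-12),
    a.Receptor("CASQERFYLTQYF", "V03", "J03", pgen=5e-13),
]

report = a.assess_feasibility(pool, config, a.default_signal_model())

print(f"required signal instances:   {report.required_total}")
print(f"achievable signal instances: {report.achievable_total}")
print(f"feasible: {report.feasible}")
print()
print(report.guidance)
# required (500) is positives x witness rate; achievable (180) sums each
# sequence's incidence cap — the gap tells the user to enlarge the pool
# (roughly 3x here) or lower the witness rate before any expensive stage runs.
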