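"""Simulate one competition experiment and estimate plasmid fitness costs.

Builds a small factorial design (two plasmids, one slow-translation
mutation), simulates flow-cytometry competitions against the GFP-tagged
reference, and prints each genotype's relative fitness W and its cost as
a percentage.  W = 1 is neutrality; cost = (1 - W) x 100, so a W of 0.9
is a 10% fitness cost.
"""

import plasmidcost as pc

config = pc.SimulationConfig.factorial(
    plasmids={"pOXA": 0.85, "pKAZ": 0.75},   # true W of plasmid carriage
    mutations={"rpsL-K43N": 0.70},           # true W of the mutation alone
    seed=1,
)
counts = pc.simulate_experiment(config)
print(f"simulated {len(counts)} competition replicates\n")

result = pc.analyze_competition_table(counts)
print(f"{'plasmid':<10}{'mutation':<12}{'W':>8}{'cost %':>9}")
for genotype, est in sorted(result.normalized.items(), key=str):
    print(
        f"{genotype[0] or '-':<10}{genotype[1] or '-':<12}"
        f"{est.w:>8.3f}{pc.percent_cost(est.w):>9.1f}"
    )
print(
    "\nEach W is the median over replicates, normalized by the plasmid-free\n"
    "wild type; costs close to the configured 15/25/30% show the estimator\n"
    "recovering the ground truth through 10,000-event sampling noise."
)
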