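"""Find reactions that drive member growth and probe them by knockout.

Key reactions are common reactions whose member fluxes track member
abundances (Spearman rho > 0.7, BH-adjusted p < 0.05) in a majority of
samples. Knocking a key reaction out community-wide and re-solving shows
its causal impact on total growth.
"""

import pandas as pd

from imic import (IMICConfig, flux_table_from_solutions, key_reactions,
                  knockout_scan, solve_imic, to_irreversible)
from imic.expression import correction_factors
from imic.fixtures import FixtureSpec, make_expression, make_toy_community

spec = FixtureSpec(seed=1)
model = to_irreversible(make_toy_community(spec)[0])
config = IMICConfig()
lam = 10.0

factors = {
    f"s{t + 1}": correction_factors(
        model, make_expression(spec, sample_id=f"s{t + 1}", sample_index=t))
    for t in range(3)
}
solutions = {s: solve_imic(model, f, config, lam=lam)
             for s, f in factors.items()}
flux_table = flux_table_from_solutions(model, solutions)

acts = dict(zip(spec.member_ids, spec.designed_activity))
total = sum(acts.values())
abundance = pd.DataFrame(
    [(s, m, a / total) for s in factors for m, a in acts.items()],
    columns=["sample", "member", "abundance"])

report = key_reactions(flux_table, abundance)
print("per-sample correlation of common-reaction fluxes with abundance:")
print(report.table.round(4).to_string(index=False))
key = [r for r, flag in report.key.items() if flag]
print(f"\nkey reactions (pass in a majority of samples): {key}")

ko = knockout_scan(model, key + ["DEAD"], factors["s1"], lam, config)
print("\nknockout scan (community-wide removal, growth LP re-solved):")
print(ko.round(4).to_string(index=False))
print("\nKnocking out a key chain reaction abolishes all growth, while the")
print("dead-end reaction (zero flux in every optimum) is neutral.")
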