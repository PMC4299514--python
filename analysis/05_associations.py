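#!/usr/bin/env python
"""Associations between the Warburg level and cohort phenotypes.

Reads the cohort metric table produced by 03_cohort_bioenergetics.py
(or regenerates it) and quantifies: Spearman correlations of AFR with
migration (expected positive) and growth (expected negative), the
partial AFR-migration correlation controlling for growth, AFR vs EOR
and BEC agreement, and the drug-response association summary (fraction
of compounds significantly correlated with AFR, their sign split, and
the shuffle-based cohort-level empirical p-value).
"""

import argparse
from pathlib import Path

import pandas as pd

from warburgflux.stats import bh_fdr, partial_spearman, response_association, spearman_exact

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--results", type=Path, default=Path("results"))
args = parser.parse_args()

metrics_path = args.results / "cohort_metrics.tsv"
if not metrics_path.exists():
    raise SystemExit("run analysis/03_cohort_bioenergetics.py first")
frame = pd.read_csv(metrics_path, sep="\t").set_index("line")
drugs = pd.read_csv(args.results / "drug_response.tsv", sep="\t").set_index("compound")[list(frame.index)]

rows = []
for name, x, y in [
    ("AFR_vs_migration", frame["AFR"], frame["migration"]),
    ("AFR_vs_growth", frame["AFR"], frame["growth"]),
    ("AFR_vs_EOR", frame["AFR"], frame["EOR"]),
    ("AFR_vs_BEC", frame["AFR"], frame["BEC"]),
    ("EOR_vs_migration", frame["EOR"], frame["migration"]),
]:
    res = spearman_exact(x.to_numpy(), y.to_numpy(), seed=args.seed)
    rows.append({"pair": name, "rho": res.rho, "p": res.p, "method": res.method})
assoc = pd.DataFrame(rows)
mask, p_adj = bh_fdr(assoc["p"].to_numpy(), alpha=0.05)
assoc["p_adj"], assoc["significant"] = p_adj, mask
partial = partial_spearman(
    frame["AFR"].to_numpy(), frame["migration"].to_numpy(), frame["growth"].to_numpy(),
    seed=args.seed, n_draws=10_000,
)
assoc.loc[len(assoc)] = ["AFR_vs_migration|growth", partial.rho, partial.p, partial.method, float("nan"), partial.p < 0.05]
assoc.to_csv(args.results / "associations.tsv", sep="\t", index=False)
print(assoc.to_string(index=False, float_format=lambda v: f"{v:.4f}"))

summary = response_association(
    frame["AFR"], drugs, growth=frame["growth"], n_shuffles=1000, seed=args.seed, n_draws=10_000
)
summary.per_compound.to_csv(args.results / "drug_associations.tsv", sep="\t", index=False)
pd.DataFrame(
    [
        {
            "fraction_significant": summary.fraction_significant,
            "fraction_positive_of_significant": summary.fraction_positive_of_significant,
            "empirical_p": summary.empirical_p,
            "n_measure_specific_compounds": len(summary.measure_specific_compounds),
        }
    ]
).to_csv(args.results / "drug_summary.tsv", sep="\t", index=False)
print(
    f"\n{100 * summary.fraction_significant:.0f}% of compounds associate with AFR "
    f"({100 * summary.fraction_positive_of_significant:.0f}% positively); "
    f"empirical cohort p = {summary.empirical_p:.3g}; "
    f"{len(summary.measure_specific_compounds)} compounds track AFR but not growth."
)
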