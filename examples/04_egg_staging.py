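"""Egg developmental-stage comparison between two genotypes.

Freshly laid eggs are staged into 1-8 cell, 8-cell-to-comma, and
post-comma classes; a shift toward later stages indicates egg retention.
The exact Fisher-Freeman-Halton test compares two genotypes' stage
distributions.
"""

import pandas as pd

import vmsync as v

records = pd.DataFrame(
    [
        {"genotype": "wild type", "stage": "1-8 cell", "count": 40},
        {"genotype": "wild type", "stage": "8-cell to comma", "count": 8},
        {"genotype": "wild type", "stage": "post-comma", "count": 2},
        {"genotype": "retentive mutant", "stage": "1-8 cell", "count": 15},
        {"genotype": "retentive mutant", "stage": "8-cell to comma", "count": 20},
        {"genotype": "retentive mutant", "stage": "post-comma", "count": 15},
    ]
)
table = v.EggStageTable.from_records(records)
print(table.counts.to_string())
p = v.egg_stage_compare(table, ("wild type", "retentive mutant"))
print(f"\nFisher-Freeman-Halton exact p = {p:.3g}")

# A worked proportion with its Wilson 95% interval, the standard way to
# report "k of n animals" phenotype penetrance:
point, (lo, hi) = v.proportion_ci(36, 88)
print(f"rescue penetrance: {100 * point:.0f}% (36 of 88), "
      f"95% CI {100 * lo:.0f}-{100 * hi:.0f}%")
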