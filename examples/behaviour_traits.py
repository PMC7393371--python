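"""Extract behavioural traits from synthetic pair logs and compare groups.

Generates event logs for the three pairing types (conspecific M. lignano,
heterospecific, conspecific M. janickei), derives the six behavioural traits
per pair from the first five copulations, summarises stereotypy as CVs, and
runs the omnibus + post-hoc comparisons.
"""

import pandas as pd

from macromate import SimulationParams, compare_groups, gen_pair_logs
from macromate.traits import TRAIT_COLUMNS, summarize_cv, traits_table

params = SimulationParams(seed=0)
pairs = []
for pairing_type in ("lignano", "hetero", "janickei"):
    pairs.extend(gen_pair_logs(params, pairing_type))

table = traits_table(pairs)
print(f"{len(table)} pairs, "
      f"{int(table.excluded_no_copulations.sum())} excluded (no copulations)")

print("\nTrait means by pairing type (s):")
means = table.groupby("pairing_type")[TRAIT_COLUMNS].mean().round(1)
print(means.T.to_string())

print("\nCoefficient of variation (%) by pairing type:")
cv = summarize_cv(table).pivot(
    index="trait", columns="pairing_type", values="cv_percent"
)
print(cv.round(0).to_string())

print("\nGroup comparison for copulation duration "
      "(one-way ANOVA on log data + Tukey HSD):")
print(compare_groups("mean_copulation_duration_s", table).summary())
# The letters summarise the post-hoc structure: groups sharing a letter do
# not differ at alpha = 0.05.  With the default parameters, M. janickei
# copulates ~5x longer than M. lignano, with heterospecific pairs
# intermediate and the most variable (highest CV).
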