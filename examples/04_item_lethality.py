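"""Per-debris-type lethality: which items kill, per item ingested?

Uses the synthetic reconstruction of the published cohort's marginal totals
(1733 birds, 2671 typed items, 13 confirmed + 9 probable debris deaths) to
reproduce the per-item risk arithmetic, then shows the same table on a
generated cohort.
"""

from debrisdose import attribute_deaths, risk_ratio_table
from debrisdose.item_risk import SOFT_VS_HARD_GROUPING
from debrisdose.synthetic_reference import published_marginals_cohort

cohort = published_marginals_cohort()

attr = attribute_deaths(cohort)
print("deaths attributed (confirmed+probable):",
      {t: n for t, n in attr.combined.items() if n})
balloon_share = attr.confirmed_only["balloon"] / sum(attr.confirmed_only.values())
print(f"balloon share of confirmed debris deaths: {100 * balloon_share:.0f}%")

table = risk_ratio_table(cohort, reference="hard_plastic")
print()
print(table.to_frame().to_string(index=False))

soft = risk_ratio_table(cohort, reference="hard", grouping=SOFT_VS_HARD_GROUPING)
print()
print(soft.to_frame().to_string(index=False))
print(
    "\nBalloons are roughly 32x as lethal per item ingested as hard plastic,\n"
    "and the soft-item aggregate roughly 15x: soft, pliable items obstruct\n"
    "the gut far more readily than the hard fragments that dominate by count."
)
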