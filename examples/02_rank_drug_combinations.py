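"""Rank drug combinations by independent-drug-action (IDA) score.

Builds a monotherapy viability table for the preset's cell-line panel from
per-(subtype, drug) Hill curves, then scores every partner drug against a
fixed taxane anchor dose: the score is the predicted drop in mean panel
viability of the combination below the best single agent.
"""

from hetmix.ida import rank_combos
from hetmix.presets import (
    CSUSTAINED,
    DRUG_DOCETAXEL,
    TEST_DOSES,
    drug_concentration_grids,
    unstratified_crpc,
)
from hetmix.synthgen import generate_monotherapy_table

config = unstratified_crpc(seed=0, n_genes=2000)
table = generate_monotherapy_table(
    config.subtypes,
    drugs=list(TEST_DOSES),
    conc_grid=drug_concentration_grids(),
)
ranked = rank_combos(
    table,
    anchor_drug=DRUG_DOCETAXEL,
    anchor_conc=TEST_DOSES[DRUG_DOCETAXEL],
    max_conc=CSUSTAINED,  # partner doses capped at sustainable plasma levels
)
print(ranked.to_string(index=False))

# The NAMPT-inhibitor analog tops the list: it covers exactly the lineages
# the taxane misses (collateral sensitivity), which is what IDA rewards.
# A positive score means the combo is predicted to outperform the best
# monotherapy in a heterogeneous panel even without any within-cell synergy.
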