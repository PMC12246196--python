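"""Design mass-unique substrate pools and instrument inclusion lists.

Multiplexing only works if every pool member has a distinguishable
molecular weight: each expected glycoside ion then maps back to exactly one
substrate. This example pools a 453-compound library into 40-compound
mixes and builds the MS2 inclusion list for the first mix.
"""

import numpy as np

from glycoscreen.chemcore import (
    CompoundRecord,
    PoolingConfig,
    make_inclusion_list,
    pool_compounds,
    reaction_grid,
)

compounds = [
    CompoundRecord(f"S{i:03d}", f"compound {i}", m)
    for i, m in enumerate(np.linspace(150.0, 800.0, 453))
]
pools = pool_compounds(compounds, PoolingConfig(capacity=40, min_separation=0.01))
n_reactions, n_runs = reaction_grid(n_enzymes=85, n_substrates=453, pools=pools)

print(f"{len(compounds)} substrates -> {len(pools)} pools "
      f"({', '.join(p.pool_id for p in pools[:3])}, ...)")
print(f"85 enzymes x 453 substrates = {n_reactions} reactions "
      f"in {n_runs} LC-MS/MS runs")

by_id = {c.compound_id: c for c in compounds}
inclusion = make_inclusion_list(pools[0], by_id)
print(f"inclusion list for {pools[0].pool_id}: {len(inclusion)} target ions "
      f"({len(pools[0].members)} members x 2 glycosylation degrees x 4 adducts)")
print(f"first entries: " + ", ".join(f"{mz:.4f}" for *_, mz in inclusion[:4]))
# Each number is the m/z at which a glycosylation product of one pool member
# would appear; the instrument prioritises these for fragmentation.
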