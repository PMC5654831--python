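"""Derived metrics from the packaged reference class-total table
(published mouse muscle class totals, mean +/- SEM at n = 4).

Run:  python examples/05_reference_table_arithmetic.py
"""

import pandas as pd

from shotgunlipids import load_reference_class_totals
from shotgunlipids.profiles import diet_delta, pc_pe_ratio

ref = load_reference_class_totals()

# PC/PE ratio per strain on chow, from the published class means
rows = ref[ref["abbr"].isin(["PC", "PE"])].pivot(
    index="strain", columns="abbr", values="chow_mean")
print("PC/PE ratio (chow), from published class totals:")
print(pc_pe_ratio(rows).round(3).to_string())

# TAG accumulation with the high-fat diet, per strain
tag = ref[ref["abbr"] == "TAG"]
metric = pd.concat([
    tag.assign(diet="CHOW", value=tag["chow_mean"]),
    tag.assign(diet="HFD", value=tag["hfd_mean"]),
])
print("\nTAG delta, mean HFD - mean CHOW (nmol/mg):")
print(diet_delta(metric).round(2).to_string(index=False))
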