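#!/usr/bin/env python
"""Hit calling on the packaged 38-compound screen.

Loads the packaged compound-ratio table (treated / untreated
disease-model speed ratios, plus the rapamycin positive control at 1.22),
applies the hit rule — ratio at least that of the positive control at the
table's printed precision — and writes the ranked screen table.
"""

from pathlib import Path

import pandas as pd

from wormscreen import call_hits, load_table1

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

table = load_table1()
treated = table[table["role"] == "treated"]
pos = float(table.loc[table["role"] == "positive_control", "ratio"].iloc[0])

results = call_hits(list(zip(treated["label"], treated["ratio"])), pos)
hits = [r for r in results if r.is_hit]
print(f"positive-control (rapamycin) ratio: {pos}")
print(f"{len(hits)} of {len(results)} compounds called as hits:")
for r in hits:
    print(f"  {r.rank:2d}. {r.compound:<14s} ratio {r.ratio:.2f}")

df = pd.DataFrame(
    [dict(rank=r.rank, compound=r.compound, ratio=r.ratio, is_hit=r.is_hit)
     for r in results]
)
df.to_csv(OUT / "table1_hits.csv", index=False)
print(f"wrote {OUT / 'table1_hits.csv'}")
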