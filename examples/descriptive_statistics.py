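"""Descriptive and normality statistics of the bundled 31-species table.

Prints mean, sample SD, range, the Lilliefors normality statistic D and its
significance bound for each raw trait column.  A large D with a small bound
(rearing period) signals departure from normality; the natural-log column
restores it.
"""

from altripgls import load_table
from altripgls.descriptives import count_where, summarize

table = load_table()
print("variable\tn\tmean\tsd\tmin\tmax\tKS_D\tp_bound")
for col in ("cylinder_pct", "fw_days", "lifespan_days", "ln_fw"):
    print(summarize(table[col].to_numpy()).row(col))

n_long = count_where(table["fw_days"], lambda v: v > 500)
print(f"\nspecies weaned/fledged after day 500: {n_long} (the great apes)")
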