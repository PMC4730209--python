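"""Correlating aggregation metrics with experimental solubility scales.

The embedded 18-residue table pairs simulation-derived aggregation
metrics (window-averaged mean cluster size, monomer count) with
experimental solubility and hydrophobicity scales.  Pearson r over
pairwise-complete rows quantifies how well in-silico aggregation tracks
each experimental scale.
"""

from pepagg import builtin_scales, correlation_report

table = builtin_scales()
print(table.head(6).to_string(float_format=lambda v: f"{v:.1f}"))

report = correlation_report()
print("\nmetric                scale                exclude   r")
for _, row in report.iterrows():
    print(
        f"{row['metric']:<21} {row['scale']:<20} {row['exclude'] or '-':<9} "
        f"{row['r_2dp']:+.2f}"
    )
print(
    "\nHydrophobicity tracks aggregation best (r=+0.79 with MCS, -0.91 with\n"
    "monomer count); the raw amino-acid solubility compilation correlates\n"
    "weakly, dominated by outliers like Pro."
)
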