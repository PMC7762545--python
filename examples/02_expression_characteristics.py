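"""The three independent per-gene characteristics: AVE, REV and COR.

For one simulated region this prints a gene's average expression level
(AVE, expression units), its relative expression variability (REV, %,
chi-square-corrected pooled CV — low REV means tight homeostatic control)
and its coordination with a chosen anchor gene (Pearson rho on log2
values with its significance class), plus the region-level median REV
comparison that quantifies how much tighter expression control is in one
region than another.
"""

import genofabric as gf
from genofabric.expression import anchor_correlations, region_stats, rev_summary

config = gf.SimulationConfig(
    n_genes=150,
    regions=("NOR", "PTA"),
    correlation_blocks=(gf.CorrelationBlock(tuple(range(30)), 0.85),),
    seed=7,
)
table = gf.simulate_dataset(config).table

stats = {r: region_stats(table, r) for r in table.regions}
gene = "G00005"
for region in table.regions:
    row = stats[region].loc[gene]
    print(f"{gene} in {region}: AVE = {row['AVE']:8.2f}  REV = {row['REV']:5.1f}%  "
          f"(probed by {int(row['R'])} spots)")

cor = anchor_correlations(table, "PTA", "G00000")
entry = cor.loc[gene]
print(f"{gene} vs anchor G00000 in PTA: rho = {entry['rho']:+.3f}, "
      f"p = {entry['p']:.3f}, class = {entry['class'] or 'blank'}")
print(f"significant partners of G00000 in PTA: "
      f"{(cor['class'] == 'S').sum()} synergistic, "
      f"{(cor['class'] == 'A').sum()} antagonistic of {len(cor)}")

summary = rev_summary({r: stats[r]["REV"].to_numpy() for r in table.regions}, "NOR")
print(summary.round(4))
# a positive reduction_vs_reference means the region's transcript
# abundances are under tighter control than in the reference
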