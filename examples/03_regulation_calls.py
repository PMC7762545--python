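"""Regulation calls with a gene-specific, variability-derived cutoff.

A gene is up-/downregulated between two regions only when its signed fold
change exceeds CUT = 1 + sqrt(2(REV_A^2 + REV_B^2))/100 AND a Welch t-test
on the log2 replicate values is significant; genes silent in exactly one
region are turned_on/turned_off.  Pathway-level regulation is scored with
a hypergeometric over-representation p-value.
"""

import genofabric as gf
from genofabric.regulation import pathway_regulation_p, tabulate_regulation

planted = {i: {"PTA": 3.0} for i in range(12)}           # upregulated
planted.update({i: {"PTA": -3.0} for i in range(12, 17)})  # downregulated
planted[17] = {"NOR": 0.0}                                # turned on in PTA
config = gf.SimulationConfig(
    n_genes=120, regions=("NOR", "PTA"), cv_law=(0.03, 0.06),
    planted_regulation=planted, seed=3,
)
table = gf.simulate_dataset(config).table

calls = gf.region_pair_calls(table, "NOR", "PTA")
print(calls["verdict"].value_counts().to_string())

pathway = [f"G{i:05d}" for i in range(25)]  # 17 planted + 8 null genes
summary = tabulate_regulation(calls, pathway)
n_reg_universe = calls["verdict"].isin(
    ["up", "down", "turned_on", "turned_off"]
).sum()
n_reg_path = summary.n_up + summary.n_down + summary.n_turned_on + summary.n_turned_off
p = pathway_regulation_p(len(calls), int(n_reg_universe), summary.n_quantified, n_reg_path)
print(f"pathway: {summary.n_quantified} quantified, {n_reg_path} regulated "
      f"(up:down = {summary.ratio}), hypergeometric p = {p:.2e}")
# a small p means regulation concentrates in this pathway far beyond what
# the region-wide regulation rate would predict
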