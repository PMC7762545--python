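"""Generate a synthetic multi-region experiment and apply spot/gene QC.

Builds a 4-region, 4-replicate dataset of 200 genes with a planted
fraction of failing spots, writes it as a TSV fixture, reads it back and
runs the quality-control chain: corrupted spots and spots whose foreground
fluorescence drops below twice the background in any sample are discarded,
then genes left without a fully quantified spot are eliminated everywhere.
"""

from pathlib import Path

import genofabric as gf

out = Path("scratch/example_run")
config = gf.SimulationConfig(
    n_genes=200,
    regions=("NOR", "PTA", "PTB", "CWM"),
    qc_fail_fraction=0.03,
    corrupt_fraction=0.01,
    seed=42,
)
dataset = gf.simulate_dataset(config)
table_path, truth_path = gf.write_fixture(dataset, out)
table = gf.read_expression_table(table_path)

filtered, discards = gf.spot_qc_filter(table)
filtered, eliminated = gf.eliminate_unquantified_genes(filtered)

print(f"simulated spots:   {table.n_spots} ({len(table.genes)} genes)")
print(f"discarded spots:   {len(discards)} "
      f"({(discards['reason'] == 'corrupted').sum()} corrupted, "
      f"{(discards['reason'] != 'corrupted').sum()} dim)")
print(f"eliminated genes:  {len(eliminated)}")
print(f"quantified genes:  {len(filtered.genes)} in all "
      f"{len(filtered.regions)} regions x {filtered.n_replicates} replicates")
# the quantified universe is the gene set every downstream stage works on
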