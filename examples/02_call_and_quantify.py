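"""From raw reads to paired, classified alleles.

Runs the read-processing pipeline (demultiplex, UMI extraction, indel
calling, UMI deduplication, control filtering) on the dataset written by
01_simulate_screen.py, normalizes to RP10K, pairs each primary-limb allele
with its abundance in the regenerate, and prints the classification.
"""

from pathlib import Path

from limbscreen import classify
from limbscreen import io as lsio
from limbscreen.pipeline import call_fastq, pair_dataset

data_dir = Path("example_screen")  # produced by 01_simulate_screen.py

targets = lsio.read_targets(data_dir / "refs.fa")
sheet = lsio.read_sample_sheet(data_dir / "sheet.tsv")
calls = call_fastq(data_dir / "reads.fastq", targets, sheet)

table = calls.table("A01_primary", "tyrosinase")
print(f"A01 primary limb, tyrosinase: {table.total_assigned} unique molecules,")
print(f"  {len(table.counts) - 1} mutant alleles detected")

data = pair_dataset(calls.tables, sheet)
for gene, pairs in sorted(data.pairs_by_gene.items()):
    cls = classify(pairs, label=gene)
    s = cls.summary()
    print(f"{gene:10s} n={cls.total_alleles:3d} alleles: "
          f"{s['pct_lost']:.1f}% lost after regeneration, "
          f"{s['pct_low_freq_preserved']:.1f}% of low-frequency alleles preserved")

print()
print("Neutral loci keep most alleles through regeneration (losses are")
print("low-frequency lineages dropped at the blastema bottleneck); the")
print("selected gene loses far more.")
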