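"""Generate a two-cohort synthetic study and write it to TSV.

Builds the default study shape -- 75 tribal (TR) and 80 urban (UR) stool
samples, 300 OTUs, read depths 10k-60k -- and saves the count table plus
sample metadata, the inputs every other example starts from.
"""

from pathlib import Path

import microcompare as mc

out = Path("example_output")
out.mkdir(exist_ok=True)

spec = mc.default_spec(seed=42)
table, meta = mc.generate_cohorts(spec)

mc.write_abundance(table, out / "counts.tsv")
mc.write_metadata(meta, out / "metadata.tsv")
mc.save_spec(spec, out / "study.cfg")

depths = table.data.sum(axis=0)
print(f"table: {table.n_features} OTUs x {table.n_samples} samples")
print(f"read depths: {depths.min()}-{depths.max()} (median {int(depths.median())})")
print(meta.groupby("cohort").size().rename("samples"))
# Two cohorts with realistic library-size variation; rarefaction in the next
# examples removes that depth bias before any diversity comparison.
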