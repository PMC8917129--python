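"""Simulate the factorial cage experiment and write its tables.

Builds the default in-silico study — colonized (CL) vs microbiota-depleted
(MD) bees under five pesticide treatments, 4 cages x 30 bees each, 4 guts
sequenced per cage — and writes every table (counts, taxonomy, metadata,
tree, Cq, dilutions, enzymes, survival, feeder logs, ground truth) as
plain text.
"""

from pathlib import Path

from beegut.synthetic_data import SimulationConfig, simulate_experiment, write_dataset

ds = simulate_experiment(SimulationConfig(seed=1))
out = Path("scratch_example_dataset")
manifest = write_dataset(ds, out)

print(f"gut samples:      {len(ds.gut_samples)}")
print(f"blank extractions:{len(ds.blank_samples):>4}")
print(f"ASVs:             {ds.asv_counts.shape[1]} "
      f"(incl. {len(ds.truth.true_contaminants)} contaminants, "
      f"{len(ds.truth.true_organelles)} organellar)")
print(f"files written under {out}/: {len(manifest)}")
# 160 gut samples = 2 colonization x 5 pesticides x 16 guts; the 16 blanks
# carry only reagent contaminants and anchor the contaminant calls.
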