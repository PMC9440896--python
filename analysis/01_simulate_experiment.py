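"""Simulate the replicate-free two-condition quantification experiment.

One pooled abundance per protein per condition, 5% of proteins truly
differential at a 4-fold effect, 5% missing cells.  Writes the
quantification table and the planted ground truth under
results/analysis/.
"""

from pathlib import Path

from ratiosig.io_tables import write_quant_table
from ratiosig.simulate import SimulationConfig, simulate_quant_experiment

OUT = Path(__file__).resolve().parents[1] / "results" / "analysis"
SEED = 20240901

config = SimulationConfig(n_proteins=10_000, frac_de=0.05, effect_log2=2.0,
                          null_sd=0.3, missing_rate=0.05, seed=SEED)
table, truth = simulate_quant_experiment(config)

OUT.mkdir(parents=True, exist_ok=True)
write_quant_table(table, OUT / "quant_table.tsv")
truth.to_csv(OUT / "truth.tsv", sep="\t", index=False)

n_de = int(truth["is_de"].sum())
n_missing = int(table.data.isna().to_numpy().sum())
print(f"simulated {len(table)} proteins: {n_de} truly differential "
      f"({(truth['planted_log2_ratio'] > 0).sum()} up, "
      f"{(truth['planted_log2_ratio'] < 0).sum()} down), "
      f"{n_missing} missing cells")
print(f"wrote {OUT / 'quant_table.tsv'} and {OUT / 'truth.tsv'}")
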