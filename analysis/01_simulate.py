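"""Simulate the study cohort: 24 benign and 37 cancer patients, 8 sites each,
plus two negative controls per control type, with matched qPCR ground truth.

Writes the count table, metadata, taxonomy and truth tables under
results/data/ in the same TSV dialects the readers consume.
"""

from pathlib import Path

import fgtmicro as fg
from fgtmicro.io_tables import write_count_table, write_metadata, write_taxonomy
from fgtmicro.synthetic_data import write_truth

SEED = 20240901
OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    table, meta, truth = fg.simulate_dataset(
        n_benign=24, n_cancer=37, seed=SEED, controls_per_type=2
    )
    write_count_table(table, OUT / "counts.tsv", dialect="tsv_matrix")
    write_metadata(meta, OUT / "metadata.tsv")
    write_taxonomy(fg.default_taxonomy(), OUT / "taxonomy.tsv")
    write_truth(truth, OUT)

    n_ctrl = int((meta["group"] == "control").sum())
    print(f"simulated {table.n_samples} samples ({n_ctrl} negative controls), "
          f"{table.n_taxa} taxa ({len(truth.contaminant_taxa())} contaminants)")
    print(f"written to {OUT}")


if __name__ == "__main__":
    main()
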