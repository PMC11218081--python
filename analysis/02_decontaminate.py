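"""Score contaminants against the pooled negative controls, remove them, and
apply the low-information OTU filters. Reports recovery against the known
contaminant flags and writes the report plus the cleaned table.
"""

from pathlib import Path

import pandas as pd

import fgtmicro as fg
from fgtmicro.io_tables import write_count_table

ROOT = Path(__file__).resolve().parents[1] / "results"


def main():
    cfg = fg.PipelineConfig()
    table = fg.read_count_table(ROOT / "data" / "counts.tsv")
    meta = fg.read_metadata(ROOT / "data" / "metadata.tsv")
    table, meta = fg.align_table_metadata(table, meta)

    report = fg.score_contaminants(table, meta, threshold=cfg.decontam_threshold)
    report.to_csv(ROOT / "contaminant_report.tsv", sep="\t")
    flagged = report.index[report["is_contaminant"]]
    print(f"flagged {len(flagged)}/{len(report)} taxa as contaminants "
          f"(prevalence test, p < {cfg.decontam_threshold})")

    truth = pd.read_csv(ROOT / "data" / "truth_contaminants.tsv", sep="\t", index_col=0)
    true_set = set(truth.index[truth["is_contaminant"]]) & set(report.index)
    tp = len(set(flagged) & true_set)
    print(f"recovery vs truth: recall {tp / len(true_set):.3f}, "
          f"precision {tp / max(len(flagged), 1):.3f}")

    cleaned = fg.remove_contaminants(table, report)
    filtered, removed = fg.filter_low_information(
        cleaned, cfg.min_count, cfg.min_prevalence_frac, cfg.iqr_drop_frac
    )
    print(f"low-information filters removed {len(removed['prevalence'])} taxa by "
          f"prevalence and {len(removed['iqr'])} by lowest IQR; "
          f"{filtered.n_taxa} taxa remain")
    write_count_table(filtered, ROOT / "counts_decontaminated.tsv")


if __name__ == "__main__":
    main()
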