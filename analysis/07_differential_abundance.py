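"""LEfSe-style differential abundance between benign and cancer per site,
across taxonomic ranks, with the log10 LDA effect-size cutoff of 2.
"""

from pathlib import Path

import pandas as pd

import fgtmicro as fg

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = 20240907

SITES = ["higher_vagina", "cervix", "endometrium_higher"]
LEVELS = ["phylum", "family", "genus", "species"]


def main():
    cfg = fg.PipelineConfig()
    table = fg.read_count_table(ROOT / "counts_decontaminated.tsv")
    meta = fg.read_metadata(ROOT / "data" / "metadata.tsv")
    table, meta = fg.align_table_metadata(table, meta)
    tax = fg.read_taxonomy(ROOT / "data" / "taxonomy.tsv")

    out = []
    for site in SITES:
        ids = list(meta.loc[meta["site"] == site, "sample_id"])
        sub = table.select_samples(ids)
        groups = meta.set_index("sample_id").loc[ids, "group"].to_numpy()
        for level in LEVELS:
            ra = fg.relative_abundance(fg.taxonomy_rollup(sub, tax, level))
            res = fg.lefse(
                ra, groups, kw_alpha=cfg.kw_alpha, lda_cutoff=cfg.lda_cutoff, seed=SEED
            )
            res = res.assign(site=site, level=level)
            out.append(res.reset_index())
        sig = out[-1][out[-1]["significant"]]  # species-level summary per site
        print(f"{site}: {len(sig)} discriminative species-level features; top by score:")
        top = sig.sort_values("lda_log_score", ascending=False).head(5)
        for _, r in top.iterrows():
            print(f"  {r['feature']:35s} score {r['lda_log_score']:.2f} "
                  f"enriched in {r['enriched_class']}")

    pd.concat(out, ignore_index=True).to_csv(
        ROOT / "differential_abundance.tsv", sep="\t", index=False
    )


if __name__ == "__main__":
    main()
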