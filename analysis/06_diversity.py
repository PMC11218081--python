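"""Alpha (Shannon) and beta (Bray-Curtis + PERMANOVA) diversity comparisons
between benign and cancer groups per anatomical site, at genus level on the
rarefied, decontaminated table.
"""

from pathlib import Path

import pandas as pd

import fgtmicro as fg
from fgtmicro.diversity_stats import alpha_diversity_table

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = 20240906

SITES = ["higher_vagina", "cervix", "endometrium_higher"]


def main():
    cfg = fg.PipelineConfig()
    table = fg.read_count_table(ROOT / "counts_decontaminated.tsv")
    meta = fg.read_metadata(ROOT / "data" / "metadata.tsv")
    table, meta = fg.align_table_metadata(table, meta)
    tax = fg.read_taxonomy(ROOT / "data" / "taxonomy.tsv")

    results = []
    for site in SITES:
        ids = list(meta.loc[meta["site"] == site, "sample_id"])
        rare = fg.rarefy(table.select_samples(ids), depth="min",
                         seed=SEED, min_depth=cfg.rarefy_min_depth)
        genus = fg.taxonomy_rollup(rare, tax, "genus")
        ra = fg.relative_abundance(genus)
        alpha = alpha_diversity_table(ra, meta)
        groups = alpha["group"].to_numpy()
        p_alpha = fg.rank_group_test(alpha["shannon"].to_numpy(), groups)
        dm = fg.bray_curtis(ra)
        f_stat, p_beta = fg.permanova(dm, groups, n_perm=cfg.n_permutations, seed=SEED)
        mean_h = alpha.groupby("group")["shannon"].mean()
        results.append({
            "site": site,
            "shannon_benign": mean_h.get("benign"),
            "shannon_cancer": mean_h.get("cancer"),
            "p_alpha_mannwhitney": p_alpha,
            "permanova_F": f_stat,
            "p_beta_permanova": p_beta,
        })
        print(f"{site}: Shannon benign {mean_h.get('benign'):.2f} vs cancer "
              f"{mean_h.get('cancer'):.2f} (MW p = {p_alpha:.2g}); "
              f"PERMANOVA F {f_stat:.2f}, p = {p_beta:.3g}")

    pd.DataFrame(results).to_csv(ROOT / "diversity_by_site.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
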