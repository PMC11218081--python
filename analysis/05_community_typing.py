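"""Rarefy per site, assign rule-based community types at genus level, and
compare type frequencies between benign and cancer groups per site with the
chi-squared test. Also reproduces the published cluster-frequency tables and
demographic odds ratios from their printed counts.
"""

from pathlib import Path

import pandas as pd

import fgtmicro as fg

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = 20240905

SITE_SETS = {
    "vagina": ["lower_vagina", "higher_vagina"],
    "cervix": ["cervix"],
    "endometrium": ["endometrium_lower", "endometrium_higher"],
}

# Printed two-group cluster-frequency tables (rows benign/cancer).
PUBLISHED_TABLE2 = {
    "vagina": [[12, 5, 9, 14], [4, 8, 3, 39]],
    "cervix": [[10, 4, 8], [3, 2, 23]],
    "endometrium": [[18, 9, 17], [5, 1, 43]],
}
# Printed 2x2 demographic tables (benign row, cancer row) and their labels.
PUBLISHED_TABLE1 = {
    "parity (parous vs nulliparous)": [[19, 5], [27, 10]],
    "HRT (ever vs never)": [[8, 16], [5, 32]],
    "ethnicity (Asian vs White)": [[1, 17], [10, 20]],
    "smoking (ever vs never)": [[11, 13], [12, 25]],
}


def main():
    cfg = fg.PipelineConfig()
    table = fg.read_count_table(ROOT / "counts_decontaminated.tsv")
    meta = fg.read_metadata(ROOT / "data" / "metadata.tsv")
    table, meta = fg.align_table_metadata(table, meta)
    tax = fg.read_taxonomy(ROOT / "data" / "taxonomy.tsv")

    all_assignments = []
    for name, sites in SITE_SETS.items():
        ids = meta.loc[meta["site"].isin(sites), "sample_id"]
        sub = table.select_samples(list(ids))
        rare = fg.rarefy(sub, depth="min", seed=SEED, min_depth=cfg.rarefy_min_depth)
        genus = fg.taxonomy_rollup(rare, tax, "genus")
        ra = fg.relative_abundance(genus)
        assignments = fg.assign_cluster_labels(
            ra, meta,
            lacto_cut=cfg.lacto_dominant_cut, gard_cut=cfg.gard_cut, strep_cut=cfg.strep_cut,
        )
        all_assignments.append(assignments)
        tab, (stat, df, p) = fg.type_frequency_comparison(assignments, meta, sites)
        print(f"{name}: community-type frequencies by group, chi2 {stat:.2f} "
              f"(df {df}), p = {p:.3g}")
        print(tab.to_string())

    pd.concat(all_assignments).to_csv(ROOT / "community_types.tsv", sep="\t", index=False)

    print("\npublished cluster-frequency tables (chi-squared on printed counts):")
    for name, rows in PUBLISHED_TABLE2.items():
        stat, df, p = fg.chi_squared_test(rows)
        print(f"  {name}: p = {p:.6g}")
    print("published demographic tables (Fisher cross-product OR):")
    for name, rows in PUBLISHED_TABLE1.items():
        res = fg.fisher_or(rows)
        print(f"  {name}: OR = {res['odds_ratio']:.2f}, p = {res['p_value']:.3f}")


if __name__ == "__main__":
    main()
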