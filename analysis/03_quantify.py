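"""Fit the qPCR standard curve, convert simulated Ct values to total 16S
copies, and call bacterial signatures above the 700-copy background per
site and group.
"""

from pathlib import Path

import pandas as pd

import fgtmicro as fg

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = 20240903


def main():
    cfg = fg.PipelineConfig()
    meta = fg.read_metadata(ROOT / "data" / "metadata.tsv")
    loads_truth = pd.read_csv(ROOT / "data" / "truth_loads.tsv", sep="\t", index_col=0)

    standards = fg.make_standard_series(replicates=3, noise_sd=0.1, seed=SEED)
    curve = fg.fit_standard_curve(standards["copies"], standards["ct"])
    print(f"standard curve: slope {curve.slope:.4f} Ct/log10, "
          f"efficiency {curve.efficiency:.3f}, r^2 {curve.r_squared:.5f}")

    # the reaction receives load_volume/extract_volume of each extract
    per_reaction = loads_truth["true_16s_copies"] * (
        cfg.load_volume_ul / cfg.extract_volume_ul
    )
    ct = fg.simulate_qpcr(per_reaction.to_dict(), curve, noise_sd=0.2, seed=SEED)
    loads = fg.ct_to_total_copies(
        ct, curve, load_volume_ul=cfg.load_volume_ul, extract_volume_ul=cfg.extract_volume_ul
    )
    loads.to_csv(ROOT / "qpcr_loads.tsv", sep="\t")

    frac = fg.call_signature_above_background(
        loads, meta, cutoff=cfg.background_copy_cutoff
    )
    frac.to_csv(ROOT / "above_background.tsv", sep="\t", index=False)
    interesting = frac[frac["site"].isin(
        ["endometrium_lower", "endometrium_higher", "fallopian_tube", "ovary", "higher_vagina"]
    )]
    print(f"fraction of samples above {cfg.background_copy_cutoff:.0f} copies:")
    print(interesting.to_string(index=False))


if __name__ == "__main__":
    main()
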