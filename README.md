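# fgtmicro

Contamination-aware analysis of low-biomass 16S microbiome profiles from the
female genital tract and rectum, built for two-group (benign vs endometrial
cancer) multi-site studies. Specimens from the endometrium, fallopian tube and
ovary carry so little bacterial DNA that reagent contamination ("kitome")
dominates naive read counts; this package implements the full analysis chain
that makes such data interpretable, together with a synthetic-data generator
with known ground truth so every stage is testable without patient data.

The pipeline stages (each a module under `src/fgtmicro/`, each driven by a
numbered script under `analysis/`):

1. **io_tables** — count tables (TSV matrix, mothur `.shared`, BIOM v1 JSON),
   sample metadata, taxonomy maps, qPCR/cytokine tables, and the flat
   `PipelineConfig` holding every operating threshold.
2. **synthetic_data** — Dirichlet-multinomial multi-site communities with an
   ascension continuum, group effects (Lactobacillus depletion, anaerobe
   enrichment, reduced bacterial load), a constant-mass contamination model
   (contaminant read share `c0/(c0 + load)`), negative controls, and matched
   qPCR truth.
3. **decontamination** — the prevalence test: per taxon, a 2x2
   presence/absence table of true samples vs pooled negative controls, Fisher
   exact (small expected counts) or one-sided chi-square, flag at p < 0.5;
   plus low-information filters (>= 5 counts in 10% of samples; drop the 5%
   lowest-IQR taxa).
4. **quantification** — qPCR standard curve (OLS of Ct on log10 copies,
   efficiency `10^(-1/slope) - 1`), Ct -> copies per reaction -> total copies
   (x10 for 5 uL loaded of a 50 uL extract), the 700-copy
   above-background call, and total-protein normalisation of cytokine plates.
5. **continuum** — per-patient taxon sets at >= 0.5% relative abundance,
   Sorensen-Dice coefficient `DSC = 2c/(S1+S2)` for every site pair, Venn
   region counts, paired-composition R².
6. **community_typing** — rarefaction (sampling without replacement to the
   per-site minimum), Ward/Euclidean clustering, rule-based community types
   (Lactobacillus >= 75%; Gardnerella >= 50% with Lactobacillus second;
   Streptococcus >= 36%, vaginal sites only), chi-squared frequency
   comparison and Fisher cross-product odds ratios.
7. **diversity_stats** — Shannon (nats), Bray-Curtis, Mann-Whitney /
   Kruskal-Wallis, Dunn post-hoc, seeded permutation PERMANOVA.
8. **differential_abundance** — taxonomy roll-up and LEfSe-style detection:
   Kruskal-Wallis screen at alpha 0.05, optional subclass consistency check,
   bootstrap one-dimensional LDA effect size, log10 score cutoff 2.

## Worked example

```python
import fgtmicro as fg

table, meta, truth = fg.simulate_dataset(n_benign=5, n_cancer=5, seed=7,
    controls_per_type=2,
    sites=("lower_vagina", "cervix", "endometrium_lower", "rectum"))
report = fg.score_contaminants(table, meta, threshold=0.5)
flagged = set(report.index[report["is_contaminant"]])
true = set(truth.contaminant_taxa())
print(f"flagged {len(flagged)} taxa; recall "
      f"{len(flagged & true) / len(true):.2f}")
cleaned = fg.remove_contaminants(table, report)
print(f"{cleaned.n_taxa} taxa remain of {table.n_taxa}")
```

prints

```
flagged 20 taxa; recall 1.00
60 taxa remain of 80
```

The prevalence test recovered all 20 spiked contaminants (recall 1.00) and
flagged nothing else: under the constant-contaminant-mass model genuine taxa
never appear in negative controls, while contaminants dominate the
low-biomass endometrial samples and the controls alike.

The full analysis narrative is the numbered scripts:

```bash
python analysis/01_simulate.py        # 24 benign + 37 cancer patients, 8 sites
python analysis/02_decontaminate.py   # prevalence test + OTU filters
python analysis/03_quantify.py        # standard curve, loads, 700-copy call
python analysis/04_continuum.py       # Sorensen indices, Venn regions
python analysis/05_community_typing.py
python analysis/06_diversity.py
python analysis/07_differential_abundance.py
```

Each prints what it found and writes its tables under `results/`. On the
default cohort, for example, `03` reports ~50-60% of endometrial samples
above the 700-copy background (vs ~100% in the benign vagina), `04` reports a
median vagina-cervix DSC near 1.0 against ~0.13 for vagina-rectum, and `07`
finds *Lactobacillus crispatus*/*iners* enriched in benign and
*Porphyromonas*, *Prevotella* and other anaerobes enriched in cancer at log10
LDA scores near 5.

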