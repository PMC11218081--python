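"""Synthetic multi-site genital-tract/rectum microbiome datasets with known truth.

The generator emulates the structure of a two-group (benign vs endometrial
cancer) study of the female genital tract and rectum:

* per-patient lower-genital-tract (GT) communities drawn from a Dirichlet
  prior over a fixed pool of named genital/gut taxa, with the benign prior
  concentrated on *Lactobacillus*;
* a cancer group whose prior down-weights *Lactobacillus* and up-weights a
  designated anaerobe set, and whose true bacterial load in the vagina,
  cervix and rectum is shifted down on the log10 scale;
* an ascension-driven compositional continuum: each upper-GT site is a
  ``w``-weighted mixture of the patient's lower-GT composition and an
  independent site-specific draw;
* reagent ("kitome") contamination: every observed sample is a mixture of
  its true composition and a shared contaminant pool, with contaminant
  mixing fraction ``c0 / (c0 + true_load)`` — the constant-contaminant-mass,
  variable-specimen-mass model that makes contaminant read share inversely
  related to biomass;
* negative controls (air / knife / extraction / sequencing) containing
  contaminant reads only;
* matched qPCR truth: per-sample true 16S copy loads, and a Ct simulator
  that inverts a standard curve.

Read counts are multinomial at a fixed depth. Sequencing error, chimeras and
read-level artefacts are not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_tables import (
    CountTable,
    LOWER_GT_SITES,
    UPPER_GT_SITES,
    validate_metadata,
)
from .quantification import StandardCurve

# ---------------------------------------------------------------------------
# Taxon pool
#
# ~60 named biological taxa (genital + gut) and 20 typical reagent-contaminant
# taxa. Lineages above genus are simplified but use the conventional class/
# order/family for each genus. Per-taxon Dirichlet weights:
#   a_v: benign lower-GT prior, a_u: upper-GT site-specific prior, a_r: rectum.

_GENUS_LINEAGE = {
    # genus: (phylum, class, order, family)
    "Lactobacillus": ("Firmicutes", "Bacilli", "Lactobacillales", "Lactobacillaceae"),
    "Gardnerella": ("Actinobacteria", "Actinomycetia", "Bifidobacteriales", "Bifidobacteriaceae"),
    "Bifidobacterium": ("Actinobacteria", "Actinomycetia", "Bifidobacteriales", "Bifidobacteriaceae"),
    "Streptococcus": ("Firmicutes", "Bacilli", "Lactobacillales", "Streptococcaceae"),
    "Enterococcus": ("Firmicutes", "Bacilli", "Lactobacillales", "Enterococcaceae"),
    "Staphylococcus": ("Firmicutes", "Bacilli", "Bacillales", "Staphylococcaceae"),
    "Gemella": ("Firmicutes", "Bacilli", "Bacillales", "Bacillales_XI"),
    "Aerococcus": ("Firmicutes", "Bacilli", "Lactobacillales", "Aerococcaceae"),
    "Porphyromonas": ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Porphyromonadaceae"),
    "Prevotella": ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Prevotellaceae"),
    "Bacteroides": ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Bacteroidaceae"),
    "Parabacteroides": ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Tannerellaceae"),
    "Alistipes": ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Rikenellaceae"),
    "Odoribacter": ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Odoribacteraceae"),
    "Butyricimonas": ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Odoribacteraceae"),
    "Barnesiella": ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Barnesiellaceae"),
    "Peptoniphilus": ("Firmicutes", "Tissierellia", "Tissierellales", "Peptoniphilaceae"),
    "Anaerococcus": ("Firmicutes", "Tissierellia", "Tissierellales", "Peptoniphilaceae"),
    "Parvimonas": ("Firmicutes", "Tissierellia", "Tissierellales", "Peptoniphilaceae"),
    "Finegoldia": ("Firmicutes", "Tissierellia", "Tissierellales", "Peptoniphilaceae"),
    "Fusobacterium": ("Fusobacteria", "Fusobacteriia", "Fusobacteriales", "Fusobacteriaceae"),
    "Sneathia": ("Fusobacteria", "Fusobacteriia", "Fusobacteriales", "Leptotrichiaceae"),
    "Atopobium": ("Actinobacteria", "Coriobacteriia", "Coriobacteriales", "Atopobiaceae"),
    "Eggerthella": ("Actinobacteria", "Coriobacteriia", "Eggerthellales", "Eggerthellaceae"),
    "Collinsella": ("Actinobacteria", "Coriobacteriia", "Coriobacteriales", "Coriobacteriaceae"),
    "Actinomyces": ("Actinobacteria", "Actinomycetia", "Actinomycetales", "Actinomycetaceae"),
    "Mobiluncus": ("Actinobacteria", "Actinomycetia", "Actinomycetales", "Actinomycetaceae"),
    "Corynebacterium": ("Actinobacteria", "Actinomycetia", "Mycobacteriales", "Corynebacteriaceae"),
    "Micrococcus": ("Actinobacteria", "Actinomycetia", "Micrococcales", "Micrococcaceae"),
    "Megasphaera": ("Firmicutes", "Negativicutes", "Veillonellales", "Veillonellaceae"),
    "Veillonella": ("Firmicutes", "Negativicutes", "Veillonellales", "Veillonellaceae"),
    "Dialister": ("Firmicutes", "Negativicutes", "Veillonellales", "Veillonellaceae"),
    "Phascolarctobacterium": ("Firmicutes", "Negativicutes", "Acidaminococcales", "Acidaminococcaceae"),
    "Peptostreptococcus": ("Firmicutes", "Clostridia", "Eubacteriales", "Peptostreptococcaceae"),
    "Clostridium": ("Firmicutes", "Clostridia", "Eubacteriales", "Clostridiaceae"),
    "Faecalibacterium": ("Firmicutes", "Clostridia", "Eubacteriales", "Oscillospiraceae"),
    "Ruminococcus": ("Firmicutes", "Clostridia", "Eubacteriales", "Oscillospiraceae"),
    "Subdoligranulum": ("Firmicutes", "Clostridia", "Eubacteriales", "Oscillospiraceae"),
    "Oscillibacter": ("Firmicutes", "Clostridia", "Eubacteriales", "Oscillospiraceae"),
    "Blautia": ("Firmicutes", "Clostridia", "Eubacteriales", "Lachnospiraceae"),
    "Roseburia": ("Firmicutes", "Clostridia", "Eubacteriales", "Lachnospiraceae"),
    "Dorea": ("Firmicutes", "Clostridia", "Eubacteriales", "Lachnospiraceae"),
    "Coprococcus": ("Firmicutes", "Clostridia", "Eubacteriales", "Lachnospiraceae"),
    "Lachnospira": ("Firmicutes", "Clostridia", "Eubacteriales", "Lachnospiraceae"),
    "Fusicatenibacter": ("Firmicutes", "Clostridia", "Eubacteriales", "Lachnospiraceae"),
    "Agathobacter": ("Firmicutes", "Clostridia", "Eubacteriales", "Lachnospiraceae"),
    "Anaerostipes": ("Firmicutes", "Clostridia", "Eubacteriales", "Lachnospiraceae"),
    "Escherichia": ("Proteobacteria", "Gammaproteobacteria", "Enterobacterales", "Enterobacteriaceae"),
    "Campylobacter": ("Proteobacteria", "Epsilonproteobacteria", "Campylobacterales", "Campylobacteraceae"),
    "Sutterella": ("Proteobacteria", "Betaproteobacteria", "Burkholderiales", "Sutterellaceae"),
    "Akkermansia": ("Verrucomicrobia", "Verrucomicrobiae", "Verrucomicrobiales", "Akkermansiaceae"),
    "Ureaplasma": ("Tenericutes", "Mollicutes", "Mycoplasmatales", "Mycoplasmataceae"),
    "Mycoplasma": ("Tenericutes", "Mollicutes", "Mycoplasmatales", "Mycoplasmataceae"),
    # typical reagent/kitome genera
    "Ralstonia": ("Proteobacteria", "Betaproteobacteria", "Burkholderiales", "Burkholderiaceae"),
    "Burkholderia": ("Proteobacteria", "Betaproteobacteria", "Burkholderiales", "Burkholderiaceae"),
    "Cupriavidus": ("Proteobacteria", "Betaproteobacteria", "Burkholderiales", "Burkholderiaceae"),
    "Delftia": ("Proteobacteria", "Betaproteobacteria", "Burkholderiales", "Comamonadaceae"),
    "Comamonas": ("Proteobacteria", "Betaproteobacteria", "Burkholderiales", "Comamonadaceae"),
    "Aquabacterium": ("Proteobacteria", "Betaproteobacteria", "Burkholderiales", "Comamonadaceae"),
    "Herbaspirillum": ("Proteobacteria", "Betaproteobacteria", "Burkholderiales", "Oxalobacteraceae"),
    "Janthinobacterium": ("Proteobacteria", "Betaproteobacteria", "Burkholderiales", "Oxalobacteraceae"),
    "Pseudomonas": ("Proteobacteria", "Gammaproteobacteria", "Pseudomonadales", "Pseudomonadaceae"),
    "Acinetobacter": ("Proteobacteria", "Gammaproteobacteria", "Moraxellales", "Moraxellaceae"),
    "Stenotrophomonas": ("Proteobacteria", "Gammaproteobacteria", "Lysobacterales", "Lysobacteraceae"),
    "Sphingomonas": ("Proteobacteria", "Alphaproteobacteria", "Sphingomonadales", "Sphingomonadaceae"),
    "Novosphingobium": ("Proteobacteria", "Alphaproteobacteria", "Sphingomonadales", "Sphingomonadaceae"),
    "Methylobacterium": ("Proteobacteria", "Alphaproteobacteria", "Hyphomicrobiales", "Methylobacteriaceae"),
    "Bradyrhizobium": ("Proteobacteria", "Alphaproteobacteria", "Hyphomicrobiales", "Bradyrhizobiaceae"),
    "Mesorhizobium": ("Proteobacteria", "Alphaproteobacteria", "Hyphomicrobiales", "Phyllobacteriaceae"),
    "Phyllobacterium": ("Proteobacteria", "Alphaproteobacteria", "Hyphomicrobiales", "Phyllobacteriaceae"),
    "Brevundimonas": ("Proteobacteria", "Alphaproteobacteria", "Caulobacterales", "Caulobacteraceae"),
    "Caulobacter": ("Proteobacteria", "Alphaproteobacteria", "Caulobacterales", "Caulobacteraceae"),
}

# (taxon_id, a_v, a_u, a_r); genus is the id prefix before the underscore.
_BIOLOGICAL_TAXA = [
    ("Lactobacillus_crispatus", 6.0, 0.30, 0.05),
    ("Lactobacillus_iners", 3.0, 0.20, 0.05),
    ("Lactobacillus_gasseri", 1.5, 0.10, 0.05),
    ("Lactobacillus_vaginalis", 1.5, 0.10, 0.02),
    ("Gardnerella_vaginalis", 1.2, 0.10, 0.01),
    ("Streptococcus_agalactiae", 0.8, 0.15, 0.05),
    ("Streptococcus_anginosus", 0.4, 0.10, 0.05),
    ("Porphyromonas_somerae", 0.25, 0.20, 0.10),
    ("Prevotella_bivia", 0.25, 0.20, 0.20),
    ("Peptoniphilus_harei", 0.25, 0.15, 0.05),
    ("Anaerococcus_tetradius", 0.25, 0.15, 0.05),
    ("Fusobacterium_nucleatum", 0.25, 0.15, 0.05),
    ("Bacteroides_fragilis", 0.25, 0.10, 1.20),
    ("Atopobium_vaginae", 0.50, 0.10, 0.02),
    ("Megasphaera_micronuciformis", 0.30, 0.10, 0.05),
    ("Sneathia_amnii", 0.30, 0.10, 0.02),
    ("Dialister_micraerophilus", 0.20, 0.10, 0.10),
    ("Mobiluncus_curtisii", 0.10, 0.05, 0.02),
    ("Ureaplasma_parvum", 0.20, 0.10, 0.02),
    ("Mycoplasma_hominis", 0.10, 0.05, 0.02),
    ("Finegoldia_magna", 0.20, 0.15, 0.05),
    ("Peptostreptococcus_anaerobius", 0.15, 0.10, 0.10),
    ("Veillonella_atypica", 0.20, 0.10, 0.10),
    ("Actinomyces_neuii", 0.10, 0.10, 0.02),
    ("Aerococcus_christensenii", 0.20, 0.10, 0.02),
    ("Parvimonas_micra", 0.10, 0.10, 0.05),
    ("Gemella_haemolysans", 0.10, 0.10, 0.02),
    ("Corynebacterium_amycolatum", 0.20, 0.15, 0.02),
    ("Staphylococcus_epidermidis", 0.20, 0.15, 0.02),
    ("Enterococcus_faecalis", 0.15, 0.10, 0.20),
    ("Escherichia_coli", 0.20, 0.15, 0.60),
    ("Bifidobacterium_breve", 0.20, 0.10, 0.30),
    ("Campylobacter_ureolyticus", 0.10, 0.05, 0.05),
    ("Eggerthella_lenta", 0.10, 0.05, 0.10),
    ("Prevotella_copri", 0.05, 0.05, 0.60),
    ("Bacteroides_vulgatus", 0.05, 0.05, 1.00),
    ("Bacteroides_uniformis", 0.02, 0.05, 0.80),
    ("Parabacteroides_distasonis", 0.02, 0.05, 0.80),
    ("Alistipes_putredinis", 0.02, 0.05, 0.80),
    ("Odoribacter_splanchnicus", 0.02, 0.02, 0.30),
    ("Butyricimonas_virosa", 0.02, 0.02, 0.20),
    ("Barnesiella_intestinihominis", 0.02, 0.02, 0.30),
    ("Faecalibacterium_prausnitzii", 0.02, 0.05, 2.00),
    ("Blautia_obeum", 0.02, 0.05, 1.20),
    ("Roseburia_intestinalis", 0.02, 0.02, 1.00),
    ("Ruminococcus_bromii", 0.02, 0.02, 1.00),
    ("Subdoligranulum_variabile", 0.02, 0.02, 0.40),
    ("Oscillibacter_valericigenes", 0.02, 0.02, 0.40),
    ("Dorea_formicigenerans", 0.02, 0.02, 0.50),
    ("Coprococcus_comes", 0.02, 0.02, 0.50),
    ("Lachnospira_pectinoschiza", 0.02, 0.02, 0.40),
    ("Fusicatenibacter_saccharivorans", 0.02, 0.02, 0.30),
    ("Agathobacter_rectalis", 0.02, 0.02, 0.40),
    ("Anaerostipes_hadrus", 0.02, 0.02, 0.30),
    ("Clostridium_leptum", 0.02, 0.02, 0.50),
    ("Phascolarctobacterium_faecium", 0.02, 0.02, 0.40),
    ("Sutterella_wadsworthensis", 0.02, 0.02, 0.30),
    ("Akkermansia_muciniphila", 0.02, 0.02, 0.50),
    ("Collinsella_aerofaciens", 0.02, 0.02, 0.50),
    ("Veillonella_dispar", 0.05, 0.05, 0.30),
]

# Anaerobe set up-weighted in the cancer group.
ANAEROBE_TAXA = (
    "Porphyromonas_somerae",
    "Prevotella_bivia",
    "Peptoniphilus_harei",
    "Anaerococcus_tetradius",
    "Fusobacterium_nucleatum",
    "Bacteroides_fragilis",
)
LACTOBACILLUS_TAXA = (
    "Lactobacillus_crispatus",
    "Lactobacillus_iners",
    "Lactobacillus_gasseri",
    "Lactobacillus_vaginalis",
)

# (taxon_id, contaminant-pool Dirichlet weight)
_CONTAMINANT_TAXA = [
    ("Ralstonia_pickettii", 5.0),
    ("Pseudomonas_fluorescens", 4.0),
    ("Sphingomonas_paucimobilis", 4.0),
    ("Methylobacterium_radiotolerans", 3.0),
    ("Burkholderia_cepacia", 3.0),
    ("Bradyrhizobium_japonicum", 3.0),
    ("Mesorhizobium_loti", 2.5),
    ("Phyllobacterium_myrsinacearum", 2.5),
    ("Acinetobacter_lwoffii", 3.0),
    ("Stenotrophomonas_maltophilia", 3.0),
    ("Delftia_acidovorans", 2.5),
    ("Comamonas_testosteroni", 2.5),
    ("Cupriavidus_metallidurans", 2.0),
    ("Herbaspirillum_seropedicae", 2.0),
    ("Janthinobacterium_lividum", 2.0),
    ("Aquabacterium_parvum", 2.0),
    ("Novosphingobium_aromaticivorans", 2.0),
    ("Brevundimonas_diminuta", 2.0),
    ("Caulobacter_vibrioides", 2.0),
    ("Micrococcus_luteus", 2.5),
]

# Median log10 true 16S load (total copies per DNA extract) per site, benign
# group, and the log10 SD. Chosen so that low-biomass sites sit near the
# 700-copy background cutoff while the vagina, cervix and rectum are one to
# four orders of magnitude above it (a predominantly postmenopausal cohort).
SITE_LOG10_LOAD = {
    "lower_vagina": 5.5,
    "higher_vagina": 5.5,
    "cervix": 5.0,
    "endometrium_lower": 3.05,
    "endometrium_higher": 3.0,
    "fallopian_tube": 4.0,
    "ovary": 4.5,
    "rectum": 6.5,
}
LOAD_LOG10_SD = 1.2

# Sites whose load the cancer group shifts down.
LOAD_REDUCED_SITES = ("lower_vagina", "higher_vagina", "cervix", "rectum")

DEFAULT_SITES = tuple(SITE_LOG10_LOAD)

_CONTROL_TYPES = ("air", "knife", "extraction", "sequencing")


def taxon_pool():
    """All taxon ids in fixed order: biological taxa then contaminants."""
    return [t for t, *_ in _BIOLOGICAL_TAXA] + [t for t, _ in _CONTAMINANT_TAXA]


def default_taxonomy() -> pd.DataFrame:
    """Taxonomy map (phylum..species) for the generator's taxon pool."""
    rows = []
    for taxon in taxon_pool():
        genus = taxon.split("_")[0]
        phylum, class_, order, family = _GENUS_LINEAGE[genus]
        rows.append(
            {
                "taxon_id": taxon,
                "phylum": phylum,
                "class": class_,
                "order": order,
                "family": family,
                "genus": genus,
                "species": taxon.replace("_", " "),
            }
        )
    return pd.DataFrame(rows).set_index("taxon_id")


@dataclass
class SimulationParams:
    """Data-generating parameters (the study conditions).

    lactobacillus_depletion : factor dividing the *Lactobacillus* Dirichlet
        weights in the cancer prior (10 -> mean vaginal share drops from
        ~0.60 to ~0.07).
    anaerobe_enrichment : factor multiplying the anaerobe-set weights in the
        cancer prior.
    load_log10_reduction : log10 shift subtracted from cancer-group loads in
        the vagina, cervix and rectum (1.5, inside the reported 1-2 range).
    continuum_w : weight of the lower-GT composition in every upper-GT site's
        mixture; larger w = stronger ascension continuum.
    c0 : contaminant-pool pseudo-load (total copies); a sample with true load
        L has contaminant read fraction c0 / (c0 + L). Controls carry c0 as
        their true load, keeping them below the 700-copy background cutoff.
    """

    lactobacillus_depletion: float = 10.0
    anaerobe_enrichment: float = 5.0
    load_log10_reduction: float = 1.5
    continuum_w: float = 0.6
    c0: float = 300.0

    def __post_init__(self):
        if self.lactobacillus_depletion <= 0 or self.anaerobe_enrichment <= 0:
            raise ValueError("depletion/enrichment factors must be > 0 (Dirichlet weights stay positive)")
        if self.c0 < 0:
            raise ValueError("c0 must be >= 0")
        if not 0.0 <= self.continuum_w <= 1.0:
            raise ValueError("continuum_w must be in [0,1]")


@dataclass
class SimulationTruth:
    """Ground truth emitted alongside a simulated dataset."""

    contaminant_flags: dict  # taxon_id -> bool, partitions the taxon pool
    true_loads: dict  # sample_id -> 16S copies
    lower_gt_composition: dict  # patient_id -> fractions over biological taxa
    continuum_w: dict  # upper-GT site -> w
    params: SimulationParams
    biological_taxa: list = field(default_factory=list)

    def contaminant_taxa(self):
        return sorted(t for t, f in self.contaminant_flags.items() if f)


# The vaginal prior's total concentration controls how dominance-skewed
# individual communities are. 0.25 x the tabulated weights (total ~5) makes
# Lactobacillus-dominant (>=75%), Gardnerella- and Streptococcus-led and
# high-diversity states all occur at realistic rates while keeping the same
# mean composition.
_VAGINAL_ALPHA_SCALE = 0.25


def _group_alphas(params: SimulationParams):
    taxa = [t for t, *_ in _BIOLOGICAL_TAXA]
    a_v = np.array([a for _, a, _, _ in _BIOLOGICAL_TAXA]) * _VAGINAL_ALPHA_SCALE
    a_u = np.array([a for _, _, a, _ in _BIOLOGICAL_TAXA])
    a_r = np.array([a for _, _, _, a in _BIOLOGICAL_TAXA])
    a_v_cancer = a_v.copy()
    a_r_cancer = a_r.copy()
    lacto = np.isin(taxa, LACTOBACILLUS_TAXA)
    anaer = np.isin(taxa, ANAEROBE_TAXA)
    a_v_cancer[lacto] /= params.lactobacillus_depletion
    a_v_cancer[anaer] *= params.anaerobe_enrichment
    return taxa, {"benign": a_v, "cancer": a_v_cancer}, a_u, {"benign": a_r, "cancer": a_r_cancer}


def simulate_dataset(
    n_benign: int,
    n_cancer: int,
    params: SimulationParams | None = None,
    depth: int = 2000,
    seed: int = 0,
    sites=DEFAULT_SITES,
    controls_per_type: int = 1,
):
    """Simulate a two-group multi-site 16S count dataset with matched truth.

    Returns ``(CountTable, metadata DataFrame, SimulationTruth)``. One sample
    is generated per patient per requested site, plus ``controls_per_type``
    negative controls for each of the four control types. Reproducible for a
    given ``seed``; one explicit RNG stream per dataset.
    """
    params = params or SimulationParams()
    if depth < 100:
        raise ValueError("depth must be >= 100")
    if n_benign < 1 or n_cancer < 1:
        raise ValueError("need at least one patient per group")
    unknown = set(sites) - set(DEFAULT_SITES)
    if unknown:
        raise ValueError(f"unknown sites: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    bio_taxa, alpha_lower, alpha_upper, alpha_rectum = _group_alphas(params)
    contam_taxa = [t for t, _ in _CONTAMINANT_TAXA]
    contam_alpha = np.array([a for _, a in _CONTAMINANT_TAXA])
    all_taxa = bio_taxa + contam_taxa
    n_bio, n_con = len(bio_taxa), len(contam_taxa)

    # One shared contaminant-pool composition per dataset (one kitome).
    contam_comp = rng.dirichlet(contam_alpha)

    patients = [(f"B{i + 1:02d}", "benign") for i in range(n_benign)] + [
        (f"C{i + 1:02d}", "cancer") for i in range(n_cancer)
    ]

    sample_ids, meta_rows, columns = [], [], []
    true_loads, lower_comp = {}, {}

    for patient_id, group in patients:
        base = rng.dirichlet(alpha_lower[group])
        lower_comp[patient_id] = base
        rectum = rng.dirichlet(alpha_rectum[group]) if "rectum" in sites else None
        for site in sites:
            if site == "rectum":
                true = rectum
            elif site in LOWER_GT_SITES:
                true = base
            else:  # upper GT: ascension mixture
                own = rng.dirichlet(alpha_upper)
                true = params.continuum_w * base + (1.0 - params.continuum_w) * own
            mu = SITE_LOG10_LOAD[site]
            if group == "cancer" and site in LOAD_REDUCED_SITES:
                mu -= params.load_log10_reduction
            load = 10.0 ** rng.normal(mu, LOAD_LOG10_SD)
            f = params.c0 / (params.c0 + load) if params.c0 > 0 else 0.0
            comp = np.concatenate([(1.0 - f) * true, f * contam_comp])
            comp /= comp.sum()
            counts = rng.multinomial(depth, comp)
            sid = f"{patient_id}_{site}"
            sample_ids.append(sid)
            columns.append(counts)
            true_loads[sid] = load
            material = "tissue" if site in UPPER_GT_SITES else "swab"
            meta_rows.append((sid, patient_id, site, group, "none", material))

    for ctype in _CONTROL_TYPES:
        for k in range(controls_per_type):
            comp = np.concatenate([np.zeros(n_bio), contam_comp])
            counts = rng.multinomial(depth, comp / comp.sum())
            sid = f"ctrl_{ctype}_{k + 1}"
            sample_ids.append(sid)
            columns.append(counts)
            true_loads[sid] = params.c0
            meta_rows.append((sid, "none", "control", "control", ctype, "swab"))

    table = CountTable(all_taxa, sample_ids, np.array(columns).T)
    meta = validate_metadata(
        pd.DataFrame(
            meta_rows,
            columns=["sample_id", "patient_id", "site", "group", "control_type", "material"],
        )
    )
    truth = SimulationTruth(
        contaminant_flags={t: (t in set(contam_taxa)) for t in all_taxa},
        true_loads=true_loads,
        lower_gt_composition=lower_comp,
        continuum_w={s: params.continuum_w for s in UPPER_GT_SITES},
        params=params,
        biological_taxa=list(bio_taxa),
    )
    return table, meta, truth


def simulate_qpcr(true_loads, curve: StandardCurve, noise_sd: float = 0.2, seed: int = 0):
    """Simulate per-sample Ct values from true copy loads.

    Ct = intercept + slope * log10(copies) + N(0, noise_sd). Accepts an array
    of loads or a {sample_id: load} mapping (returning a pandas Series).
    """
    rng = np.random.default_rng(seed)
    if isinstance(true_loads, dict):
        keys = list(true_loads)
        loads = np.asarray([true_loads[k] for k in keys], dtype=float)
    else:
        keys = None
        loads = np.asarray(true_loads, dtype=float)
    if (loads <= 0).any():
        raise ValueError("true loads must be strictly positive")
    ct = curve.intercept + curve.slope * np.log10(loads)
    if noise_sd > 0:
        ct = ct + rng.normal(0.0, noise_sd, size=loads.shape)
    if keys is not None:
        return pd.Series(ct, index=keys, name="ct")
    return ct


def make_standard_series(
    intercept: float = 38.0,
    slope: float = -3.3219280948873623,
    log10_levels=(1, 2, 3, 4, 5, 6, 7, 8),
    replicates: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """A ten-fold qPCR dilution series with known copies and (noisy) Ct values."""
    rng = np.random.default_rng(seed)
    rows = []
    for lev in log10_levels:
        copies = 10.0 ** lev
        for rep in range(1, replicates + 1):
            ct = intercept + slope * lev
            if noise_sd > 0:
                ct += rng.normal(0.0, noise_sd)
            rows.append({"sample_id": "standard", "copies": copies, "ct": ct, "replicate": rep})
    return pd.DataFrame(rows)


def write_truth(truth: SimulationTruth, out_dir) -> None:
    """Write ground truth as two TSVs (taxon flags; sample loads)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pd.Series(truth.contaminant_flags, name="is_contaminant").rename_axis("taxon_id").to_csv(
        out_dir / "truth_contaminants.tsv", sep="\t"
    )
    pd.Series(truth.true_loads, name="true_16s_copies").rename_axis("sample_id").to_csv(
        out_dir / "truth_loads.tsv", sep="\t"
    )
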