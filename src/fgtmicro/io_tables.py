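"""Tables, metadata and configuration for the genital-tract microbiome pipeline.

Count tables are taxa x samples matrices of raw read counts. Relative
abundances are never stored here; they are derived downstream so that
rarefaction stays well-defined. Sample identifiers are case-sensitive and
whitespace-trimmed on read (mothur group names are case-sensitive).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, fields, asdict
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

# Anatomical sites sampled along the genital tract plus rectum and controls.
SITES = (
    "lower_vagina",
    "higher_vagina",
    "cervix",
    "endometrium_lower",
    "endometrium_higher",
    "fallopian_tube",
    "ovary",
    "rectum",
    "control",
)
LOWER_GT_SITES = ("lower_vagina", "higher_vagina", "cervix")
UPPER_GT_SITES = ("endometrium_lower", "endometrium_higher", "fallopian_tube", "ovary")
VAGINAL_SITES = ("lower_vagina", "higher_vagina")

GROUPS = ("benign", "cancer", "control")
CONTROL_TYPES = ("air", "knife", "extraction", "sequencing", "none")
MATERIALS = ("swab", "tissue")

METADATA_COLUMNS = ("sample_id", "patient_id", "site", "group", "control_type", "material")

RANKS = ("phylum", "class", "order", "family", "genus", "species")


class TableFormatError(ValueError):
    """Raised when an input table violates its format contract."""


@dataclass
class CountTable:
    """Taxa x samples matrix of non-negative integer read counts.

    Parameters
    ----------
    taxon_ids : list of str
        Unique row identifiers (OTU ids or species labels).
    sample_ids : list of str
        Unique column identifiers.
    counts : ndarray of int, shape (n_taxa, n_samples)
    """

    taxon_ids: list
    sample_ids: list
    counts: np.ndarray

    def __post_init__(self):
        self.taxon_ids = [str(t).strip() for t in self.taxon_ids]
        self.sample_ids = [str(s).strip() for s in self.sample_ids]
        counts = np.asarray(self.counts)
        if counts.dtype.kind == "f":
            if not np.allclose(counts, np.round(counts)):
                raise TableFormatError("counts must be integers")
            counts = np.round(counts).astype(np.int64)
        self.counts = counts.astype(np.int64, copy=False)
        if self.counts.ndim != 2:
            raise TableFormatError("counts must be a 2-D matrix")
        if self.counts.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise TableFormatError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.taxon_ids)} taxa x {len(self.sample_ids)} samples"
            )
        if (self.counts < 0).any():
            i, j = np.argwhere(self.counts < 0)[0]
            raise TableFormatError(
                f"negative count at taxon {self.taxon_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )
        for name, ids in (("taxon", self.taxon_ids), ("sample", self.sample_ids)):
            dup = _first_duplicate(ids)
            if dup is not None:
                raise TableFormatError(f"duplicate {name} id: {dup!r}")

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.taxon_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CountTable":
        return cls(list(df.index), list(df.columns), df.to_numpy())

    def select_samples(self, sample_ids: Iterable[str]) -> "CountTable":
        sample_ids = list(sample_ids)
        idx = {s: j for j, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in idx]
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        cols = [idx[s] for s in sample_ids]
        return CountTable(list(self.taxon_ids), sample_ids, self.counts[:, cols])

    def select_taxa(self, taxon_ids: Iterable[str]) -> "CountTable":
        taxon_ids = list(taxon_ids)
        idx = {t: i for i, t in enumerate(self.taxon_ids)}
        missing = [t for t in taxon_ids if t not in idx]
        if missing:
            raise KeyError(f"unknown taxon ids: {missing}")
        rows = [idx[t] for t in taxon_ids]
        return CountTable(taxon_ids, list(self.sample_ids), self.counts[rows, :])

    def sample_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)


def _first_duplicate(ids):
    seen = set()
    for x in ids:
        if x in seen:
            return x
        seen.add(x)
    return None


# ---------------------------------------------------------------------------
# Count-table I/O


def read_count_table(path, dialect: str = "tsv_matrix") -> CountTable:
    """Read a count table.

    Dialects
    --------
    ``tsv_matrix``
        First column taxon id, header row sample ids, tab-separated integers.
    ``mothur_shared``
        mothur ``.shared`` layout: columns ``label Group numOtus Otu...``,
        samples as rows; transposed into taxa x samples on read.
    ``biom``
        BIOM v1 (JSON), read-only.
    """
    path = Path(path)
    if dialect == "tsv_matrix":
        return _read_tsv_matrix(path)
    if dialect == "mothur_shared":
        return _read_mothur_shared(path)
    if dialect == "biom":
        return _read_biom_v1(path)
    raise ValueError(f"unknown dialect {dialect!r}; expected tsv_matrix, mothur_shared or biom")


def _parse_count(text, where):
    try:
        value = int(text)
    except ValueError:
        raise TableFormatError(f"non-integer count {text!r} at {where}") from None
    if value < 0:
        raise TableFormatError(f"negative count {value} at {where}")
    return value


def _read_tsv_matrix(path: Path) -> CountTable:
    lines = path.read_text().splitlines()
    if not lines:
        raise TableFormatError(f"{path}: empty file")
    header = lines[0].rstrip("\n").split("\t")
    sample_ids = [s.strip() for s in header[1:]]
    taxon_ids, rows = [], []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != len(header):
            raise TableFormatError(
                f"{path}:{lineno}: ragged row ({len(parts)} fields, expected {len(header)})"
            )
        taxon_ids.append(parts[0].strip())
        rows.append(
            [
                _parse_count(v, f"{path}:{lineno} sample {sample_ids[j]!r}")
                for j, v in enumerate(parts[1:])
            ]
        )
    counts = np.asarray(rows, dtype=np.int64) if rows else np.zeros((0, len(sample_ids)), int)
    return CountTable(taxon_ids, sample_ids, counts)


def _read_mothur_shared(path: Path) -> CountTable:
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise TableFormatError(f"{path}: empty file")
    header = lines[0].split("\t")
    if [h.lower() for h in header[:3]] != ["label", "group", "numotus"]:
        raise TableFormatError(
            f"{path}: mothur shared header must start 'label Group numOtus', got {header[:3]}"
        )
    taxon_ids = [t.strip() for t in header[3:]]
    sample_ids, cols = [], []
    for lineno, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if len(parts) != len(header):
            raise TableFormatError(
                f"{path}:{lineno}: ragged row ({len(parts)} fields, expected {len(header)})"
            )
        sample_ids.append(parts[1].strip())
        cols.append(
            [
                _parse_count(v, f"{path}:{lineno} OTU {taxon_ids[j]!r}")
                for j, v in enumerate(parts[3:])
            ]
        )
    counts = np.asarray(cols, dtype=np.int64).T  # samples-as-rows -> taxa x samples
    return CountTable(taxon_ids, sample_ids, counts)


def _read_biom_v1(path: Path) -> CountTable:
    doc = json.loads(path.read_text())
    taxon_ids = [row["id"] for row in doc["rows"]]
    sample_ids = [col["id"] for col in doc["columns"]]
    counts = np.zeros((len(taxon_ids), len(sample_ids)), dtype=np.int64)
    if doc.get("matrix_type") == "sparse":
        for i, j, v in doc["data"]:
            counts[int(i), int(j)] = _parse_count(v, f"{path} sparse entry ({i},{j})")
    else:
        for i, row in enumerate(doc["data"]):
            for j, v in enumerate(row):
                counts[i, j] = _parse_count(v, f"{path} dense entry ({i},{j})")
    return CountTable(taxon_ids, sample_ids, counts)


def write_count_table(table: CountTable, path, dialect: str = "tsv_matrix") -> None:
    """Write a count table in a read-compatible dialect (``biom`` is read-only)."""
    path = Path(path)
    if dialect == "tsv_matrix":
        with path.open("w") as fh:
            fh.write("taxon_id\t" + "\t".join(table.sample_ids) + "\n")
            for i, t in enumerate(table.taxon_ids):
                fh.write(t + "\t" + "\t".join(str(v) for v in table.counts[i]) + "\n")
    elif dialect == "mothur_shared":
        with path.open("w") as fh:
            fh.write("label\tGroup\tnumOtus\t" + "\t".join(table.taxon_ids) + "\n")
            for j, s in enumerate(table.sample_ids):
                row = "\t".join(str(v) for v in table.counts[:, j])
                fh.write(f"0.03\t{s}\t{table.n_taxa}\t{row}\n")
    else:
        raise ValueError(f"cannot write dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Sample metadata


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample metadata table and return a trimmed copy.

    Enforces the column contract (sample_id, patient_id, site, group,
    control_type, material), enum membership, uniqueness of sample ids, and
    the control consistency rule: control_type != 'none' exactly for rows
    with group == 'control'.
    """
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise TableFormatError(f"metadata missing required columns: {missing}")
    meta = meta.loc[:, list(METADATA_COLUMNS)].copy()
    for col in METADATA_COLUMNS:
        meta[col] = meta[col].astype(str).str.strip()
    dup = _first_duplicate(list(meta["sample_id"]))
    if dup is not None:
        raise TableFormatError(f"duplicate sample id in metadata: {dup!r}")
    for col, allowed in (("site", SITES), ("group", GROUPS),
                         ("control_type", CONTROL_TYPES), ("material", MATERIALS)):
        bad = sorted(set(meta[col]) - set(allowed))
        if bad:
            raise TableFormatError(
                f"unknown {col} value(s) {bad}; allowed: {list(allowed)}"
            )
    is_control = meta["group"] == "control"
    has_type = meta["control_type"] != "none"
    offenders = meta.loc[is_control != has_type, "sample_id"].tolist()
    if offenders:
        raise TableFormatError(
            "control_type must be 'none' exactly for non-control samples; "
            f"violated by: {offenders}"
        )
    return meta.reset_index(drop=True)


def read_metadata(path) -> pd.DataFrame:
    """Read and validate a TSV sample metadata table."""
    meta = pd.read_csv(path, sep="\t", dtype=str)
    return validate_metadata(meta)


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def align_table_metadata(table: CountTable, meta: pd.DataFrame):
    """Restrict a count table and metadata to their common samples, same order.

    Logs a warning naming any dropped ids. Raises on an empty intersection.
    Idempotent: aligning already-aligned inputs is a no-op.
    """
    meta_ids = list(meta["sample_id"])
    common = [s for s in table.sample_ids if s in set(meta_ids)]
    if not common:
        raise ValueError("count table and metadata share no sample ids")
    dropped_counts = sorted(set(table.sample_ids) - set(common))
    dropped_meta = sorted(set(meta_ids) - set(common))
    if dropped_counts or dropped_meta:
        logger.warning(
            "align_table_metadata dropped ids: counts-only=%s metadata-only=%s",
            dropped_counts, dropped_meta,
        )
    aligned_meta = (
        meta.set_index("sample_id").loc[common].reset_index()
    )
    return table.select_samples(common), validate_metadata(aligned_meta)


# ---------------------------------------------------------------------------
# Taxonomy


def read_taxonomy(path) -> pd.DataFrame:
    """Read a taxon_id -> ranks map (TSV with columns taxon_id, phylum..species).

    The species column may be absent. Empty rank strings are replaced by
    'unclassified'.
    """
    tax = pd.read_csv(path, sep="\t", dtype=str)
    if "taxon_id" not in tax.columns:
        raise TableFormatError("taxonomy table must have a taxon_id column")
    known = [r for r in RANKS if r in tax.columns]
    if not known:
        raise TableFormatError(f"taxonomy table has none of the rank columns {RANKS}")
    tax = tax.loc[:, ["taxon_id"] + known].copy()
    for col in known:
        tax[col] = tax[col].fillna("unclassified").astype(str).str.strip()
        tax.loc[tax[col] == "", col] = "unclassified"
    dup = _first_duplicate(list(tax["taxon_id"]))
    if dup is not None:
        raise TableFormatError(f"duplicate taxon id in taxonomy: {dup!r}")
    return tax.set_index("taxon_id")


def write_taxonomy(tax: pd.DataFrame, path) -> None:
    tax.reset_index().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# qPCR and cytokine tables


def read_qpcr_table(path):
    """Read a qPCR TSV with columns sample_id, copies, ct, replicate.

    Rows whose sample_id is 'standard' form the dilution series (copies
    required); all other rows are per-sample Ct measurements. Returns
    (standards DataFrame, samples DataFrame).
    """
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise TableFormatError(f"qPCR table missing columns: {sorted(missing)}")
    df["sample_id"] = df["sample_id"].astype(str).str.strip()
    std = df[df["sample_id"] == "standard"].copy()
    smp = df[df["sample_id"] != "standard"].copy()
    if not std.empty and ("copies" not in std.columns or std["copies"].isna().any()):
        raise TableFormatError("standard rows must carry known copy numbers")
    return std, smp


def read_cytokine_plate(path) -> pd.DataFrame:
    """Read a cytokine plate TSV: well, analyte, concentration_pg_ml, protein_ug_ml."""
    df = pd.read_csv(path, sep="\t")
    required = {"well", "analyte", "concentration_pg_ml", "protein_ug_ml"}
    missing = required - set(df.columns)
    if missing:
        raise TableFormatError(f"cytokine plate missing columns: {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# Pipeline configuration


@dataclass
class PipelineConfig:
    """Flat pipeline configuration; defaults are the study's operating thresholds.

    decontam_threshold : p-value below which a taxon is called a contaminant
        in the prevalence test (0.5).
    min_count / min_prevalence_frac : keep taxa with >= min_count reads in at
        least that fraction of samples (5 counts in 10%).
    iqr_drop_frac : fraction of remaining taxa with the lowest count IQR that
        the variance filter removes (0.05).
    background_copy_cutoff : total 16S copies above which a sample is called
        above background contamination (700, strict >).
    continuum_min_relabund : relative-abundance floor for a taxon to count as
        present in continuum/Venn analyses (0.005, inclusive).
    lacto_dominant_cut / gard_cut / strep_cut : community-type thresholds
        (0.75 / 0.50 / 0.36 relative abundance).
    lda_cutoff : log10 LDA effect-size threshold for discriminative taxa (2.0).
    kw_alpha : Kruskal-Wallis screening alpha (0.05).
    rarefy_min_depth : samples with fewer reads are dropped before rarefying
        to the per-site minimum (500).
    load_volume_ul / extract_volume_ul : qPCR reaction load and total DNA
        extract volumes (5 uL / 50 uL), fixing the x10 total-copy scaling.
    """

    decontam_threshold: float = 0.5
    min_count: int = 5
    min_prevalence_frac: float = 0.10
    iqr_drop_frac: float = 0.05
    background_copy_cutoff: float = 700.0
    continuum_min_relabund: float = 0.005
    lacto_dominant_cut: float = 0.75
    gard_cut: float = 0.50
    strep_cut: float = 0.36
    lda_cutoff: float = 2.0
    kw_alpha: float = 0.05
    n_permutations: int = 999
    rng_seed: int = 17
    rarefy_min_depth: int = 500
    load_volume_ul: float = 5.0
    extract_volume_ul: float = 50.0

    def __post_init__(self):
        for name in ("decontam_threshold", "min_prevalence_frac", "iqr_drop_frac",
                     "continuum_min_relabund", "lacto_dominant_cut", "gard_cut",
                     "strep_cut", "kw_alpha"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        for name in ("background_copy_cutoff", "min_count", "n_permutations",
                     "rarefy_min_depth", "load_volume_ul", "extract_volume_ul"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
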