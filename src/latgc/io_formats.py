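"""Readers/writers for the on-disk formats used throughout the pipeline.

All tabular formats are plain TSV; gene sets use the standard GMT layout
(name, description, genes...). The immune-related prognostic model (IRPM)
signature — 35 positively and 12 negatively immune-correlated marker genes —
ships as a packaged GMT fixture.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "MutationTable",
    "GeneSetCollection",
    "CohortClinical",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_maf",
    "write_maf",
    "read_gmt",
    "write_gmt",
    "read_clinical",
    "write_clinical",
    "load_table1_signature",
    "SYNONYMOUS_CLASSES",
    "KNOWN_VARIANT_CLASSES",
]

EXPRESSION_LAYOUTS = ("counts", "fpkm", "log2")

#: MAF variant classes treated as synonymous (removed before TMB).
SYNONYMOUS_CLASSES = frozenset({"Silent", "Synonymous_Variant"})

KNOWN_VARIANT_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Splice_Site",
        "Translation_Start_Site",
        "Silent",
        "Synonymous_Variant",
    }
)


@dataclass
class ExpressionMatrix:
    """Gene-by-sample numeric matrix with a declared layout.

    Parameters
    ----------
    data:
        DataFrame with gene symbols as index, sample ids as columns. Missing
        values are ``NaN`` — deliberately distinct from 0, because a 0 in an
        FPKM matrix is a value scheduled for imputation, not absence of data.
    layout:
        One of ``counts``, ``fpkm``, ``log2``.
    """

    data: pd.DataFrame
    layout: str

    def __post_init__(self) -> None:
        if self.layout not in EXPRESSION_LAYOUTS:
            raise ValueError(f"unknown layout {self.layout!r}; expected one of {EXPRESSION_LAYOUTS}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        values = self.data.to_numpy(dtype=float)
        finite_or_nan = np.isfinite(values) | np.isnan(values)
        if not finite_or_nan.all():
            raise ValueError("expression values must be finite or NaN")
        if self.layout == "counts":
            observed = values[np.isfinite(values)]
            if (observed < 0).any():
                raise ValueError("counts layout requires non-negative values")
            if not np.allclose(observed, np.round(observed)):
                raise ValueError("counts layout requires integral values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


MAF_REQUIRED = ("Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification")

_MUTATION_COLUMNS = [
    "sample_id",
    "gene",
    "variant_classification",
    "chrom",
    "position",
    "ref_count",
    "alt_count",
]


@dataclass
class MutationTable:
    """Long-form somatic variant records (one row per variant call)."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _MUTATION_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"MutationTable missing columns: {missing}")
        rc = self.records["ref_count"]
        ac = self.records["alt_count"]
        both = rc.notna() & ac.notna()
        if ((rc[both] < 0) | (ac[both] < 0)).any():
            raise ValueError("allele counts must be non-negative")
        if ((rc[both] + ac[both]) <= 0).any():
            raise ValueError("ref_count + alt_count must be positive when both present")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.records["sample_id"].unique())

    def vaf(self) -> pd.Series:
        """Variant allele frequency alt/(ref+alt); NaN where counts absent."""
        rc = self.records["ref_count"].astype(float)
        ac = self.records["alt_count"].astype(float)
        return ac / (rc + ac)

    def is_synonymous(self, vocabulary: frozenset[str] = SYNONYMOUS_CLASSES) -> pd.Series:
        return self.records["variant_classification"].isin(vocabulary)


class GeneSetCollection:
    """Named gene sets, optionally signed (+1/-1 per gene) for signatures."""

    def __init__(
        self,
        sets: dict[str, set[str]],
        signs: dict[str, dict[str, int]] | None = None,
    ) -> None:
        names = list(sets)
        if len(set(names)) != len(names):
            raise ValueError("gene set names must be unique")
        for name, genes in sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
        self.sets: dict[str, frozenset[str]] = {n: frozenset(g) for n, g in sets.items()}
        self.signs = signs or {}
        for name, sign_map in self.signs.items():
            bad = set(sign_map.values()) - {1, -1}
            if bad:
                raise ValueError(f"signs for {name!r} must be +1/-1, got {bad}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def names(self) -> list[str]:
        return list(self.sets)

    def subset(self, names) -> "GeneSetCollection":
        return GeneSetCollection(
            {n: set(self.sets[n]) for n in names},
            {n: dict(self.signs[n]) for n in names if n in self.signs} or None,
        )


@dataclass
class CohortClinical:
    """Per-sample survival and clinical covariates.

    ``table`` is indexed by sample_id with at least ``os_time`` (days, >= 0)
    and ``os_event`` (0 censored / 1 death). A numeric ``latitude`` column
    and categorical factors (stage, grade, response, gender, ...) are
    optional; missing categorical values are NaN.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("os_time", "os_event"):
            if col not in self.table.columns:
                raise ValueError(f"clinical table missing column {col!r}")
        if self.table.index.has_duplicates:
            raise ValueError("duplicate sample ids in clinical table")
        if (self.table["os_time"] < 0).any():
            raise ValueError("os_time must be non-negative")
        events = set(self.table["os_event"].dropna().unique())
        if not events <= {0, 1}:
            raise ValueError(f"os_event must be in {{0,1}}, found {sorted(events - {0, 1})}")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)


# ---------------------------------------------------------------------------
# readers / writers


def read_expression_matrix(path, layout: str, duplicate_policy: str = "error") -> ExpressionMatrix:
    """Read a genes-x-samples TSV (header row of sample ids, gene id column 0).

    duplicate_policy: how to collapse duplicated gene rows —
    ``error`` (default, safest for signatures), ``max`` or ``mean``.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate sample ids {dups[:5]}")
    non_numeric = df.columns[[not pd.api.types.is_numeric_dtype(df[c]) for c in df.columns]]
    if len(non_numeric):
        col = non_numeric[0]
        bad = df[col][pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
        row = bad.index[0] if len(bad) else "?"
        raise ValueError(f"{path}: non-numeric cell at gene {row!r}, sample {col!r}")
    if df.index.has_duplicates:
        if duplicate_policy == "error":
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"{path}: duplicate gene rows {dups[:5]} (duplicate_policy='error')")
        if duplicate_policy not in ("max", "mean"):
            raise ValueError(f"unknown duplicate_policy {duplicate_policy!r}")
        df = df.groupby(level=0, sort=False).agg(duplicate_policy)
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df.astype(float), layout)


def write_expression_matrix(mat: ExpressionMatrix, path) -> None:
    mat.data.to_csv(path, sep="\t", index_label="gene_id")


def read_maf(path) -> MutationTable:
    """Read a MAF-subset TSV. Only Hugo_Symbol / Tumor_Sample_Barcode /
    Variant_Classification are mandatory; allele-count and locus columns are
    optional and extra columns are ignored. Unknown variant classes are kept
    verbatim but flagged with a warning."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"Chromosome": str})
    for col in MAF_REQUIRED:
        if col not in df.columns:
            raise ValueError(f"{path}: missing mandatory MAF column {col!r}")
    records = pd.DataFrame(
        {
            "sample_id": df["Tumor_Sample_Barcode"].astype(str),
            "gene": df["Hugo_Symbol"].astype(str),
            "variant_classification": df["Variant_Classification"].astype(str),
            "chrom": df["Chromosome"].astype(str) if "Chromosome" in df else pd.NA,
            "position": df["Start_Position"] if "Start_Position" in df else pd.NA,
            "ref_count": pd.to_numeric(df["t_ref_count"], errors="coerce") if "t_ref_count" in df else np.nan,
            "alt_count": pd.to_numeric(df["t_alt_count"], errors="coerce") if "t_alt_count" in df else np.nan,
        }
    )
    unknown = sorted(set(records["variant_classification"]) - KNOWN_VARIANT_CLASSES)
    if unknown:
        warnings.warn(f"unknown variant classes retained: {unknown}", stacklevel=2)
    return MutationTable(records)


def write_maf(mut: MutationTable, path) -> None:
    out = pd.DataFrame(
        {
            "Hugo_Symbol": mut.records["gene"],
            "Tumor_Sample_Barcode": mut.records["sample_id"],
            "Variant_Classification": mut.records["variant_classification"],
            "Chromosome": mut.records["chrom"],
            "Start_Position": mut.records["position"],
            "t_ref_count": mut.records["ref_count"],
            "t_alt_count": mut.records["alt_count"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3")
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            sets[name] = {g for g in fields[2:] if g}
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path, descriptions: dict[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name in collection.names():
            genes = sorted(collection[name])
            fh.write("\t".join([name, descriptions.get(name, "na"), *genes]) + "\n")


def load_table1_signature() -> GeneSetCollection:
    """Load the packaged IRPM marker-gene signature.

    Two signed sets: ``IRPM_positive`` (35 genes positively correlated with
    prognostic immune-cell infiltration) and ``IRPM_negative`` (12 negatively
    correlated genes).
    """
    ref = resources.files("latgc.data").joinpath("irpm_table1.gmt")
    with resources.as_file(ref) as path:
        collection = read_gmt(path)
    signs = {
        "IRPM_positive": {g: 1 for g in collection["IRPM_positive"]},
        "IRPM_negative": {g: -1 for g in collection["IRPM_negative"]},
    }
    return GeneSetCollection({n: set(collection[n]) for n in collection.names()}, signs)


def read_clinical(path) -> CohortClinical:
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: missing sample_id column")
    df = df.set_index("sample_id")
    df.index = df.index.astype(str)
    return CohortClinical(df)


def write_clinical(clinical: CohortClinical, path) -> None:
    clinical.table.to_csv(path, sep="\t", index_label="sample_id")
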