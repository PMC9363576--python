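"""Readers, writers and global input filters for the subtyping pipeline.

All tabular formats are plain tab-separated text: expression matrices are
genes x samples with the gene identifier in the first column, gene sets use
the standard GMT layout, and clinical / mutation tables are headered TSV.
Identifiers are matched case-sensitively throughout.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Scale",
    "ExpressionMatrix",
    "GeneSetCollection",
    "SurvivalTable",
    "MutationTable",
    "DEFAULT_VARIANT_CLASSES",
    "NONSILENT_CLASSES",
    "read_expression",
    "write_expression",
    "read_gene_sets",
    "write_gene_sets",
    "filter_expressed_genes",
    "log_transform",
    "read_survival",
    "write_survival",
    "read_mutations",
    "write_mutations",
]


class Scale(str, enum.Enum):
    """Expression scale: raw TPM or log2(TPM+1)."""

    TPM = "TPM"
    LOG2_TPM1 = "LOG2_TPM1"


@dataclass
class ExpressionMatrix:
    """Genes x samples numeric matrix with an explicit scale flag.

    Invariants enforced at construction: unique gene and sample identifiers,
    no missing values, and non-negative values on the TPM scale.
    """

    data: pd.DataFrame
    scale: Scale = Scale.TPM

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            raise TypeError("expression data must be a pandas DataFrame")
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate gene identifier: {dup!r}")
        if self.data.columns.duplicated().any():
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise ValueError(f"duplicate sample identifier: {dup!r}")
        if self.data.isna().any().any():
            gene, sample = _first_na(self.data)
            raise ValueError(f"missing value at gene {gene!r}, sample {sample!r}")
        self.data = self.data.astype(float)
        if self.scale is Scale.TPM and (self.data.values < 0).any():
            raise ValueError("negative values are not valid on the TPM scale")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.values

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class GeneSetCollection:
    """Named gene lists (order-preserving, genes unique within a set)."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"gene set {name!r} contains duplicate genes")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    @property
    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class SurvivalTable:
    """Per-sample disease-free survival: time in days, event flag, covariates.

    ``data`` is indexed by sample id with columns ``time_days`` (positive),
    ``event`` (0/1) and any number of categorical covariate columns.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("time_days", "event"):
            if col not in self.data.columns:
                raise ValueError(f"survival table missing required column {col!r}")
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate sample identifier: {dup!r}")
        if self.data["time_days"].isna().any() or self.data["event"].isna().any():
            raise ValueError("survival table contains missing time/event values")
        if (self.data["time_days"] <= 0).any():
            bad = self.data.index[self.data["time_days"] <= 0][0]
            raise ValueError(f"non-positive survival time for sample {bad!r}")
        if not self.data["event"].isin([0, 1]).all():
            bad = self.data.index[~self.data["event"].isin([0, 1])][0]
            raise ValueError(f"event flag must be 0/1 (sample {bad!r})")
        self.data = self.data.assign(
            time_days=self.data["time_days"].astype(float),
            event=self.data["event"].astype(int),
        )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def time(self) -> pd.Series:
        return self.data["time_days"]

    @property
    def event(self) -> pd.Series:
        return self.data["event"]

    def subset(self, sample_ids) -> "SurvivalTable":
        return SurvivalTable(self.data.loc[list(sample_ids)].copy())


# Standard MAF variant-classification vocabulary.
DEFAULT_VARIANT_CLASSES = (
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
    "Intron",
    "3'UTR",
    "5'UTR",
    "3'Flank",
    "5'Flank",
    "IGR",
    "RNA",
)

# Nonsynonymous classes counted toward tumor mutational burden by default.
NONSILENT_CLASSES = frozenset(DEFAULT_VARIANT_CLASSES[:9])


@dataclass
class MutationTable:
    """Simplified MAF: one record per (sample, gene, variant class)."""

    data: pd.DataFrame
    vocabulary: tuple[str, ...] = DEFAULT_VARIANT_CLASSES

    def __post_init__(self) -> None:
        for col in ("sample_id", "gene", "variant_class"):
            if col not in self.data.columns:
                raise ValueError(f"mutation table missing required column {col!r}")
        unknown = sorted(
            set(self.data["variant_class"]) - set(self.vocabulary)
        )
        self.unknown_classes = unknown
        if unknown:
            warnings.warn(
                f"mutation table contains variant classes outside the declared "
                f"vocabulary (kept, flagged): {unknown}",
                stacklevel=2,
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(pd.unique(self.data["sample_id"]))

    def __len__(self) -> int:
        return len(self.data)


def _first_na(df: pd.DataFrame) -> tuple[str, str]:
    mask = df.isna()
    rows, cols = np.nonzero(mask.values)
    return str(df.index[rows[0]]), str(df.columns[cols[0]])


def read_expression(path, scale_hint: Scale = Scale.TPM) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column gene id, header = sample ids).

    Duplicate gene rows are collapsed by the per-cell maximum (with a
    warning); duplicate sample columns and non-numeric cells are errors.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    seen = set()
    for col in header:
        if col in seen:
            raise ValueError(f"duplicate sample identifier: {col!r}")
        seen.add(col)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    raw.columns = header
    raw.index.name = None
    df = raw.apply(pd.to_numeric, errors="coerce")
    bad = df.isna() & raw.notna()
    if bad.any().any():
        rows, cols = np.nonzero(bad.values)
        gene, sample = str(df.index[rows[0]]), str(df.columns[cols[0]])
        raise ValueError(
            f"non-numeric cell at gene {gene!r}, sample {sample!r}: "
            f"{raw.iloc[rows[0], cols[0]]!r}"
        )
    if df.isna().any().any():
        gene, sample = _first_na(df)
        raise ValueError(f"missing value (NA) at gene {gene!r}, sample {sample!r}")
    if df.index.duplicated().any():
        dups = sorted(set(df.index[df.index.duplicated()]))
        warnings.warn(
            f"{len(dups)} duplicated gene row(s) collapsed by per-cell maximum: "
            f"{dups[:5]}{'...' if len(dups) > 5 else ''}",
            stacklevel=2,
        )
        df = df.groupby(level=0, sort=False).max()
    return ExpressionMatrix(df, scale=Scale(scale_hint))


def write_expression(X: ExpressionMatrix, path) -> None:
    X.data.to_csv(path, sep="\t", index_label="gene_id")


def read_gene_sets(path) -> GeneSetCollection:
    """Parse a GMT file: name, description, then genes (tab-separated)."""
    sets: dict[str, list[str]] = {}
    provenance: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: GMT line needs name, description "
                    f"and at least one gene"
                )
            name, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
            if name in sets:
                raise ValueError(f"{path}: duplicate gene-set name {name!r}")
            if not genes:
                raise ValueError(f"{path}: gene set {name!r} has zero genes")
            uniq = list(dict.fromkeys(genes))
            if len(uniq) != len(genes):
                warnings.warn(
                    f"gene set {name!r}: repeated genes de-duplicated",
                    stacklevel=2,
                )
            sets[name] = uniq
            provenance[name] = desc
    if not sets:
        warnings.warn(f"{path}: empty GMT file, returning empty collection",
                      stacklevel=2)
    return GeneSetCollection(sets=sets, provenance=provenance)


def write_gene_sets(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            desc = collection.provenance.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def filter_expressed_genes(X: ExpressionMatrix, min_prop: float = 0.5) -> ExpressionMatrix:
    """Keep genes with TPM > 0 in strictly more than ``min_prop`` of samples."""
    if X.scale is not Scale.TPM:
        raise ValueError("expression filter is defined on the TPM scale")
    frac_positive = (X.values > 0).mean(axis=1)
    keep = frac_positive > min_prop
    if not keep.any():
        raise ValueError("expression filter removed every gene")
    return ExpressionMatrix(X.data.loc[keep].copy(), scale=Scale.TPM)


def log_transform(X: ExpressionMatrix) -> ExpressionMatrix:
    """TPM -> log2(TPM + 1). Double transformation is an error."""
    if X.scale is Scale.LOG2_TPM1:
        raise ValueError("matrix is already on the log2(TPM+1) scale")
    return ExpressionMatrix(np.log2(X.data + 1.0), scale=Scale.LOG2_TPM1)


def read_survival(path, column_map: dict[str, str] | None = None) -> SurvivalTable:
    """Read a headered TSV with columns sample_id, time_days, event (+covariates)."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if column_map:
        df = df.rename(columns=column_map)
    for col in ("sample_id", "time_days", "event"):
        if col not in df.columns:
            raise ValueError(f"survival file missing required column {col!r}")
    df = df.set_index("sample_id")
    return SurvivalTable(df)


def write_survival(surv: SurvivalTable, path) -> None:
    surv.data.to_csv(path, sep="\t", index_label="sample_id")


MAF_COLUMN_MAP = {
    "Tumor_Sample_Barcode": "sample_id",
    "Hugo_Symbol": "gene",
    "Variant_Classification": "variant_class",
}


def read_mutations(
    path,
    column_map: dict[str, str] | None = None,
    vocabulary: tuple[str, ...] = DEFAULT_VARIANT_CLASSES,
) -> MutationTable:
    """Read a simplified MAF-style TSV.

    Standard MAF column names (Tumor_Sample_Barcode, Hugo_Symbol,
    Variant_Classification) are mapped automatically; ``column_map`` can
    supply additional renames. Unknown variant classes are kept but flagged.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    df = df.rename(columns=MAF_COLUMN_MAP)
    if column_map:
        df = df.rename(columns=column_map)
    for col in ("sample_id", "gene", "variant_class"):
        if col not in df.columns:
            raise ValueError(f"mutation file missing required column {col!r}")
    return MutationTable(df[["sample_id", "gene", "variant_class"]].copy(),
                         vocabulary=vocabulary)


def write_mutations(muts: MutationTable, path) -> None:
    muts.data.to_csv(path, sep="\t", index=False)
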