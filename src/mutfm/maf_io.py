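"""Reading somatic mutation calls (MAF) and building the binary gene x sample matrix.

A MAF (Mutation Annotation Format) file is a tab-separated table of somatic
variant calls, one row per called variant.  For subtype modelling only three
columns matter: the gene symbol (``Hugo_Symbol``), the sample barcode
(``Tumor_Sample_Barcode``) and the functional consequence
(``Variant_Classification``).  Everything downstream operates on the binary
presence/absence matrix: entry (sample, gene) is 1 iff the sample carries at
least one non-synonymous variant in that gene.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "MutationTable",
    "BinaryMutationMatrix",
    "CohortSummary",
    "MafFormatError",
    "NONSYNONYMOUS_CLASSES",
    "DEFAULT_CAPTURE_SIZE_MB",
    "read_maf",
    "filter_nonsynonymous",
    "build_binary_matrix",
    "summarize_cohort",
]

REQUIRED_COLUMNS = ("Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification")

#: Variant classes that alter the encoded protein.  This is the conventional
#: non-synonymous set used by maftools and most MAF-based analyses; silent,
#: UTR, intronic and flank variants are excluded.
NONSYNONYMOUS_CLASSES = frozenset(
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
    }
)

#: Default capture territory used to convert mutation counts into
#: mutations-per-megabase (TMB).  50 Mb is the conventional whole-exome
#: estimate; override when the true capture size is known.
DEFAULT_CAPTURE_SIZE_MB = 50.0


class MafFormatError(ValueError):
    """Raised when a MAF file cannot be parsed under the required contract."""


@dataclass(frozen=True)
class MutationRecord:
    """One parsed MAF row: sample barcode, gene symbol, variant class."""

    sample_id: str
    gene: str
    variant_class: str


@dataclass
class MutationTable:
    """An ordered collection of mutation records (parsed MAF rows)."""

    records: list[MutationRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def sample_ids(self) -> list[str]:
        """Distinct sample barcodes in first-appearance order."""
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.sample_id, None)
        return list(seen)

    def gene_ids(self) -> list[str]:
        """Distinct gene symbols in first-appearance order."""
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.gene, None)
        return list(seen)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "MutationTable":
        recs = [
            MutationRecord(str(s), str(g), str(v))
            for s, g, v in zip(
                df["Tumor_Sample_Barcode"], df["Hugo_Symbol"], df["Variant_Classification"]
            )
        ]
        return cls(recs)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "Hugo_Symbol": [r.gene for r in self.records],
                "Tumor_Sample_Barcode": [r.sample_id for r in self.records],
                "Variant_Classification": [r.variant_class for r in self.records],
            }
        )


@dataclass
class BinaryMutationMatrix:
    """Samples x genes presence/absence matrix with aligned identifier lists.

    ``values[i, j]`` is 1 iff sample ``sample_ids[i]`` carries at least one
    retained variant in gene ``gene_ids[j]``.
    """

    values: np.ndarray
    sample_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("matrix must be 2-D (samples x genes)")
        if self.values.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.gene_ids)} genes"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample_ids")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene_ids")
        uniq = np.unique(self.values)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError("matrix entries must be 0 or 1")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def gene_frequencies(self) -> np.ndarray:
        """Fraction of samples mutated, per gene (column means)."""
        return self.values.mean(axis=0) if self.n_samples else np.zeros(self.n_genes)

    def subset_genes(self, genes: Sequence[str]) -> "BinaryMutationMatrix":
        idx = {g: j for j, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in idx]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        cols = [idx[g] for g in genes]
        return BinaryMutationMatrix(self.values[:, cols], list(self.sample_ids), list(genes))

    def subset_samples(self, rows: Sequence[int]) -> "BinaryMutationMatrix":
        rows = list(rows)
        return BinaryMutationMatrix(
            self.values[rows, :], [self.sample_ids[i] for i in rows], list(self.gene_ids)
        )

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values.astype(int), columns=self.gene_ids)
        df.insert(0, "sample_id", self.sample_ids)
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BinaryMutationMatrix":
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
        samples = df["sample_id"].tolist()
        genes = [c for c in df.columns if c != "sample_id"]
        return cls(df[genes].to_numpy(dtype=np.int8), samples, genes)


@dataclass
class CohortSummary:
    """Cohort-level mutation burden summaries over retained records."""

    tmb_per_sample: dict[str, float]
    variants_per_sample: dict[str, int]
    variant_class_counts: dict[str, int]
    capture_size_mb: float

    def median_tmb(self) -> float:
        if not self.tmb_per_sample:
            return float("nan")
        return float(np.median(list(self.tmb_per_sample.values())))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "capture_size_mb": self.capture_size_mb,
                    "tmb_per_sample": self.tmb_per_sample,
                    "variants_per_sample": self.variants_per_sample,
                    "variant_class_counts": self.variant_class_counts,
                },
                indent=2,
            )
        )


def read_maf(
    path: str | Path, required_columns: Sequence[str] = REQUIRED_COLUMNS
) -> MutationTable:
    """Parse a MAF file into a :class:`MutationTable`.

    Leading ``#`` comment lines (e.g. ``#version 2.4``) are skipped.  The
    header must contain every column in ``required_columns`` with exact,
    case-sensitive names.  Row order is preserved and no filtering is applied.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(
            path, sep="\t", comment="#", dtype=str, keep_default_na=False, low_memory=False
        )
    except pd.errors.EmptyDataError:
        raise MafFormatError(f"{path}: empty MAF file (no header)") from None
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise MafFormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    for col in ("Tumor_Sample_Barcode", "Hugo_Symbol"):
        if col in df.columns and (df[col] == "").any():
            raise MafFormatError(f"{path}: empty values in column {col}")
    return MutationTable.from_dataframe(df)


def filter_nonsynonymous(
    table: MutationTable, nonsyn_classes: Iterable[str] = NONSYNONYMOUS_CLASSES
) -> MutationTable:
    """Keep only records whose variant class is in ``nonsyn_classes``.

    Order is preserved; the operation is idempotent.
    """
    keep = frozenset(nonsyn_classes)
    if not keep:
        raise ValueError("nonsyn_classes must be non-empty")
    return MutationTable([r for r in table.records if r.variant_class in keep])


def build_binary_matrix(
    table: MutationTable, all_samples: Sequence[str] | None = None
) -> BinaryMutationMatrix:
    """Collapse mutation records into a binary samples x genes matrix.

    Any multiplicity of records for one (sample, gene) pair collapses to a
    single 1.  Gene order is first-appearance order in ``table``; sample order
    is ``all_samples`` if given (allowing all-zero rows for unmutated
    samples), else first-appearance order.
    """
    genes = table.gene_ids()
    if all_samples is not None:
        samples = list(all_samples)
        if len(set(samples)) != len(samples):
            raise ValueError("all_samples contains duplicates")
        known = set(samples)
        stray = [s for s in table.sample_ids() if s not in known]
        if stray:
            raise ValueError(
                f"table contains sample(s) absent from all_samples: {stray[:5]}"
            )
    else:
        samples = table.sample_ids()
    srow = {s: i for i, s in enumerate(samples)}
    gcol = {g: j for j, g in enumerate(genes)}
    values = np.zeros((len(samples), len(genes)), dtype=np.int8)
    for r in table.records:
        values[srow[r.sample_id], gcol[r.gene]] = 1
    return BinaryMutationMatrix(values, samples, genes)


def summarize_cohort(
    table: MutationTable, capture_size_mb: float = DEFAULT_CAPTURE_SIZE_MB
) -> CohortSummary:
    """Per-sample variant counts, TMB (count / capture Mb) and class tallies."""
    if capture_size_mb <= 0:
        raise ValueError(f"capture_size_mb must be positive, got {capture_size_mb}")
    counts: Counter[str] = Counter(r.sample_id for r in table.records)
    class_counts: Counter[str] = Counter(r.variant_class for r in table.records)
    variants = dict(counts)
    tmb = {s: c / capture_size_mb for s, c in variants.items()}
    return CohortSummary(
        tmb_per_sample=tmb,
        variants_per_sample=variants,
        variant_class_counts=dict(class_counts),
        capture_size_mb=capture_size_mb,
    )
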