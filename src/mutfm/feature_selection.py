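"""Pathway-constrained mutual-information feature selection.

The gene space of a mutation matrix is reduced in three steps:

1. **Recurrence filter** — drop genes mutated in fewer than a threshold
   fraction of samples (default 0.5%), removing ultra-rare events with no
   statistical support.
2. **Pathway grouping** — organise surviving genes by a curated pathway
   collection (GMT format, e.g. MSigDB C2) instead of data-driven clustering.
3. **Representative selection** — within each pathway keep the single gene
   whose binary mutation status carries the most mutual information about the
   subtype label, computed on training samples only.

The union of per-pathway representatives is the model's feature set.
:class:`PathwayRepresentativeSelector` exposes the procedure as a
scikit-learn transformer so it can sit inside a ``Pipeline`` and inherit its
leakage guarantees (``fit`` on the training fold, ``transform`` everywhere).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .maf_io import BinaryMutationMatrix

__all__ = [
    "PathwayCollection",
    "FeatureScore",
    "FeatureSet",
    "StabilityReport",
    "GmtFormatError",
    "read_gmt",
    "recurrence_filter",
    "mutual_information",
    "select_pathway_representatives",
    "stability_analysis",
    "PathwayRepresentativeSelector",
    "DEFAULT_RECURRENCE_THRESHOLD",
    "THRESHOLD_GRID",
]

#: Minimum mutated-sample fraction for a gene to enter selection.
DEFAULT_RECURRENCE_THRESHOLD = 0.005

#: Threshold grid used for selection-stability analysis.
THRESHOLD_GRID = (0.01, 0.005, 0.0025, 0.001)


class GmtFormatError(ValueError):
    """Raised on malformed GMT gene-set files."""


@dataclass
class PathwayCollection:
    """Named gene sets; each pathway maps to an ordered, de-duplicated tuple."""

    pathways: dict[str, tuple[str, ...]]

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways.items())

    def gene_universe(self) -> set[str]:
        return {g for genes in self.pathways.values() for g in genes}


@dataclass(frozen=True)
class FeatureScore:
    gene: str
    mi: float
    frequency: float


@dataclass
class FeatureSet:
    """Selected representative genes with scores and pathway provenance."""

    genes: list[str]
    scores: dict[str, FeatureScore]
    provenance: dict[str, list[str]]
    threshold: float
    n_recurrent: int = 0  # genes passing the recurrence filter before grouping

    def __len__(self) -> int:
        return len(self.genes)

    def mi_ranking(self) -> list[str]:
        """Genes ordered by decreasing MI (frequency, then symbol break ties)."""
        return sorted(
            self.genes,
            key=lambda g: (-self.scores[g].mi, -self.scores[g].frequency, g),
        )

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {
                "gene": g,
                "mi": self.scores[g].mi,
                "frequency": self.scores[g].frequency,
                "pathways": ";".join(self.provenance[g]),
            }
            for g in self.genes
        ]
        pd.DataFrame(rows, columns=["gene", "mi", "frequency", "pathways"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path: str | Path, threshold: float = float("nan")) -> "FeatureSet":
        df = pd.read_csv(path, sep="\t", dtype={"gene": str, "pathways": str})
        genes = df["gene"].tolist()
        scores = {
            r.gene: FeatureScore(r.gene, float(r.mi), float(r.frequency))
            for r in df.itertuples()
        }
        prov = {r.gene: str(r.pathways).split(";") for r in df.itertuples()}
        return cls(genes, scores, prov, threshold)


@dataclass
class StabilityReport:
    """Agreement between feature sets selected at two recurrence thresholds."""

    jaccard: float
    inclusion_rate: float
    spearman_rho: float
    n_compared: int  # genes of the stricter top list present in both sets

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "jaccard": self.jaccard,
                    "inclusion_rate": self.inclusion_rate,
                    "spearman_rho": self.spearman_rho,
                    "n_compared": self.n_compared,
                },
                indent=2,
            )
        )


def read_gmt(path: str | Path) -> PathwayCollection:
    """Parse a GMT gene-set file (name, description, member genes per line)."""
    path = Path(path)
    pathways: dict[str, tuple[str, ...]] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtFormatError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields, got {len(fields)}"
                )
            name = fields[0]
            if name in pathways:
                raise GmtFormatError(f"{path}:{lineno}: duplicate pathway name {name!r}")
            seen: dict[str, None] = {}
            for g in fields[2:]:
                if g:
                    seen.setdefault(g, None)
            if not seen:
                raise GmtFormatError(f"{path}:{lineno}: pathway {name!r} has no genes")
            pathways[name] = tuple(seen)
    return PathwayCollection(pathways)


def write_gmt(pathways: PathwayCollection, path: str | Path, description: str = "na") -> None:
    with Path(path).open("w") as fh:
        for name, genes in pathways:
            fh.write("\t".join([name, description, *genes]) + "\n")


def recurrence_filter(
    matrix: BinaryMutationMatrix, threshold: float = DEFAULT_RECURRENCE_THRESHOLD
) -> list[str]:
    """Genes mutated in >= ``threshold`` fraction of samples, in column order.

    The boundary is inclusive: a gene exactly at the threshold is retained
    (genes *below* the threshold are filtered out).
    """
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    if matrix.n_samples == 0:
        return []
    freq = matrix.gene_frequencies()
    return [g for g, f in zip(matrix.gene_ids, freq) if f >= threshold]


def mutual_information(
    x: Sequence[int] | np.ndarray,
    y: Sequence | np.ndarray,
    log_base: float | str = "e",
) -> float:
    """Plug-in mutual information I(X;Y) between two discrete variables.

    Empirical (maximum-likelihood) probabilities are used with no
    pseudocounts; cells with zero joint probability contribute 0 (the
    x log x -> 0 limit).  ``log_base`` is ``"e"`` (nats, default) or ``2``
    (bits); rankings are base-invariant.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"x and y must be 1-D of equal length, got {x.shape} vs {y.shape}")
    n = x.size
    if n == 0:
        raise ValueError("empty input")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    joint = np.zeros((xi.max() + 1, yi.max() + 1))
    np.add.at(joint, (xi, yi), 1.0)
    joint /= n
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    mi = float(np.sum(joint[nz] * np.log(joint[nz] / (px @ py)[nz])))
    mi = max(mi, 0.0)  # clip negative rounding error
    if log_base == "e":
        return mi
    return mi / math.log(float(log_base))


def _column_mi(values: np.ndarray, y_codes: np.ndarray, n_classes: int) -> np.ndarray:
    """Vectorised plug-in MI of each binary column of ``values`` against labels."""
    n, _ = values.shape
    # counts of (x=1, y=c) per gene: genes x classes
    onehot = np.zeros((n, n_classes))
    onehot[np.arange(n), y_codes] = 1.0
    c1 = values.T @ onehot  # genes x classes, count of mutated per class
    cy = onehot.sum(axis=0)  # class counts
    c0 = cy[None, :] - c1
    joint = np.stack([c0, c1], axis=1) / n  # genes x 2 x classes
    px = joint.sum(axis=2, keepdims=True)
    py = joint.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = joint * np.log(joint / (px * py))
    term[~np.isfinite(term)] = 0.0
    return np.maximum(term.sum(axis=(1, 2)), 0.0)


class PathwayRepresentativeSelector(BaseEstimator, TransformerMixin):
    """Select one maximal-MI representative gene per pathway.

    Parameters
    ----------
    pathways:
        Curated gene sets (:class:`PathwayCollection`) used as grouping prior.
    gene_ids:
        Column names of the matrices passed to :meth:`fit` / :meth:`transform`.
        May be omitted when fitting on a :class:`BinaryMutationMatrix`.
    threshold:
        Recurrence threshold; genes mutated in a smaller fraction of the
        training samples are excluded before grouping.

    Ties in MI break toward the higher mutation frequency and then the
    lexicographically smaller symbol, making selection deterministic.
    Genes outside every pathway are never selected.

    Attributes
    ----------
    feature_set_ : FeatureSet
        Selected genes with MI scores and pathway provenance.
    support_ : ndarray of bool
        Mask over input columns marking selected genes.
    """

    def __init__(
        self,
        pathways: PathwayCollection | None = None,
        gene_ids: Sequence[str] | None = None,
        threshold: float = DEFAULT_RECURRENCE_THRESHOLD,
    ):
        self.pathways = pathways
        self.gene_ids = gene_ids
        self.threshold = threshold

    def _resolve(self, X) -> tuple[np.ndarray, list[str]]:
        if isinstance(X, BinaryMutationMatrix):
            return np.asarray(X.values, dtype=np.float64), list(X.gene_ids)
        X = np.asarray(X, dtype=np.float64)
        if self.gene_ids is None:
            raise ValueError("gene_ids must be provided when X is a plain array")
        if X.shape[1] != len(self.gene_ids):
            raise ValueError(
                f"X has {X.shape[1]} columns but {len(self.gene_ids)} gene_ids given"
            )
        return X, list(self.gene_ids)

    def fit(self, X, y):
        if self.pathways is None or len(self.pathways) == 0:
            raise ValueError("a non-empty PathwayCollection is required")
        values, genes = self._resolve(X)
        y = np.asarray(y)
        if y.shape[0] != values.shape[0]:
            raise ValueError("labels are not aligned to matrix rows")
        classes, y_codes = np.unique(y, return_inverse=True)

        freq = values.mean(axis=0)
        mi_all = _column_mi(values, y_codes, len(classes))
        col = {g: j for j, g in enumerate(genes)}
        passing = {g for g, f in zip(genes, freq) if f >= self.threshold}

        selected: dict[str, None] = {}
        scores: dict[str, FeatureScore] = {}
        provenance: dict[str, list[str]] = {}
        for name, members in self.pathways:
            cands = [g for g in members if g in col and g in passing]
            if not cands:
                continue
            best = min(
                cands, key=lambda g: (-mi_all[col[g]], -freq[col[g]], g)
            )
            selected.setdefault(best, None)
            scores[best] = FeatureScore(best, float(mi_all[col[best]]), float(freq[col[best]]))
            provenance.setdefault(best, []).append(name)

        if not selected:
            warnings.warn(
                "no pathway yielded a representative gene; feature set is empty",
                stacklevel=2,
            )
        self.classes_seen_ = classes
        self.n_features_in_ = values.shape[1]
        self.gene_ids_in_ = genes
        self.feature_set_ = FeatureSet(
            genes=list(selected),
            scores=scores,
            provenance=provenance,
            threshold=self.threshold,
            n_recurrent=len(passing),
        )
        sel = set(selected)
        self.support_ = np.array([g in sel for g in genes])
        return self

    def transform(self, X):
        check_is_fitted(self, "support_")
        if isinstance(X, BinaryMutationMatrix):
            return X.subset_genes(self.feature_set_.genes)
        X = np.asarray(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} columns, expected {self.n_features_in_}"
            )
        return X[:, self.support_]

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "support_")
        return np.asarray(self.feature_set_.genes, dtype=object)


def select_pathway_representatives(
    matrix: BinaryMutationMatrix,
    labels: Sequence,
    pathways: PathwayCollection,
    threshold: float = DEFAULT_RECURRENCE_THRESHOLD,
) -> FeatureSet:
    """Functional wrapper around :class:`PathwayRepresentativeSelector`.

    ``matrix`` must be the training partition only; calling this on data that
    includes evaluation samples leaks label information into the features.
    """
    sel = PathwayRepresentativeSelector(pathways=pathways, threshold=threshold)
    sel.fit(matrix, np.asarray(labels))
    return sel.feature_set_


def stability_analysis(
    set_strict: FeatureSet, set_loose: FeatureSet, rank_depth: int
) -> StabilityReport:
    """Quantify agreement between feature sets from two recurrence thresholds.

    ``jaccard`` and ``inclusion_rate`` (fraction of the stricter set retained
    in the looser one) are set statistics.  ``spearman_rho`` correlates the
    MI-based ranks of the stricter set's top ``rank_depth`` genes as ranked
    within each set; genes absent from the looser set are excluded and their
    complement count is reported as ``n_compared``.
    """
    if rank_depth < 2:
        raise ValueError(f"rank_depth must be >= 2, got {rank_depth}")
    if rank_depth > len(set_strict):
        raise ValueError(
            f"rank_depth {rank_depth} exceeds stricter set size {len(set_strict)}"
        )
    a = set(set_strict.genes)
    b = set(set_loose.genes)
    inter = a & b
    union = a | b
    jaccard = len(inter) / len(union) if union else 1.0
    inclusion = len(inter) / len(a) if a else 1.0

    rank_a = {g: i for i, g in enumerate(set_strict.mi_ranking())}
    rank_b = {g: i for i, g in enumerate(set_loose.mi_ranking())}
    top = set_strict.mi_ranking()[:rank_depth]
    shared = [g for g in top if g in rank_b]
    if len(shared) >= 2:
        ra = [rank_a[g] for g in shared]
        rb = [rank_b[g] for g in shared]
        if len(set(ra)) == 1 or len(set(rb)) == 1:
            rho = 1.0 if ra == rb else 0.0
        else:
            rho = float(stats.spearmanr(ra, rb).statistic)
    else:
        rho = float("nan")
    return StabilityReport(
        jaccard=float(jaccard),
        inclusion_rate=float(inclusion),
        spearman_rho=rho,
        n_compared=len(shared),
    )
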