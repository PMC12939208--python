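"""Synthetic mutation cohorts with the statistical structure the method assumes.

A cohort is a sparse binary samples x genes matrix in which

* most genes are uninformative background: gene g is mutated i.i.d. with a
  rate drawn log-uniformly from a low range, reproducing the long-tailed
  recurrence distribution of real tumor cohorts;
* a small minority of *informative* genes have Bernoulli rates that depend
  on the sample's class, mimicking subtype-associated drivers (elevated in
  one subtype, near-background elsewhere);
* classes are imbalanced (the default preset approximates the Luminal A /
  Luminal B / Basal-like / HER2-enriched mix of breast cancer cohorts);
* a pathway collection partitions part of the gene space, with each
  informative gene planted in exactly one pathway among noise genes;
* optionally, *interacting pairs*: two genes that co-occur (both mutated or
  neither, marginal rate ``interaction_rate``) in their associated class but
  are independent with marginal ``interaction_off_rate`` elsewhere.  Their
  class signal is partly second-order — the pattern "exactly one of the two
  mutated" excludes the associated class — which a purely linear model
  cannot express; these pairs make architecture ablations informative.

The generator records the planted truth so tests can score recovery, and it
can write MAF/GMT fixture files whose round-trip through the I/O modules
reproduces the cohort exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .feature_selection import PathwayCollection, write_gmt
from .maf_io import (
    NONSYNONYMOUS_CLASSES,
    BinaryMutationMatrix,
    build_binary_matrix,
    filter_nonsynonymous,
    read_maf,
)

__all__ = [
    "SyntheticConfig",
    "SyntheticCohort",
    "informative_rate_matrix",
    "tcga_like_config",
    "generate_cohort",
    "write_fixture_maf",
    "write_fixture_gmt",
    "reconstruct_matrix_from_maf",
    "bayes_reference",
    "DEFAULT_CLASS_NAMES",
]

DEFAULT_CLASS_NAMES = ("LumA", "LumB", "Basal", "Her2")

#: Off-class baseline rate of an informative gene.  Real subtype drivers are
#: mutated in a few percent of tumors outside their associated subtype.
DEFAULT_OFF_RATE = 0.02

#: Default elevation of an informative gene in its associated class.
DEFAULT_RATE_GAP = 0.4


def informative_rate_matrix(
    n_classes: int,
    n_informative: int,
    off_rate: float = DEFAULT_OFF_RATE,
    gap: float = DEFAULT_RATE_GAP,
) -> np.ndarray:
    """C x n_informative rates: gene j is elevated to ``off_rate + gap`` in
    class ``j % C`` and sits at ``off_rate`` elsewhere (driver-like)."""
    rates = np.full((n_classes, n_informative), off_rate, dtype=float)
    for j in range(n_informative):
        rates[j % n_classes, j] = off_rate + gap
    return rates


@dataclass
class SyntheticConfig:
    """Generator settings; defaults emulate a TCGA-scale mutation cohort."""

    n_samples: int = 900
    class_proportions: tuple[float, ...] = (0.47, 0.21, 0.21, 0.11)
    class_names: tuple[str, ...] = DEFAULT_CLASS_NAMES
    n_genes: int = 2500
    n_pathways: int = 200
    genes_per_pathway: int = 10
    n_informative: int = 10
    background_rate_range: tuple[float, float] = (0.001, 0.02)
    background_mode: str = "loguniform"  # or "fixed" (rate = low bound)
    informative_rates: np.ndarray | None = None  # C x n_informative
    n_interacting_pairs: int = 0
    interaction_rate: float = 0.4
    interaction_off_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        props = np.asarray(self.class_proportions, dtype=float)
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError("class_proportions must sum to 1")
        if len(self.class_names) != len(props):
            raise ValueError("class_names and class_proportions disagree on C")
        if self.n_informative > self.n_genes:
            raise ValueError("n_informative exceeds n_genes")
        if self.n_pathways * self.genes_per_pathway > self.n_genes:
            raise ValueError("pathway layout needs more genes than available")
        if self.n_informative + 2 * self.n_interacting_pairs > self.n_pathways:
            raise ValueError("each planted gene needs its own pathway")
        if self.n_informative + 2 * self.n_interacting_pairs > self.n_genes:
            raise ValueError("planted genes exceed n_genes")
        if not 0 <= self.interaction_off_rate <= self.interaction_rate <= 1:
            raise ValueError("need 0 <= interaction_off_rate <= interaction_rate <= 1")
        lo, hi = self.background_rate_range
        if not (0 < lo <= hi < 1):
            raise ValueError("background_rate_range must satisfy 0 < low <= high < 1")
        if self.background_mode not in ("loguniform", "fixed"):
            raise ValueError("background_mode must be 'loguniform' or 'fixed'")
        if self.informative_rates is None:
            self.informative_rates = informative_rate_matrix(len(props), self.n_informative)
        self.informative_rates = np.asarray(self.informative_rates, dtype=float)
        if self.informative_rates.shape != (len(props), self.n_informative):
            raise ValueError(
                f"informative_rates shape {self.informative_rates.shape} != "
                f"({len(props)}, {self.n_informative})"
            )
        if ((self.informative_rates < 0) | (self.informative_rates > 1)).any():
            raise ValueError("informative_rates must lie in [0, 1]")


def tcga_like_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """The default preset: 900 samples, 4 imbalanced classes, 2500 genes,
    200 pathways of 10 genes, 10 driver-like informative genes."""
    return SyntheticConfig(seed=seed, **overrides)


@dataclass
class SyntheticCohort:
    """Generated cohort plus the planted ground truth."""

    matrix: BinaryMutationMatrix
    labels: np.ndarray  # class name per sample, aligned to matrix rows
    pathways: PathwayCollection
    informative_genes: list[str]
    truth_rates: dict[str, list[float]]  # gene -> per-class Bernoulli rates
    background_rates: dict[str, float]
    config: SyntheticConfig
    interacting_pairs: list[tuple[str, str, str]] = field(default_factory=list)

    def truth_to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "informative_genes": self.informative_genes,
                    "truth_rates": self.truth_rates,
                    "class_names": list(self.config.class_names),
                },
                indent=2,
            )
        )


def _largest_remainder_sizes(n: int, proportions: np.ndarray) -> np.ndarray:
    """Deterministic apportionment of n samples to class proportions."""
    raw = n * proportions
    sizes = np.floor(raw).astype(int)
    rem = raw - sizes
    short = n - sizes.sum()
    for i in np.argsort(-rem)[:short]:
        sizes[i] += 1
    return sizes


def generate_cohort(config: SyntheticConfig | None = None) -> SyntheticCohort:
    """Draw a cohort: multinomial-rounded class sizes, log-uniform background
    rates, class-dependent informative rates, planted pathway structure.
    Deterministic given ``config.seed``."""
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    props = np.asarray(config.class_proportions)
    n_classes = len(props)

    sizes = _largest_remainder_sizes(config.n_samples, props)
    y_codes = np.repeat(np.arange(n_classes), sizes)
    rng.shuffle(y_codes)
    labels = np.asarray(config.class_names, dtype=object)[y_codes]
    sample_ids = [f"S{i:04d}" for i in range(config.n_samples)]

    width = len(str(config.n_genes))
    gene_ids = [f"G{j:0{width}d}" for j in range(config.n_genes)]
    perm = rng.permutation(config.n_genes)
    informative_idx = perm[: config.n_informative]
    n_pair_genes = 2 * config.n_interacting_pairs
    pair_idx = perm[config.n_informative : config.n_informative + n_pair_genes]
    planted = list(informative_idx) + list(pair_idx)
    noise_pool = list(perm[config.n_informative + n_pair_genes :])

    # pathway layout: the first pathways each hold one planted gene plus
    # noise genes; remaining pathways are all noise
    pathway_members: dict[str, tuple[str, ...]] = {}
    cursor = 0
    for p in range(config.n_pathways):
        members: list[int] = []
        if p < len(planted):
            members.append(int(planted[p]))
        need = config.genes_per_pathway - len(members)
        members.extend(int(j) for j in noise_pool[cursor : cursor + need])
        cursor += need
        pathway_members[f"PW{p:04d}"] = tuple(gene_ids[j] for j in sorted(members))
    pathways = PathwayCollection(pathway_members)

    lo, hi = config.background_rate_range
    if config.background_mode == "loguniform":
        rates = np.exp(rng.uniform(np.log(lo), np.log(hi), size=config.n_genes))
    else:
        rates = np.full(config.n_genes, lo)

    # per-sample per-gene rates: background everywhere, then overwrite the
    # informative columns with class-dependent rates
    rate_matrix = np.tile(rates, (config.n_samples, 1))
    rate_matrix[:, informative_idx] = config.informative_rates[y_codes, :]
    values = (rng.random((config.n_samples, config.n_genes)) < rate_matrix).astype(np.int8)

    interacting_pairs: list[tuple[str, str, str]] = []
    for q in range(config.n_interacting_pairs):
        c = q % n_classes
        g1, g2 = int(pair_idx[2 * q]), int(pair_idx[2 * q + 1])
        own = y_codes == c
        z = (rng.random(int(own.sum())) < config.interaction_rate).astype(np.int8)
        values[own, g1] = z  # perfect co-occurrence within the class
        values[own, g2] = z
        n_off = int((~own).sum())
        values[~own, g1] = (rng.random(n_off) < config.interaction_off_rate).astype(np.int8)
        values[~own, g2] = (rng.random(n_off) < config.interaction_off_rate).astype(np.int8)
        interacting_pairs.append(
            (gene_ids[g1], gene_ids[g2], str(config.class_names[c]))
        )

    matrix = BinaryMutationMatrix(values, sample_ids, gene_ids)
    informative_genes = [gene_ids[j] for j in informative_idx]
    truth_rates = {
        gene_ids[j]: [float(r) for r in config.informative_rates[:, pos]]
        for pos, j in enumerate(informative_idx)
    }
    non_background = set(informative_idx) | set(pair_idx)
    background = {
        gene_ids[j]: float(rates[j])
        for j in range(config.n_genes)
        if j not in non_background
    }
    return SyntheticCohort(
        matrix=matrix,
        labels=labels,
        pathways=pathways,
        informative_genes=informative_genes,
        truth_rates=truth_rates,
        background_rates=background,
        config=config,
        interacting_pairs=interacting_pairs,
    )


def write_fixture_maf(
    cohort: SyntheticCohort,
    path: str | Path,
    silent_rate: float = 0.0,
    seed: int = 0,
) -> None:
    """Write the cohort as a MAF file.

    One row per mutated (sample, gene) cell, with a non-synonymous variant
    class drawn at random.  ``silent_rate`` optionally sprinkles extra
    ``Silent``/``3'UTR`` rows (a fraction of the mutated-cell count at random
    cells) to exercise the non-synonymous filter; they are removed by
    filtering and never change the reconstructed matrix.  Rows are emitted
    gene-major so that first-appearance gene order matches the cohort's
    column order restricted to mutated genes.
    """
    rng = np.random.default_rng(seed)
    values = cohort.matrix.values
    samples = cohort.matrix.sample_ids
    genes = cohort.matrix.gene_ids
    nonsyn = sorted(NONSYNONYMOUS_CLASSES)
    rows: list[tuple[str, str, str]] = []
    gj, si = np.nonzero(values.T)  # gene-major ordering
    for j, i in zip(gj, si):
        rows.append((genes[j], samples[i], nonsyn[rng.integers(len(nonsyn))]))
    n_silent = int(round(silent_rate * len(rows)))
    for _ in range(n_silent):
        i = int(rng.integers(len(samples)))
        j = int(rng.integers(len(genes)))
        cls = "Silent" if rng.random() < 0.5 else "3'UTR"
        rows.append((genes[j], samples[i], cls))
    with Path(path).open("w") as fh:
        fh.write("#version 2.4\n")
        fh.write("Hugo_Symbol\tTumor_Sample_Barcode\tVariant_Classification\n")
        for g, s, v in rows:
            fh.write(f"{g}\t{s}\t{v}\n")


def write_fixture_gmt(cohort: SyntheticCohort, path: str | Path) -> None:
    """Write the cohort's pathway collection in GMT format."""
    write_gmt(cohort.pathways, path)


def bayes_reference(
    config: SyntheticConfig, n: int = 200_000, seed: int = 0
) -> dict[str, float]:
    """Monte-Carlo accuracy and macro-F1 of the Bayes-optimal classifier.

    Under the generating model the background genes are class-independent,
    so the exact posterior over classes depends only on the informative
    columns; this evaluates the argmax-posterior rule (true rates, true
    priors) on ``n`` fresh samples.  No trained model can beat these numbers
    in expectation — they are the information ceiling of a cohort
    configuration.  Requires ``n_interacting_pairs == 0`` (with planted
    dependence the posterior is no longer a product over genes).
    """
    if config.n_interacting_pairs != 0:
        raise ValueError("bayes_reference assumes independent informative genes")
    rng = np.random.default_rng(seed)
    priors = np.asarray(config.class_proportions, dtype=float)
    rates = np.clip(config.informative_rates, 1e-12, 1 - 1e-12)  # C x G
    C = len(priors)
    y = rng.choice(C, size=n, p=priors)
    X = (rng.random((n, rates.shape[1])) < rates[y]).astype(float)
    log_post = np.log(priors) + X @ np.log(rates.T) + (1 - X) @ np.log(1 - rates.T)
    pred = log_post.argmax(axis=1)
    f1s = []
    for c in range(C):
        tp = np.sum((pred == c) & (y == c))
        fp = np.sum((pred == c) & (y != c))
        fn = np.sum((pred != c) & (y == c))
        prec = tp / (tp + fp) if tp + fp else 0.0
        sens = tp / (tp + fn) if tp + fn else 0.0
        f1s.append(2 * prec * sens / (prec + sens) if prec + sens else 0.0)
    return {
        "accuracy": float(np.mean(pred == y)),
        "macro_f1": float(np.mean(f1s)),
    }


def reconstruct_matrix_from_maf(
    path: str | Path, sample_ids: Sequence[str], gene_ids: Sequence[str]
) -> BinaryMutationMatrix:
    """Read a fixture MAF back into a matrix aligned to the given identifier
    lists (genes never mutated become all-zero columns)."""
    table = filter_nonsynonymous(read_maf(path))
    partial = build_binary_matrix(table, all_samples=list(sample_ids))
    values = np.zeros((len(sample_ids), len(gene_ids)), dtype=np.int8)
    col = {g: j for j, g in enumerate(gene_ids)}
    for jsrc, g in enumerate(partial.gene_ids):
        values[:, col[g]] = partial.values[:, jsrc]
    return BinaryMutationMatrix(values, list(sample_ids), list(gene_ids))
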