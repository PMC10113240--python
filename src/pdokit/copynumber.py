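"""Allele-specific copy-number indices and cross-sample similarity.

Two per-sample genomic indices summarise a segmented allele-specific
copy-number profile:

* allele-specific ploidy (asP) — the segment-length-weighted mean of
  cnA+cnB, i.e. 2 for a diploid genome;
* genomic burden (GB) — the length-weighted fraction of the genome whose
  allele-specific state differs from the wild-type (1, 1). A uniformly
  triploid or tetraploid genome has GB = 1.

For cohort comparisons, continuous segment copy numbers are discretised
gene-wise (each gene takes the rounded state of the segment containing
its midpoint) and the per-gene major/minor copy-number vectors of two
samples are compared by Euclidean distance. Distances are min-max
rescaled over all off-diagonal pairs, and similarity is s = 1 - d'.
Matched tumor/organoid pairs can then be tested against all remaining
cross-sample pairs with a two-sided rank-sum test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from ._stats import rank_sum_test, round_half_away
from .types import GenePanel, SegmentProfile, TumorClass


def compute_asp(profile: SegmentProfile) -> float:
    """Allele-specific ploidy: length-weighted mean of cnA+cnB over segments."""
    if not profile.segments:
        raise ValueError(f"{profile.sample_id}: cannot compute asP on an empty profile")
    weights = np.array([s.length for s in profile.segments], dtype=float)
    totals = np.array([s.total_cn for s in profile.segments], dtype=float)
    return float(np.sum(totals * weights) / np.sum(weights))


def compute_gb(profile: SegmentProfile, tol: float = 1e-9) -> float:
    """Genomic burden: length-weighted fraction of genome not in state (1, 1)."""
    if not profile.segments:
        raise ValueError(f"{profile.sample_id}: cannot compute GB on an empty profile")
    weights = np.array([s.length for s in profile.segments], dtype=float)
    aberrant = np.array(
        [abs(s.cn_a - 1.0) > tol or abs(s.cn_b - 1.0) > tol for s in profile.segments],
        dtype=float,
    )
    return float(np.sum(aberrant * weights) / np.sum(weights))


@dataclass
class GeneCnMatrix:
    """Cohort x gene discrete allele-specific copy numbers (complete cases)."""

    samples: list[str]
    genes: list[str]
    cn_a: np.ndarray  # (n_samples, n_genes) int
    cn_b: np.ndarray

    def __post_init__(self) -> None:
        self.cn_a = np.asarray(self.cn_a)
        self.cn_b = np.asarray(self.cn_b)
        if self.cn_a.shape != (len(self.samples), len(self.genes)):
            raise ValueError("cn_a shape does not match samples x genes")
        if self.cn_b.shape != self.cn_a.shape:
            raise ValueError("cn_a and cn_b shapes differ")
        if (self.cn_a < self.cn_b).any():
            raise ValueError("cnA < cnB at some (sample, gene) entry")

    def index_of(self, sample_id: str) -> int:
        try:
            return self.samples.index(sample_id)
        except ValueError as exc:
            raise KeyError(f"sample {sample_id!r} not in matrix") from exc


def project_to_genes(profiles: list[SegmentProfile], panel: GenePanel) -> GeneCnMatrix:
    """Discretise profiles gene-wise: each gene takes the rounded (cnA, cnB)
    of the segment containing its midpoint.

    Genes whose midpoint is not covered by any segment in *some* sample are
    dropped for the whole cohort (complete-case rule), so downstream
    distances always compare identical gene vectors.
    """
    if len(panel) == 0:
        raise ValueError("gene panel is empty")
    n_samples, n_genes = len(profiles), len(panel)
    cn_a = np.zeros((n_samples, n_genes))
    cn_b = np.zeros((n_samples, n_genes))
    covered = np.ones(n_genes, dtype=bool)
    for i, prof in enumerate(profiles):
        for j, gene in enumerate(panel):
            seg = prof.segment_at(gene.chrom, gene.midpoint)
            if seg is None:
                covered[j] = False
            else:
                cn_a[i, j] = seg.cn_a
                cn_b[i, j] = seg.cn_b
    if not covered.all():
        dropped = [g.gene for g, c in zip(panel, covered) if not c]
        warnings.warn(
            f"dropped {len(dropped)} gene(s) uncovered in at least one sample",
            stacklevel=2,
        )
    if not covered.any():
        warnings.warn("no gene is covered in every sample; matrix is empty", stacklevel=2)
    # round half away from zero, floor at 0; enforce cnA >= cnB after rounding
    a = np.maximum(round_half_away(cn_a[:, covered]), 0).astype(int)
    b = np.maximum(round_half_away(cn_b[:, covered]), 0).astype(int)
    hi, lo = np.maximum(a, b), np.minimum(a, b)
    genes = [g.gene for g, c in zip(panel, covered) if c]
    return GeneCnMatrix(samples=[p.sample_id for p in profiles], genes=genes, cn_a=hi, cn_b=lo)


def cn_distance(matrix: GeneCnMatrix, k1: str, k2: str) -> float:
    """Euclidean distance between concatenated (cnA, cnB) gene vectors."""
    if not matrix.genes:
        raise ValueError("no shared genes: distance undefined")
    i, j = matrix.index_of(k1), matrix.index_of(k2)
    v1 = np.concatenate([matrix.cn_a[i], matrix.cn_b[i]]).astype(float)
    v2 = np.concatenate([matrix.cn_a[j], matrix.cn_b[j]]).astype(float)
    return float(np.linalg.norm(v1 - v2))


@dataclass
class SimilarityResult:
    """Pairwise distances, min-max rescaled distances, and s = 1 - d'."""

    samples: list[str]
    distance: np.ndarray
    dprime: np.ndarray
    similarity: np.ndarray
    matched_pairs: list[tuple[str, str]] = field(default_factory=list)

    def pair_similarity(self, k1: str, k2: str) -> float:
        i = self.samples.index(k1)
        j = self.samples.index(k2)
        return float(self.similarity[i, j])


def similarity(
    matrix: GeneCnMatrix,
    matched_pairs: list[tuple[str, str]] | None = None,
) -> SimilarityResult:
    """Pairwise copy-number similarity over the whole cohort.

    Distances are rescaled over all off-diagonal pairs: the closest pair in
    the cohort attains s = 1, the most dissimilar pair s = 0.
    """
    n = len(matrix.samples)
    if n < 2:
        raise ValueError("similarity requires >= 2 samples")
    vec = np.hstack([matrix.cn_a, matrix.cn_b]).astype(float)
    dmat = _pairwise(vec)
    d = squareform(dmat, checks=False)  # off-diagonal entries only
    lo, hi = d.min(), d.max()
    if hi <= lo:
        raise ValueError("all pairwise distances are equal; rescaling undefined")
    dprime = (dmat - lo) / (hi - lo)
    np.fill_diagonal(dprime, 0.0)
    sim = 1.0 - dprime
    np.fill_diagonal(sim, 1.0)
    return SimilarityResult(
        samples=list(matrix.samples),
        distance=dmat,
        dprime=dprime,
        similarity=sim,
        matched_pairs=list(matched_pairs or []),
    )


def _pairwise(vec: np.ndarray) -> np.ndarray:
    diff = vec[:, None, :] - vec[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


def matched_vs_random_test(result: SimilarityResult) -> tuple[float, int, int]:
    """Two-sided rank-sum test: matched-pair similarities vs all remaining
    cross-sample pair similarities.

    Returns ``(p, n_matched, n_random)`` with
    ``n_random = C(n_samples, 2) - n_matched``.
    """
    if not result.matched_pairs:
        raise ValueError("no matched pairs supplied")
    idx = {s: i for i, s in enumerate(result.samples)}
    matched_idx = {tuple(sorted((idx[a], idx[b]))) for a, b in result.matched_pairs}
    matched, random_ = [], []
    n = len(result.samples)
    for i in range(n):
        for j in range(i + 1, n):
            (matched if (i, j) in matched_idx else random_).append(result.similarity[i, j])
    if len(matched) == 1 and len(random_) <= 1:
        return 1.0, len(matched), len(random_)
    p = rank_sum_test(matched, random_)
    return p, len(matched), len(random_)


@dataclass
class Dendrogram:
    """Agglomerative clustering of samples on the pairwise distance matrix."""

    labels: list[str]
    linkage: np.ndarray  # scipy linkage matrix
    method: str = "average"

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def walk(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            left, right = walk(node.left), walk(node.right)
            dl = node.dist - node.left.dist
            dr = node.dist - node.right.dist
            return f"({left}:{dl:.6g},{right}:{dr:.6g})"

        return walk(tree) + ";"

    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]


def cluster_profiles(result: SimilarityResult, method: str = "average") -> Dendrogram:
    """Average-linkage agglomerative clustering on the distance matrix."""
    if len(result.samples) < 3:
        raise ValueError("clustering requires >= 3 samples")
    condensed = squareform(result.distance, checks=False)
    link = hierarchy.linkage(condensed, method=method)
    return Dendrogram(labels=list(result.samples), linkage=link, method=method)


def ordinal_trend(values, classes) -> tuple[float, float]:
    """Kendall tau-b (tie-corrected) between ordered tumor classes and values.

    ``classes`` may contain :class:`TumorClass` members or their string
    values; the class ordering NMIBC_LG < NMIBC_HG < MIBC is used.
    """
    ranks = np.array([TumorClass(c).rank for c in classes], dtype=float)
    vals = np.asarray(values, dtype=float)
    if np.unique(ranks).size < 2:
        raise ValueError("ordinal trend requires >= 2 distinct classes")
    if np.unique(vals).size < 2:
        raise ValueError("constant values: tau undefined")
    res = stats.kendalltau(ranks, vals, variant="b")
    return float(res.statistic), float(res.pvalue)
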