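"""Kimura 2-parameter distances on genotype pseudo-sequences, UPGMA trees,
locus-resampling bootstrap supports and Newick export.

Diploid SNP genotypes are expanded into two nucleotide characters per locus
(sorted alphabetically for heterozygotes, ``N`` for missing) rather than
IUPAC ambiguity codes: that keeps transition/transversion counting
well-defined for heterozygotes and lets pairwise deletion act per character.
The K2P distance over pairwise-complete sites is

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

with P and Q the transition (A<->G, C<->T) and transversion proportions.
Saturated pairs (log argument <= 0) are flagged and, at matrix level,
replaced by 1.1x the largest finite distance so clustering stays total. K2P
distances may violate the triangle inequality; nothing here assumes it.

UPGMA merges the closest pair, ties broken deterministically by lowest
(row, column) index, with size-weighted arithmetic-mean updates; node height
is half the merge distance, so the tree is ultrametric by construction.
Bootstrap resamples SNP loci (both characters of a locus together,
preserving within-genotype dependence) with replacement; support is the
percentage of replicate trees containing each original internal clade.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.exceptions import NotFittedError

from .errors import DataError
from .genotype_io import MISSING, SNPGenotypeMatrix

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
_PURINES = {"A", "G"}


@dataclass
class PseudoSequence:
    """Two sorted allele characters per SNP; missing encoded as 'NN'."""

    sample_id: str
    characters: str


def encode_sequences(matrix: SNPGenotypeMatrix) -> list[PseudoSequence]:
    """Expand genotype codes to nucleotide pseudo-sequences (length 2 x loci)."""
    per_locus = []
    for locus in matrix.panel.loci:
        het = "".join(sorted((locus.ref, locus.alt)))
        per_locus.append(
            {0: locus.ref * 2, 1: het, 2: locus.alt * 2, MISSING: "NN"}
        )
    out = []
    for i, sid in enumerate(matrix.sample_ids):
        chars = "".join(per_locus[j][int(g)] for j, g in enumerate(matrix.calls[i]))
        out.append(PseudoSequence(sid, chars))
    return out


def decode_sequences(seqs: list[PseudoSequence], matrix: SNPGenotypeMatrix) -> np.ndarray:
    """Inverse of encode_sequences against the matrix's panel (for round-trips)."""
    calls = np.full((len(seqs), matrix.n_loci), MISSING, dtype=np.int16)
    for i, s in enumerate(seqs):
        for j, locus in enumerate(matrix.panel.loci):
            pair = s.characters[2 * j : 2 * j + 2]
            if "N" in pair:
                continue
            calls[i, j] = sum(c == locus.alt for c in pair)
    return calls


def k2p_distance(seq1, seq2) -> float:
    """K2P distance between two pseudo-sequences (pairwise deletion).

    Returns ``inf`` as the saturation flag when the log argument is
    non-positive; raises DataError when no site is pairwise complete.
    """
    s1 = seq1.characters if isinstance(seq1, PseudoSequence) else seq1
    s2 = seq2.characters if isinstance(seq2, PseudoSequence) else seq2
    if len(s1) != len(s2):
        raise DataError("sequences differ in length")
    n = ts = tv = 0
    for c1, c2 in zip(s1, s2):
        if c1 == "N" or c2 == "N":
            continue
        n += 1
        if c1 == c2:
            continue
        if (c1, c2) in _TRANSITIONS:
            ts += 1
        else:
            tv += 1
    if n == 0:
        raise DataError("zero pairwise-complete sites")
    P, Q = ts / n, tv / n
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return float("inf")
    return float(-0.5 * np.log(w1 * np.sqrt(w2)))


# ---------------------------------------------------------------------------
# vectorised distance matrix
# ---------------------------------------------------------------------------

_CHAR_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def _char_matrix(matrix: SNPGenotypeMatrix, locus_idx: np.ndarray | None = None) -> np.ndarray:
    """(n_samples, 2 x loci) uint8 character codes, optionally locus-resampled."""
    refs = np.array([_CHAR_CODE[l.ref] for l in matrix.panel.loci], dtype=np.uint8)
    alts = np.array([_CHAR_CODE[l.alt] for l in matrix.panel.loci], dtype=np.uint8)
    lo = np.minimum(refs, alts)
    hi = np.maximum(refs, alts)
    if locus_idx is not None:
        refs, alts, lo, hi = refs[locus_idx], alts[locus_idx], lo[locus_idx], hi[locus_idx]
        calls = matrix.calls[:, locus_idx]
    else:
        calls = matrix.calls
    n, L = calls.shape
    chars = np.empty((n, 2 * L), dtype=np.uint8)
    c1, c2 = chars[:, 0::2], chars[:, 1::2]
    c1[:] = np.where(calls == 0, refs, np.where(calls == 1, lo, alts))
    c2[:] = np.where(calls == 0, refs, np.where(calls == 1, hi, alts))
    miss = calls == MISSING
    c1[miss] = _CHAR_CODE["N"]
    c2[miss] = _CHAR_CODE["N"]
    return chars


def _k2p_matrix(chars: np.ndarray) -> np.ndarray:
    """Pairwise K2P distances from a character-code matrix via matmuls."""
    valid = (chars != _CHAR_CODE["N"]).astype(np.float64)
    purine = np.isin(chars, (_CHAR_CODE["A"], _CHAR_CODE["G"])).astype(np.float64) * valid
    pyrim = valid - purine
    n_sites = valid @ valid.T
    transversions = purine @ pyrim.T + pyrim @ purine.T
    same_base = np.zeros_like(n_sites)
    for b in ("A", "C", "G", "T"):
        xb = (chars == _CHAR_CODE[b]).astype(np.float64)
        same_base += xb @ xb.T
    transitions = n_sites - transversions - same_base
    with np.errstate(divide="ignore", invalid="ignore"):
        P = transitions / n_sites
        Q = transversions / n_sites
        w1 = 1.0 - 2.0 * P - Q
        w2 = 1.0 - 2.0 * Q
        d = np.where((w1 > 0) & (w2 > 0), -0.5 * np.log(w1 * np.sqrt(np.maximum(w2, 1e-30))), np.inf)
    if (n_sites == 0).any():
        raise DataError("a sample pair shares zero pairwise-complete sites")
    np.fill_diagonal(d, 0.0)
    return d.astype(float)


def distance_matrix(matrix: SNPGenotypeMatrix) -> tuple[list[str], np.ndarray]:
    """Square K2P distance matrix; saturated entries replaced by 1.1x the
    largest finite distance (with a warning)."""
    d = _k2p_matrix(_char_matrix(matrix))
    if np.isinf(d).any():
        finite_max = d[np.isfinite(d)].max()
        warnings.warn("saturated K2P distances replaced by 1.1 x max finite distance")
        d[np.isinf(d)] = 1.1 * finite_max
    return list(matrix.sample_ids), d


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    name: str | None = None
    height: float = 0.0
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class SupportTree:
    """Rooted ultrametric binary tree with optional bootstrap supports."""

    root: TreeNode
    support_display_min: float | None = None

    def leaves(self) -> list[str]:
        return self.root.leaves()

    def internal_nodes(self) -> list[TreeNode]:
        out = []

        def walk(n):
            if not n.is_leaf:
                out.append(n)
                for c in n.children:
                    walk(c)

        walk(self.root)
        return out

    def clades(self) -> set[frozenset[str]]:
        """Leaf sets of all internal nodes (the root clade included)."""
        return {frozenset(n.leaves()) for n in self.internal_nodes()}

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        depths = []

        def walk(n, d):
            if n.is_leaf:
                depths.append(d)
            for c in n.children:
                walk(c, d + (n.height - c.height))

        walk(self.root, 0.0)
        return max(depths) - min(depths) <= tol

    def cophenetic(self) -> tuple[list[str], np.ndarray]:
        """Pairwise tree distances (2 x merge height) between leaves."""
        labels = sorted(self.leaves())
        idx = {l: i for i, l in enumerate(labels)}
        d = np.zeros((len(labels), len(labels)))

        def walk(n):
            if n.is_leaf:
                return [n.name]
            groups = [walk(c) for c in n.children]
            for i, ga in enumerate(groups):
                for gb in groups[i + 1:]:
                    for a in ga:
                        for b in gb:
                            d[idx[a], idx[b]] = d[idx[b], idx[a]] = 2.0 * n.height
            return [l for g in groups for l in g]

        walk(self.root)
        return labels, d

    def to_newick(self) -> str:
        def fmt(n: TreeNode, parent_height: float | None) -> str:
            if n.is_leaf:
                body = n.name
            else:
                inner = ",".join(fmt(c, n.height) for c in n.children)
                label = "" if n.support is None else str(int(round(n.support)))
                body = f"({inner}){label}"
            if parent_height is None:
                return body
            return f"{body}:{parent_height - n.height:.10g}"

        return fmt(self.root, None) + ";"


def upgma(dist: np.ndarray, labels: list[str]) -> SupportTree:
    """Agglomerate by size-weighted average linkage (supports unset).

    The closest active pair is merged each round; equal minima resolve to the
    lowest (row, column) index pair in the current cluster list, which makes
    the output deterministic.
    """
    dist = np.asarray(dist, dtype=float)
    n = len(labels)
    if dist.shape != (n, n):
        raise DataError("distance matrix shape does not match labels")
    if n == 0:
        raise DataError("empty distance matrix")
    nodes = [TreeNode(name=l) for l in labels]
    sizes = [1] * n
    d = dist.copy()
    active = list(range(n))
    while len(active) > 1:
        sub = d[np.ix_(active, active)]
        iu = np.triu_indices(len(active), k=1)
        k = int(np.argmin(sub[iu]))  # first minimum = lowest (row, column) pair
        v = float(sub[iu][k])
        ai, aj = int(iu[0][k]), int(iu[1][k])
        i, j = active[ai], active[aj]
        merged = TreeNode(height=v / 2.0, children=[nodes[i], nodes[j]])
        # size-weighted arithmetic mean to every other active cluster
        for ak in range(len(active)):
            k = active[ak]
            if k in (i, j):
                continue
            d[i, k] = d[k, i] = (sizes[i] * d[i, k] + sizes[j] * d[j, k]) / (sizes[i] + sizes[j])
        nodes[i] = merged
        sizes[i] += sizes[j]
        active.pop(aj)
    return SupportTree(nodes[active[0]])


def bootstrap_support(
    matrix: SNPGenotypeMatrix,
    n_reps: int = 500,
    seed: int | None = None,
    support_display_min: float = 75.0,
) -> SupportTree:
    """UPGMA tree with locus-bootstrap clade supports.

    Loci are resampled with replacement (both characters of a locus move
    together); support is the percentage of replicates whose tree contains
    each original internal clade. The tree remembers ``support_display_min``
    so renderers can mark only strongly supported clades.
    """
    if n_reps < 1:
        raise DataError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    labels = list(matrix.sample_ids)
    tree = upgma(_saturation_fix(_k2p_matrix(_char_matrix(matrix))), labels)
    counts: dict[frozenset, int] = {frozenset(n.leaves()): 0 for n in tree.internal_nodes()}
    for _ in range(n_reps):
        idx = rng.integers(0, matrix.n_loci, size=matrix.n_loci)
        rep = upgma(_saturation_fix(_k2p_matrix(_char_matrix(matrix, idx))), labels)
        rep_clades = rep.clades()
        for clade in counts:
            if clade in rep_clades:
                counts[clade] += 1
    for node in tree.internal_nodes():
        node.support = 100.0 * counts[frozenset(node.leaves())] / n_reps
    tree.support_display_min = support_display_min
    return tree


def _saturation_fix(d: np.ndarray) -> np.ndarray:
    if np.isinf(d).any():
        finite_max = d[np.isfinite(d)].max()
        d = np.where(np.isinf(d), 1.1 * finite_max, d)
    return d


def write_newick(tree: SupportTree, path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


class UPGMADendrogram(BaseEstimator):
    """Clustering front end: fit(X) computes the K2P distance matrix, the
    UPGMA tree and (when ``n_bootstrap`` > 0) bootstrap supports.

    Attributes: ``labels_``, ``distances_``, ``tree_``.
    """

    def __init__(self, n_bootstrap: int = 500, seed: int | None = None,
                 support_display_min: float = 75.0):
        self.n_bootstrap = n_bootstrap
        self.seed = seed
        self.support_display_min = support_display_min

    def fit(self, X: SNPGenotypeMatrix, y=None):
        self.labels_, self.distances_ = distance_matrix(X)
        if self.n_bootstrap > 0:
            self.tree_ = bootstrap_support(
                X, self.n_bootstrap, self.seed, self.support_display_min
            )
        else:
            self.tree_ = upgma(self.distances_, self.labels_)
        return self

    def _check_fitted(self):
        if not hasattr(self, "tree_"):
            raise NotFittedError("UPGMADendrogram is not fitted")
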