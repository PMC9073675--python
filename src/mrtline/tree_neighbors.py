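"""Phylogenetic dispersion of the Mrt phenotype: nearest-neighbor analysis.

A trait held at mutation–selection balance recurs by mutation and is
quickly purged, so carrier strains should sit scattered on tip branches of
a haplotype tree, each nearest to a wild-type strain.  A trait under
balancing selection persists, producing clades of carriers.  This module
maps per-strain Mrt classes onto a Newick tree and scores, for a focal
class, how many of its tips have a wild-type nearest phenotyped neighbor
(by patristic distance), with a permutation null obtained by shuffling the
class labels over the phenotyped tips.

Unphenotyped tips stay in the tree — they shape topology and branch
lengths — but are never counted as neighbors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .phenotyping import MrtClass

__all__ = [
    "PhenoTree",
    "NeighborResult",
    "PermutationTestResult",
    "nearest_phenotyped_neighbor",
    "scatter_statistic",
    "scatter_permutation_test",
]


@dataclass
class PhenoTree:
    """A tree with a (possibly partial) tip → phenotype-class map."""

    tree: dendropy.Tree
    phenotypes: dict[str, str]
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        labels = [t.label for t in self.tree.taxon_namespace]
        if len(labels) != len(set(labels)):
            raise ValueError("tip labels must be unique")
        tips = set(labels)
        self.phenotypes = {k: str(v) for k, v in self.phenotypes.items()}
        missing = set(self.phenotypes) - tips
        if missing:
            raise ValueError(f"phenotyped tips not in tree: {sorted(missing)}")
        for e in self.tree.preorder_edge_iter():
            if e.length is not None and e.length < 0:
                raise ValueError("branch lengths must be >= 0")

    @classmethod
    def from_newick(
        cls, source: str | Path, phenotypes: dict[str, str]
    ) -> "PhenoTree":
        """Build from a Newick file path or literal Newick string."""
        src = str(source)
        if src.lstrip().startswith("("):
            tree = dendropy.Tree.get(data=src, schema="newick")
        else:
            tree = dendropy.Tree.get(path=src, schema="newick")
        return cls(tree=tree, phenotypes=phenotypes)

    # -- internal ----------------------------------------------------------

    def _distances(self, metric: str) -> tuple[list[str], np.ndarray]:
        """Pairwise tip distance matrix (labels sorted lexicographically)."""
        key = ("dist", metric)
        if key not in self._cache:
            pdm = self.tree.phylogenetic_distance_matrix()
            taxa = sorted(self.tree.taxon_namespace, key=lambda t: t.label)
            labels = [t.label for t in taxa]
            n = len(taxa)
            mat = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    if metric == "patristic":
                        d = pdm.patristic_distance(taxa[i], taxa[j])
                    elif metric == "hops":
                        d = pdm.path_edge_count(taxa[i], taxa[j])
                    else:
                        raise ValueError(f"unknown metric {metric!r}")
                    mat[i, j] = mat[j, i] = d
            self._cache[key] = (labels, mat)
        return self._cache[key]

    def _neighbor_order(self, metric: str) -> tuple[list[str], np.ndarray]:
        """For each phenotyped tip, index of its nearest phenotyped neighbor.

        Ties in distance break lexicographically by neighbor label; labels
        are already sorted, so a stable argmin over label order suffices.
        """
        key = ("nn", metric)
        if key not in self._cache:
            labels, mat = self._distances(metric)
            pheno_idx = [i for i, lab in enumerate(labels) if lab in self.phenotypes]
            pheno_labels = [labels[i] for i in pheno_idx]
            sub = mat[np.ix_(pheno_idx, pheno_idx)].copy()
            np.fill_diagonal(sub, np.inf)
            nn = sub.argmin(axis=1)  # first minimum = lexicographic tie-break
            dists = sub[np.arange(len(pheno_idx)), nn]
            self._cache[key] = (pheno_labels, nn, dists)
        return self._cache[key]


@dataclass(frozen=True)
class NeighborResult:
    """Nearest phenotyped neighbor of a query tip."""

    query: str
    neighbor: str
    neighbor_class: str
    distance: float


def nearest_phenotyped_neighbor(
    ptree: PhenoTree, tip: str, metric: str = "patristic"
) -> NeighborResult:
    """Nearest phenotyped tip to ``tip`` (the query itself excluded).

    Distance is patristic (sum of branch lengths) by default, or ``"hops"``
    for topological edge counts; distance ties break lexicographically by
    neighbor label.
    """
    labels, mat = ptree._distances(metric)
    if tip not in labels:
        raise ValueError(f"tip {tip!r} not in tree")
    candidates = [lab for lab in labels if lab in ptree.phenotypes and lab != tip]
    if not candidates:
        raise ValueError("no other phenotyped tip in the tree")
    qi = labels.index(tip)
    best = min(candidates, key=lambda lab: (mat[qi, labels.index(lab)], lab))
    return NeighborResult(
        query=tip,
        neighbor=best,
        neighbor_class=ptree.phenotypes[best],
        distance=float(mat[qi, labels.index(best)]),
    )


def scatter_statistic(
    ptree: PhenoTree, focal_class: str = MrtClass.STRONG.value, metric: str = "patristic"
) -> int:
    """Number of focal-class tips whose nearest phenotyped neighbor is wild type.

    Large values indicate the focal phenotype is scattered among wild-type
    strains (the mutation–selection-balance expectation); small values
    indicate clustering of focal strains with each other.
    """
    focal_class = str(focal_class)
    pheno_labels, nn, _ = ptree._neighbor_order(metric)
    classes = np.array([ptree.phenotypes[lab] for lab in pheno_labels])
    focal = classes == focal_class
    if not focal.any():
        raise ValueError(f"no tip has the focal class {focal_class!r}")
    return int((classes[nn[focal]] == MrtClass.WILD_TYPE.value).sum())


@dataclass(frozen=True)
class PermutationTestResult:
    """Label-permutation test of the scatter statistic."""

    statistic: int
    p_value: float
    n_permutations: int
    alternative: str


def scatter_permutation_test(
    ptree: PhenoTree,
    focal_class: str = MrtClass.STRONG.value,
    n_permutations: int = 999,
    seed: int | None = None,
    alternative: str = "scattered",
    metric: str = "patristic",
) -> PermutationTestResult:
    """Permutation null for the scatter statistic.

    Class labels are shuffled over the phenotyped tips (tree and phenotyped
    set fixed).  ``alternative="scattered"`` asks whether the observed
    statistic is unusually large (focal tips next to wild type more often
    than chance); ``"clustered"`` asks whether it is unusually small.  The
    p-value uses +1 smoothing and is therefore never 0.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if alternative not in ("scattered", "clustered"):
        raise ValueError("alternative must be 'scattered' or 'clustered'")
    focal_class = str(focal_class)
    pheno_labels, nn, _ = ptree._neighbor_order(metric)
    classes = np.array([ptree.phenotypes[lab] for lab in pheno_labels])
    focal = classes == focal_class
    if not focal.any():
        raise ValueError(f"no tip has the focal class {focal_class!r}")
    wt = MrtClass.WILD_TYPE.value

    def stat(lab: np.ndarray) -> int:
        f = lab == focal_class
        return int((lab[nn[f]] == wt).sum())

    observed = stat(classes)
    rng = np.random.default_rng(seed)
    extreme = 0
    for _ in range(n_permutations):
        perm = rng.permutation(classes)
        s = stat(perm)
        if alternative == "scattered":
            extreme += s >= observed
        else:
            extreme += s <= observed
    p = (1 + extreme) / (n_permutations + 1)
    return PermutationTestResult(
        statistic=observed, p_value=p, n_permutations=n_permutations, alternative=alternative
    )
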