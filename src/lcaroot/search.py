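"""Exhaustive ML topology search for small taxon sets, with bootstrap
support and rooting utilities.

With at most eight taxa the number of unrooted binary topologies is
(2n-5)!! <= 10395, so the maximum-likelihood tree can be found by scoring
every topology instead of heuristic rearrangement — correctness over
generality at this scale. Branch support is the nonparametric bootstrap
(columns resampled with replacement, full re-search per replicate,
support = fraction of replicates whose best tree contains the
bipartition).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import Alignment
from .likelihood import TreeLikelihood, compress_patterns
from .substmodels import SubstitutionModel
from .tree import Node, Tree, TreeError

logger = logging.getLogger(__name__)

__all__ = [
    "enumerate_unrooted_topologies",
    "ml_tree_search",
    "bootstrap_support",
    "root_with_taxon",
    "SearchResult",
    "SupportedTree",
    "MAX_EXHAUSTIVE_TAXA",
]

MAX_EXHAUSTIVE_TAXA = 8


def double_factorial(n: int) -> int:
    out = 1
    while n > 1:
        out *= n
        n -= 2
    return out


def enumerate_unrooted_topologies(taxa) -> list[Tree]:
    """All (2n-5)!! unrooted binary topologies by stepwise leaf insertion.

    Capped at 8 taxa (10395 topologies): this module scores every topology
    exhaustively, which is only sensible for small taxon sets. Branch
    lengths are left unset.
    """
    taxa = list(taxa)
    n = len(taxa)
    if not 3 <= n <= MAX_EXHAUSTIVE_TAXA:
        raise TreeError(
            f"exhaustive enumeration supports 3..{MAX_EXHAUSTIVE_TAXA} taxa, "
            f"got {n}; the search is exhaustive by design and larger trees "
            f"would need a heuristic search"
        )
    base = Tree(
        Node(children=[Node(label=t) for t in taxa[:3]]), rooted=False
    )
    trees = [base]
    for label in taxa[3:]:
        nxt = []
        for tree in trees:
            for idx in range(len(tree.edges())):
                grown = tree.copy()
                edge_child = grown.edges()[idx]
                parent = edge_child.parent
                pos = parent.children.index(edge_child)
                mid = Node()
                parent.children[pos] = mid
                mid.parent = parent
                mid.add_child(edge_child)
                mid.add_child(Node(label=label))
                nxt.append(Tree(grown.root, rooted=False))
        trees = nxt
    expected = double_factorial(2 * n - 5)
    canon = {t.canonical_newick() for t in trees}
    assert len(trees) == expected and len(canon) == expected
    return trees


@dataclass
class SupportedTree:
    """A tree with per-internal-bipartition support values and its lnL."""

    tree: Tree
    log_likelihood: float
    supports: dict[frozenset, float] = field(default_factory=dict)

    def newick_with_support(self) -> str:
        tree = self.tree.copy()
        all_labels = frozenset(tree.tip_labels())
        ref = min(all_labels)
        for node in tree.postorder():
            if node.is_tip or node is tree.root:
                continue
            clade = tree.clade_labels(node)
            side = clade if ref not in clade else all_labels - clade
            if side in self.supports:
                node.label = f"{self.supports[side]:.3f}"
        return tree.to_newick(internal_labels=True)


@dataclass
class SearchResult:
    """Exhaustive-search outcome: every topology scored and ranked."""

    table: pd.DataFrame              # canonical newick, lnL, delta_lnl
    best: SupportedTree
    trees: list[Tree]                # optimized trees, ranked like the table

    @property
    def best_tree(self) -> Tree:
        return self.best.tree


def ml_tree_search(
    aln: Alignment,
    model: SubstitutionModel,
    *,
    init_length: float = 0.1,
    coarse_cycles: int = 2,
    refine_top: int = 3,
    refine_cycles: int = 50,
    refine_tol: float = 1e-6,
    fit_free: tuple[str, ...] = (),
) -> SearchResult:
    """Exhaustive ML search over all unrooted topologies of the alignment.

    Every topology's branch lengths are optimized with a fast vectorized
    coarse schedule (``TreeLikelihood.grid_sweeps``); the ``refine_top``
    best are then re-optimized to convergence with exact scalar searches.
    Ranking is by log-likelihood, ties broken by the lexicographically
    smallest canonical Newick, so the output is a strict deterministic
    ranking even on uninformative data. With ``fit_free`` nonempty, shared
    model parameters (e.g. the Gamma shape) are first fit on one reference
    topology and then held fixed across the search.
    """
    taxa = sorted(aln.taxa)
    topologies = enumerate_unrooted_topologies(taxa)
    patterns = compress_patterns(aln)
    if fit_free:
        seed_engine = TreeLikelihood(
            _with_lengths(topologies[0], init_length), aln, model, patterns=patterns
        )
        model = seed_engine.fit(free=fit_free, branch_cycles=3).model
        logger.info("shared model parameters fit before search: %s", model.name)
    scored = []
    for topo in topologies:
        engine = TreeLikelihood(
            _with_lengths(topo, init_length), aln, model, patterns=patterns
        )
        lnl = engine.grid_sweeps(cycles=coarse_cycles)
        scored.append([engine.tree.canonical_newick(), lnl, engine.tree])
    scored.sort(key=lambda row: (-row[1], row[0]))
    for row in scored[: max(1, refine_top)]:
        engine = TreeLikelihood(row[2], aln, model, patterns=patterns)
        row[1] = engine.optimize_branch_lengths(
            max_cycles=refine_cycles, tol=refine_tol
        )
        row[2] = engine.tree
    scored.sort(key=lambda row: (-row[1], row[0]))
    table = pd.DataFrame(
        {
            "topology": [r[0] for r in scored],
            "log_likelihood": [r[1] for r in scored],
        }
    )
    table["delta_lnl"] = table["log_likelihood"].iloc[0] - table["log_likelihood"]
    best = SupportedTree(tree=scored[0][2], log_likelihood=scored[0][1])
    return SearchResult(table=table, best=best, trees=[r[2] for r in scored])


def _with_lengths(tree: Tree, init_length: float) -> Tree:
    out = tree.copy()
    for node in out.edges():
        if node.length is None:
            node.length = init_length
    return out


def bootstrap_support(
    aln: Alignment,
    model: SubstitutionModel,
    best_topology: Tree,
    n_replicates: int,
    seed: int,
    **search_kw,
) -> SupportedTree:
    """Nonparametric bootstrap with full exhaustive re-search per replicate.

    Columns are resampled with replacement to the original length; support
    for each internal bipartition of ``best_topology`` is the fraction of
    replicate best trees containing it. Reproducible given the seed.
    """
    if n_replicates < 1:
        raise ValueError("need at least one bootstrap replicate")
    rng = np.random.default_rng(seed)
    search_kw.setdefault("refine_top", 1)
    target = best_topology.bipartitions()
    hits = {bp: 0 for bp in target}
    for _ in range(n_replicates):
        cols = rng.integers(0, aln.length, size=aln.length)
        replicate = aln.take_columns(cols)
        result = ml_tree_search(replicate, model, **search_kw)
        found = result.best_tree.bipartitions()
        for bp in target:
            if bp in found:
                hits[bp] += 1
    supports = {bp: hits[bp] / n_replicates for bp in target}
    engine = TreeLikelihood(_with_lengths(best_topology, 0.1), aln, model)
    lnl = engine.optimize_branch_lengths()
    return SupportedTree(tree=engine.tree, log_likelihood=lnl, supports=supports)


def root_with_taxon(tree: Tree, outgroup_label: str) -> Tree:
    """Root on the outgroup's pendant edge (midpoint); see Tree.root_with_taxon."""
    return tree.root_with_taxon(outgroup_label)
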