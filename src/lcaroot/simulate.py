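"""Sequence-evolution simulation, including canned long-branch-attraction
scenarios.

Sites evolve i.i.d. under a reversible substitution model: the root state
is drawn from the equilibrium frequencies, each site draws a rate category
(discrete Gamma, plus a rate-0 invariant category when p_inv > 0), and
states propagate along branches via the transition probabilities. The
simulator shares its model assumptions with the inference engine so that
parameter- and topology-recovery experiments are well posed.

The LBA scenario emulates a deep-split design: four ingroup lineages, one
of them fast-evolving and represented by two near-identical strain tips
(a cherry subtending the fast branch), plus one highly divergent
outgroup. Alignments are gapless; curated alignments are the intended
downstream input and indels are out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .alignment import Alignment
from .substmodels import SubstitutionModel, lg
from .tree import Node, Tree, TreeError

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationSpec",
    "LBAScenarioSpec",
    "LBAScenario",
    "simulate_alignment",
    "make_lba_scenario",
    "default_lba_tree",
    "fast_lineage_is_basal",
    "clusters_with_sister",
]


@dataclass(frozen=True)
class SimulationSpec:
    """What to simulate: a tree, a model, a length, and a seed.

    ``n_genes`` splits the sites into contiguous, near-equal gene
    partitions (for supermatrix/concatenation experiments).
    """

    tree: Tree
    model: SubstitutionModel
    n_sites: int
    n_genes: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError(f"n_sites must be >= 1, got {self.n_sites}")
        if not 1 <= self.n_genes <= self.n_sites:
            raise ValueError("n_genes must be in [1, n_sites]")
        if self.tree.n_tips == 0:
            raise ValueError("tree has no tips")
        for node in self.tree.edges():
            if node.length is None or node.length < 0:
                raise ValueError("every branch needs a non-negative length")

    def gene_lengths(self) -> list[int]:
        base, extra = divmod(self.n_sites, self.n_genes)
        return [base + (1 if i < extra else 0) for i in range(self.n_genes)]


def _propagate(states: np.ndarray, P: np.ndarray, rng) -> np.ndarray:
    """Draw child states from rows of P selected by the parent states."""
    cum = np.cumsum(P[states], axis=1)
    u = rng.random(len(states))
    return (u[:, None] > cum).sum(axis=1).astype(np.int64)


def simulate_alignment(spec: SimulationSpec) -> tuple[Alignment, str]:
    """Simulate one alignment; returns it with the true root sequence.

    Output is a pure function of the spec (including the seed). With all
    branch lengths zero every tip equals the root sequence; with p_inv = 1
    every column is constant.
    """
    logger.info("simulate_alignment: seed=%d, n_sites=%d", spec.seed, spec.n_sites)
    rng = np.random.default_rng(spec.seed)
    model = spec.model
    k = model.alphabet.size
    pi = model.frequencies
    cats = model.rate_categories()
    eig = model.eigensystem()
    n = spec.n_sites

    category = rng.choice(cats.k, size=n, p=cats.weights)
    root_states = rng.choice(k, size=n, p=pi)

    # per-node state arrays, filled preorder
    states: dict[int, np.ndarray] = {id(spec.tree.root): root_states}
    tip_seqs: dict[str, np.ndarray] = {}
    for node in spec.tree.preorder():
        if node is spec.tree.root:
            if node.is_tip:
                tip_seqs[node.label] = root_states
            continue
        parent_states = states[id(node.parent)]
        out = np.empty(n, dtype=np.int64)
        for c in range(cats.k):
            mask = category == c
            if not mask.any():
                continue
            rate = cats.rates[c]
            if rate == 0.0 or node.length == 0.0:
                out[mask] = parent_states[mask]
            else:
                P = eig.probability(node.length, rate)
                out[mask] = _propagate(parent_states[mask], P, rng)
        states[id(node)] = out
        if node.is_tip:
            tip_seqs[node.label] = out

    decode = np.array(list(model.alphabet.states))
    seqs = {t: "".join(decode[s]) for t, s in tip_seqs.items()}
    aln = Alignment.from_mapping(seqs, model.alphabet)
    root_seq = "".join(decode[root_states])
    return aln, root_seq


# -- LBA scenario ------------------------------------------------------------


def default_lba_tree() -> Tree:
    """Default rooted ingroup topology over the 4 lineages.

    ``basal`` branches first, then ``middle``, with the fast lineage sister
    to ``sister``: (basal,(middle,(fast,sister))). The fast lineage is the
    one later expanded into the strain cherry.
    """
    return Tree.from_newick("(basal,(middle,(fast,sister)));", rooted=True)


@dataclass(frozen=True)
class LBAScenarioSpec:
    """Parameters of the canned long-branch-attraction scenario.

    Lengths are in expected substitutions per site. Invariants:
    ``long_branch > short_branch`` (the fast lineage is genuinely fast),
    ``outgroup_distance > long_branch`` (the outgroup is the most divergent
    lineage), and ``strain_divergence < short_branch`` (the strain pair is
    near-identical).
    """

    ingroup_topology: Tree = field(default_factory=default_lba_tree)
    fast_lineage: str = "fast"
    short_branch: float = 0.1
    long_branch: float = 1.0
    strain_divergence: float = 0.01
    outgroup_distance: float = 2.0
    #: length of the *internal* ingroup edges. The scenario emulates a deep,
    #: rapid radiation: successive splits carry little signal, so internal
    #: edges are an order of magnitude shorter than the pendant edges.
    internal_branch: float = 0.01
    model: SubstitutionModel = field(default_factory=lambda: lg(gamma_shape=1.0))
    n_sites: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.long_branch > self.short_branch:
            raise ValueError(
                f"long_branch ({self.long_branch}) must exceed short_branch "
                f"({self.short_branch})"
            )
        if not self.outgroup_distance > self.long_branch:
            raise ValueError(
                f"outgroup_distance ({self.outgroup_distance}) must exceed "
                f"long_branch ({self.long_branch})"
            )
        if not 0.0 <= self.strain_divergence < self.short_branch:
            raise ValueError(
                f"strain_divergence ({self.strain_divergence}) must be small "
                f"relative to short_branch ({self.short_branch})"
            )
        if self.internal_branch < 0:
            raise ValueError("internal_branch must be non-negative")
        if not self.ingroup_topology.rooted:
            raise ValueError("ingroup_topology must be rooted")
        labels = set(self.ingroup_topology.tip_labels())
        if len(labels) != 4 or self.fast_lineage not in labels:
            raise ValueError(
                "ingroup_topology needs exactly 4 lineages including "
                f"{self.fast_lineage!r}; got {sorted(labels)}"
            )


@dataclass(frozen=True)
class LBAScenario:
    """A simulated LBA replicate with its generating truth."""

    alignment: Alignment          # 6 tips: ingroup (5, incl. strain pair) + outgroup
    ingroup_alignment: Alignment  # the same without the outgroup
    true_tree: Tree               # rooted generating tree, 6 tips
    true_ingroup_tree: Tree       # rooted generating ingroup tree, 5 tips
    root_sequence: str
    outgroup: str
    strain_tips: tuple[str, str]
    sister: str | None
    spec: LBAScenarioSpec


def make_lba_scenario(spec: LBAScenarioSpec) -> LBAScenario:
    """Simulate one replicate of the long-branch-attraction design.

    The generating tree is the rooted ingroup topology with pendant edges
    set to ``short_branch`` (``long_branch`` for the fast lineage),
    internal edges set to ``internal_branch``, the fast tip replaced by a
    two-strain cherry (pendant edges ``strain_divergence/2``), and the
    outgroup attached at the ingroup root at ``outgroup_distance``.
    """
    base = _strainify(spec.ingroup_topology, spec)
    strain_a, strain_b = f"{spec.fast_lineage}_A", f"{spec.fast_lineage}_B"

    # generating tree: outgroup diverges at the ingroup LCA
    sim_root = Node(children=list(base.root.children))
    sim_root.add_child(Node(label="outgroup", length=spec.outgroup_distance))
    sim_tree = Tree(sim_root, rooted=False)  # basal trichotomy at the LCA

    aln, root_seq = simulate_alignment(
        SimulationSpec(tree=sim_tree, model=spec.model, n_sites=spec.n_sites, seed=spec.seed)
    )

    # recorded truth: rooted trees for scoring
    true_ingroup = _strainify(spec.ingroup_topology, spec)
    true_root = Node(
        children=[
            Node(label="outgroup", length=spec.outgroup_distance),
            _strainify(spec.ingroup_topology, spec).root,
        ]
    )
    true_root.children[1].length = 0.0
    true_tree = Tree(true_root, rooted=True)

    sister = _true_sister(spec)
    return LBAScenario(
        alignment=aln,
        ingroup_alignment=aln.drop_taxa(["outgroup"]),
        true_tree=true_tree,
        true_ingroup_tree=true_ingroup,
        root_sequence=root_seq,
        outgroup="outgroup",
        strain_tips=(strain_a, strain_b),
        sister=sister,
        spec=spec,
    )


def _strainify(topology: Tree, spec: LBAScenarioSpec) -> Tree:
    """Apply scenario branch lengths and expand the fast tip into a cherry."""
    tree = topology.copy()
    for node in tree.postorder():
        if node is not tree.root:
            node.length = spec.short_branch if node.is_tip else spec.internal_branch
    fast = tree.find_tip(spec.fast_lineage)
    fast.length = spec.long_branch
    fast.label = None
    for lab in (f"{spec.fast_lineage}_A", f"{spec.fast_lineage}_B"):
        fast.add_child(Node(label=lab, length=spec.strain_divergence / 2.0))
    return tree


def _true_sister(spec: LBAScenarioSpec) -> str | None:
    """The lineage forming a cherry with the fast lineage, if any."""
    fast = spec.ingroup_topology.find_tip(spec.fast_lineage)
    siblings = [c for c in fast.parent.children if c is not fast]
    if len(siblings) == 1 and siblings[0].is_tip:
        return siblings[0].label
    return None


# -- scenario scoring --------------------------------------------------------


def fast_lineage_is_basal(rooted_ingroup_tree: Tree, strain_tips) -> bool:
    """True iff the fast lineage is the basalmost branch of the rooted tree.

    The fast lineage is basal when one child of the root is exactly the
    fast clade (both strain tips, or the single remaining strain tip).
    """
    wanted = frozenset(t for t in strain_tips if t in rooted_ingroup_tree.tip_labels())
    if not rooted_ingroup_tree.rooted:
        raise TreeError("scoring requires a rooted ingroup tree")
    for child in rooted_ingroup_tree.root.children:
        if rooted_ingroup_tree.clade_labels(child) == wanted:
            return True
    return False


def clusters_with_sister(tree: Tree, strain_tips, sister: str) -> bool:
    """True iff {fast strain tip(s)} + sister form a clade/bipartition."""
    present = [t for t in strain_tips if t in tree.tip_labels()]
    group = frozenset(present + [sister])
    n = tree.n_tips
    if len(group) == n - 1:
        # complement is a single tip; always a (trivial) split
        return True
    if tree.rooted:
        for node in tree.postorder():
            if tree.clade_labels(node) == group:
                return True
        # a rooted tree also shows the split if the complement is a clade
        comp = frozenset(tree.tip_labels()) - group
        return any(tree.clade_labels(nd) == comp for nd in tree.postorder())
    all_labels = frozenset(tree.tip_labels())
    ref = min(all_labels)
    side = group if ref not in group else all_labels - group
    return side in tree.bipartitions()
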