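"""Rooting deep splits with a reconstructed ancestral (LCA) sequence.

Distant outgroups can attract the fastest-evolving ingroup branch and so
distort where the root lands (long-branch attraction). The method
implemented here replaces the extant outgroup with the ingroup's own last
common ancestor: a marginal maximum-likelihood ancestral sequence is
reconstructed at the central node of a *star* tree over the ingroup — a
topology that presumes no ingroup relationships, so the reconstruction is
unbiased with respect to the very hypothesis being tested — and the tree
is then re-inferred with the reconstructed sequence standing in for the
outgroup and rooted on its branch.

The full diagnostic protocol additionally re-analyzes the data with
singleton positions pruned and with taxa deleted, which homogenizes
branch lengths and shows whether a basal placement of the fast lineage is
an attraction artifact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .alignment import (
    Alignment,
    concatenate,
    drop_taxa,
    prune_singletons,
)
from .likelihood import TreeLikelihood
from .search import SearchResult, SupportedTree, bootstrap_support, ml_tree_search
from .substmodels import SubstitutionModel, parse_model
from .tree import Tree, TreeError, star_tree

logger = logging.getLogger(__name__)

__all__ = [
    "AncestralProfile",
    "build_star_tree",
    "build_lineage_star",
    "marginal_asr",
    "lca_root",
    "LcaRootResult",
    "run_lba_protocol",
    "AnalysisResult",
    "ProtocolReport",
]


def build_star_tree(taxa, branch_length: float = 0.1) -> Tree:
    """Star intree over the taxa: one internal node, initial lengths 0.1."""
    return star_tree(taxa, branch_length=branch_length)


def build_lineage_star(
    taxa,
    strain_pair: tuple[str, str] | None = None,
    branch_length: float = 0.1,
) -> Tree:
    """Star intree over *lineages*: a star whose children are tips, except
    that a near-identical strain pair is kept resolved as a cherry.

    Keeping the pair resolved lets its two sequences speak through one
    stem instead of casting two independent votes, which would otherwise
    pull the central node — the ancestor being reconstructed — toward the
    pair. The intree still presumes nothing about lineage relationships.
    """
    from .tree import Node

    if strain_pair is None:
        return star_tree(taxa, branch_length=branch_length)
    a, b = strain_pair
    rest = [t for t in taxa if t not in {a, b}]
    if len(rest) != len(taxa) - 2:
        raise TreeError(f"strain pair {strain_pair} not found among taxa")
    root = Node()
    for label in rest:
        root.add_child(Node(label=label, length=branch_length))
    cherry = Node(length=branch_length)
    cherry.add_child(Node(label=a, length=branch_length))
    cherry.add_child(Node(label=b, length=branch_length))
    root.add_child(cherry)
    return Tree(root, rooted=False)


def _is_star_like(tree: Tree) -> bool:
    """True for a star over lineages: every grandchild of the basal node
    is a tip."""
    if tree.rooted or len(tree.root.children) < 3:
        return False
    return all(
        all(gc.is_tip for gc in child.children) for child in tree.root.children
    )


@dataclass
class AncestralProfile:
    """Per-site posterior state distributions at the star tree's center.

    ``posteriors[i]`` sums to 1; ``map_sequence`` takes the
    maximum-a-posteriori state per site, ties broken by alphabet order
    (tied sites listed in ``tied_sites``).
    """

    posteriors: np.ndarray          # (n_sites, n_states)
    map_sequence: str
    map_posterior: np.ndarray       # (n_sites,)
    tied_sites: tuple[int, ...]
    star_tree: Tree
    model: SubstitutionModel

    def write_fasta(self, handle, label: str = "LCA") -> None:
        handle.write(f">{label}\n")
        seq = self.map_sequence
        for i in range(0, len(seq), 60):
            handle.write(seq[i : i + 60] + "\n")

    def write_posterior_tsv(self, handle) -> None:
        states = self.model.alphabet.states
        handle.write("site\tmap_state\tmap_posterior\t" + "\t".join(states) + "\n")
        for i, row in enumerate(self.posteriors):
            cells = "\t".join(f"{p:.6g}" for p in row)
            handle.write(
                f"{i + 1}\t{self.map_sequence[i]}\t{self.map_posterior[i]:.6g}\t{cells}\n"
            )


def marginal_asr(
    star: Tree,
    aln: Alignment,
    model: SubstitutionModel,
    optimize: bool = True,
    fit_free: tuple[str, ...] = (),
) -> AncestralProfile:
    """Marginal ancestral reconstruction at the center of a star tree.

    Branch lengths (and, with ``fit_free``, model parameters) are
    ML-optimized on the star tree first. Per site, the posterior over the
    central state s is proportional to

        sum_c w_c(site) * pi_s * prod_tips P(s -> tip state; t_tip * r_c),

    i.e. the rate categories (including the invariant one) are mixed by
    their posterior weights. The intree may also be *star-like*: a star
    over lineages in which a strain pair stays resolved as a cherry (see
    :func:`build_lineage_star`); the posterior is always computed at the
    basal node.
    """
    if not (star.is_star or _is_star_like(star)):
        raise TreeError(
            "marginal_asr requires a star (or star-over-lineages) intree"
        )
    engine = TreeLikelihood(star, aln, model)
    if fit_free:
        engine.fit(free=fit_free)
    elif optimize:
        engine.optimize_branch_lengths()
    partials, plog, site_map = engine.root_partials()
    pi = engine.eig.pi
    # log joint over (category, pattern, state)
    with np.errstate(divide="ignore"):
        A = engine.log_cat_weights[:, None, None] + np.log(
            partials * pi[None, None, :]
        )
        if plog is not None:
            A = A + plog[:, :, None]
    shift = A.max(axis=(0, 2), keepdims=True)
    joint = np.exp(A - shift).sum(axis=0)  # (P, k)
    norm = joint.sum(axis=1, keepdims=True)
    post_patterns = joint / norm
    posteriors = post_patterns[site_map]
    map_idx = posteriors.argmax(axis=1)  # first max = alphabet order
    near = np.isclose(posteriors, posteriors.max(axis=1, keepdims=True), rtol=0, atol=1e-12)
    tied = tuple(int(i) for i in np.nonzero(near.sum(axis=1) > 1)[0])
    if tied:
        logger.info("%d site(s) had tied MAP states; alphabet order used", len(tied))
    states = np.array(list(model.alphabet.states))
    return AncestralProfile(
        posteriors=posteriors,
        map_sequence="".join(states[map_idx]),
        map_posterior=posteriors[np.arange(len(map_idx)), map_idx],
        tied_sites=tied,
        star_tree=engine.tree,
        model=engine.model,
    )


@dataclass
class LcaRootResult:
    """Outcome of LCA rooting: the rooted ingroup tree and its provenance."""

    rooted_tree: Tree               # rooted on the LCA tip's edge
    supported: SupportedTree        # best tree over ingroup + LCA
    profile: AncestralProfile
    search: SearchResult
    lca_label: str

    @property
    def rooted_ingroup_tree(self) -> Tree:
        """The rooted ingroup tree with the LCA tip removed (for display)."""
        return self.rooted_tree.without_tip(self.lca_label)

    @property
    def lca_branch_length(self) -> float:
        tip = self.rooted_tree.find_tip(self.lca_label)
        other = [c for c in self.rooted_tree.root.children if c is not tip][0]
        return (tip.length or 0.0) + (other.length or 0.0)


def lca_root(
    aln_with_outgroup: Alignment,
    outgroup_label: str,
    model: SubstitutionModel,
    *,
    strain_pair: tuple[str, str] | None = None,
    lca_label: str = "LCA",
    bootstrap_replicates: int = 0,
    seed: int = 0,
    asr_fit_free: tuple[str, ...] = (),
    **search_kw,
) -> LcaRootResult:
    """Root the ingroup via a reconstructed LCA sequence.

    Pipeline: drop the outgroup; ML-optimize a star intree over the
    ingroup lineages (the strain pair, if given, stays resolved as a
    cherry) and reconstruct the marginal LCA sequence at its center; build
    a new alignment of ingroup + LCA (MAP sequence); exhaustive ML search
    (plus bootstrap if requested); root on the LCA tip's pendant edge.
    """
    if outgroup_label not in aln_with_outgroup.taxa:
        raise TreeError(f"outgroup {outgroup_label!r} not in alignment")
    ingroup_aln = drop_taxa(aln_with_outgroup, [outgroup_label])
    if ingroup_aln.n_taxa < 4:
        raise TreeError(
            "LCA rooting needs an ingroup of at least 4 tips for a "
            f"nontrivial rooted topology; got {ingroup_aln.n_taxa}"
        )
    if lca_label in ingroup_aln.taxa:
        raise TreeError(f"label {lca_label!r} collides with an ingroup taxon")
    star = build_lineage_star(ingroup_aln.taxa, strain_pair)
    profile = marginal_asr(star, ingroup_aln, model, fit_free=asr_fit_free)
    lca_aln = Alignment(
        taxa=ingroup_aln.taxa + (lca_label,),
        sequences=ingroup_aln.sequences + (profile.map_sequence,),
        alphabet=ingroup_aln.alphabet,
    )
    search = ml_tree_search(lca_aln, profile.model, **search_kw)
    if bootstrap_replicates > 0:
        supported = bootstrap_support(
            lca_aln, profile.model, search.best_tree, bootstrap_replicates, seed,
            **{k: v for k, v in search_kw.items() if k != "fit_free"},
        )
    else:
        supported = search.best
    rooted = supported.tree.root_with_taxon(lca_label)
    return LcaRootResult(
        rooted_tree=rooted,
        supported=supported,
        profile=profile,
        search=search,
        lca_label=lca_label,
    )


# -- the four-analysis diagnostic protocol -----------------------------------


@dataclass
class AnalysisResult:
    name: str
    dataset: str
    alignment_length: int
    n_taxa: int
    tree: Tree
    log_likelihood: float
    supports: dict | None = None
    notes: tuple[str, ...] = ()

    def manifest(self) -> dict:
        return {
            "analysis": self.name,
            "dataset": self.dataset,
            "alignment_length": self.alignment_length,
            "n_taxa": self.n_taxa,
            "tree": self.tree.to_newick(),
            "log_likelihood": self.log_likelihood,
            "notes": list(self.notes),
        }


@dataclass
class ProtocolReport:
    """Results of the four diagnostic analyses.

    A: full supermatrix, outgroup-rooted tree;
    B: singleton-pruned, outgroup removed, unrooted search;
    C: as B with one strain tip deleted in turn (both variants),
       singletons re-pruned so states private to the remaining strain go;
    D: LCA-rooted tree on the unpruned ingroup alignment.
    """

    analyses: dict[str, AnalysisResult]
    changed_bipartitions: dict = field(default_factory=dict)
    lca: LcaRootResult | None = None

    def manifest(self) -> dict:
        return {
            "analyses": {k: v.manifest() for k, v in self.analyses.items()},
            "changed_clades": {
                k: sorted(sorted(c) for c in v)
                for k, v in self.changed_bipartitions.items()
            },
        }


def run_lba_protocol(
    data,
    outgroup: str,
    strain_pair: tuple[str, str] | None = None,
    model: SubstitutionModel | str = "LG+G4+F",
    *,
    bootstrap_replicates: int = 0,
    seed: int = 0,
    **search_kw,
) -> ProtocolReport:
    """Run the four-analysis long-branch-attraction diagnostic protocol.

    ``data`` is a supermatrix alignment or a list of per-gene alignments
    (concatenated first). ``model`` may be a spec string, parsed per
    analysis dataset so that +F frequencies stay empirical for each edited
    alignment. The protocol takes the substitution model as given — as
    after an a-priori model selection — but ``search_kw`` may request
    parameter fitting via ``fit_free``.
    """
    if isinstance(data, Alignment):
        supermatrix = data
    else:
        supermatrix, _ = concatenate(list(data))
    for label in [outgroup, *(strain_pair or ())]:
        if label not in supermatrix.taxa:
            raise TreeError(f"taxon {label!r} not in the supermatrix")

    def model_for(aln: Alignment) -> SubstitutionModel:
        return parse_model(model, aln) if isinstance(model, str) else model

    analyses: dict[str, AnalysisResult] = {}

    # A: full alignment, outgroup rooting
    result_a = ml_tree_search(supermatrix, model_for(supermatrix), **search_kw)
    tree_a = result_a.best_tree.root_with_taxon(outgroup)
    supports_a = None
    if bootstrap_replicates:
        supports_a = bootstrap_support(
            supermatrix, model_for(supermatrix), result_a.best_tree,
            bootstrap_replicates, seed, **search_kw,
        ).supports
    analyses["full_outgroup"] = AnalysisResult(
        name="A", dataset="full+outgroup", alignment_length=supermatrix.length,
        n_taxa=supermatrix.n_taxa, tree=tree_a,
        log_likelihood=result_a.best.log_likelihood, supports=supports_a,
    )

    # B: prune singletons, drop outgroup, unrooted search
    pruned, _, records = prune_singletons(supermatrix)
    notes_b = () if records else ("no singletons removed",)
    aln_b = drop_taxa(pruned, [outgroup])
    result_b = ml_tree_search(aln_b, model_for(aln_b), **search_kw)
    analyses["nosing_5otu"] = AnalysisResult(
        name="B", dataset="noSing-ingroup", alignment_length=aln_b.length,
        n_taxa=aln_b.n_taxa, tree=result_b.best_tree,
        log_likelihood=result_b.best.log_likelihood, notes=notes_b,
    )

    # C: additionally drop each strain in turn; re-prune so states that
    # were shared by the strain pair become recognizable singletons
    if strain_pair is not None:
        for kept, dropped in (strain_pair, strain_pair[::-1]):
            reduced = drop_taxa(aln_b, [dropped])
            aln_c, _, _ = prune_singletons(reduced)
            result_c = ml_tree_search(aln_c, model_for(aln_c), **search_kw)
            key = f"nosing_4otu_{kept}"
            analyses[key] = AnalysisResult(
                name="C", dataset=f"noSing-kept-{kept}",
                alignment_length=aln_c.length, n_taxa=aln_c.n_taxa,
                tree=result_c.best_tree,
                log_likelihood=result_c.best.log_likelihood,
            )

    # D: LCA rooting on the unpruned ingroup
    ingroup_full = drop_taxa(supermatrix, [outgroup])
    lca = lca_root(
        supermatrix, outgroup, model_for(ingroup_full),
        strain_pair=strain_pair,
        bootstrap_replicates=bootstrap_replicates, seed=seed, **search_kw,
    )
    analyses["lca_rooted"] = AnalysisResult(
        name="D", dataset="ingroup+LCA", alignment_length=ingroup_full.length,
        n_taxa=ingroup_full.n_taxa + 1, tree=lca.rooted_tree,
        log_likelihood=lca.supported.log_likelihood,
        supports=lca.supported.supports or None,
    )

    # which rooted ingroup clades changed between A and D
    ingroup_a = tree_a.without_tip(outgroup)
    ingroup_d = lca.rooted_ingroup_tree
    changed = {
        "only_outgroup_rooted": ingroup_a.clades() - ingroup_d.clades(),
        "only_lca_rooted": ingroup_d.clades() - ingroup_a.clades(),
    }

    len_a = analyses["full_outgroup"].alignment_length
    len_b = analyses["nosing_5otu"].alignment_length
    lens_c = [
        a.alignment_length for k, a in analyses.items() if k.startswith("nosing_4otu")
    ]
    if not (len_a >= len_b and all(len_b >= lc for lc in lens_c)):
        raise AssertionError(
            f"pruning can only shorten alignments: A={len_a}, B={len_b}, C={lens_c}"
        )
    return ProtocolReport(analyses=analyses, changed_bipartitions=changed, lca=lca)
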