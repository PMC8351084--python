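"""Felsenstein-pruning likelihood, branch/parameter optimization, AIC.

The engine computes the log-likelihood of an alignment on a tree under a
reversible substitution model with discrete rate categories (Gamma and/or
invariant). Columns are compressed to unique site patterns; gap/missing
symbols contribute flat partial likelihoods; underflow is handled with
per-node log-scaling factors, enabled automatically for trees large
enough to need them (small trees cannot underflow double precision, and
an impossible site then correctly yields a -inf log-likelihood).

Branch lengths are optimized coordinate-wise with bounded scalar
searches. For speed, the per-edge objective is expressed in the eigenbasis
of the rate matrix: with directional partial likelihoods F (outside the
edge, frequency-weighted) and G (inside), the per-site likelihood along an
edge of length t is

    L(t) = sum_j exp(lambda_j * r * t) * (F~ . G~)_j,

one small matrix product per evaluation, so a full scalar search per edge
costs little more than one likelihood pass per sweep. Exhaustive topology
search additionally uses a vectorized variant that scores a whole grid of
candidate lengths per edge in one pass (see ``grid_sweeps``).

Invariant sites enter as a rate-0 category: P(0) = I, which reproduces
the usual shortcut (a site contributes p_inv * pi_state only if
compatible with being constant) without special-casing gaps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar

from .alignment import Alignment
from .substmodels import SubstitutionModel, gtr
from .tree import Tree

logger = logging.getLogger(__name__)

__all__ = [
    "LikelihoodResult",
    "TreeLikelihood",
    "log_likelihood",
    "optimize_branch_lengths",
    "fit_model_parameters",
    "aic_select",
    "compress_patterns",
    "BRANCH_BOUNDS",
]

#: bounds for optimized branch lengths (expected substitutions/site)
BRANCH_BOUNDS = (1e-8, 20.0)
_NEG_INF = float("-inf")
#: trees with more tips than this get per-node log-scaling
_SCALING_TIP_THRESHOLD = 10

#: log-spaced candidate lengths for the vectorized coarse optimizer
_COARSE_GRID = np.concatenate(
    [[BRANCH_BOUNDS[0]], np.geomspace(1e-3, 15.0, 22), [BRANCH_BOUNDS[1]]]
)


class LikelihoodError(ValueError):
    pass


@dataclass
class LikelihoodResult:
    """A likelihood evaluation with its fitted context."""

    log_likelihood: float
    per_site: np.ndarray
    tree: Tree
    model: SubstitutionModel
    n_free_parameters: int
    converged: bool = True
    message: str = "ok"


def _logsumexp_rows(a: np.ndarray) -> np.ndarray:
    """logsumexp over axis 0, tolerating -inf columns."""
    m = a.max(axis=0)
    finite = np.isfinite(m)
    out = np.full(a.shape[1:], _NEG_INF)
    if finite.any():
        shifted = np.exp(a[:, finite] - m[finite])
        out[finite] = m[finite] + np.log(shifted.sum(axis=0))
    return out


def compress_patterns(aln: Alignment):
    """Unique site patterns, their counts, and the site -> pattern map.

    Compute once per alignment and pass to several :class:`TreeLikelihood`
    instances (e.g. one per candidate topology) to avoid recompression.
    """
    matrix = aln.matrix().astype(np.int64)
    patterns, inverse, counts = np.unique(
        matrix, axis=1, return_inverse=True, return_counts=True
    )
    return patterns, counts.astype(float), inverse.ravel()


class TreeLikelihood:
    """Pruning likelihood of one alignment on one tree under one model.

    The engine works on its own copy of the tree; optimized branch lengths
    are written back to that copy (exposed as :attr:`tree`). Traversal
    order, and hence every tie-break, is the deterministic postorder of
    the input tree.
    """

    def __init__(
        self,
        tree: Tree,
        aln: Alignment,
        model: SubstitutionModel,
        patterns=None,
    ):
        if model.alphabet.name != aln.alphabet.name:
            raise LikelihoodError(
                f"model alphabet {model.alphabet.name!r} != alignment "
                f"alphabet {aln.alphabet.name!r}"
            )
        tip_labels = set(tree.tip_labels())
        if tip_labels != set(aln.taxa):
            raise LikelihoodError(
                f"tree/alignment label mismatch: only in tree "
                f"{sorted(tip_labels - set(aln.taxa))}, only in alignment "
                f"{sorted(set(aln.taxa) - tip_labels)}"
            )
        self.tree = tree.copy()
        self.aln = aln
        self._nodes = list(self.tree.postorder())
        index = {id(n): i for i, n in enumerate(self._nodes)}
        self._children = [[index[id(c)] for c in n.children] for n in self._nodes]
        self._root = len(self._nodes) - 1
        self.lengths = np.array(
            [
                (n.length if n.length is not None else 0.1)
                if n is not self.tree.root
                else 0.0
                for n in self._nodes
            ]
        )
        if (self.lengths < 0).any():
            raise LikelihoodError("negative branch length")

        if patterns is None:
            patterns = compress_patterns(aln)
        pattern_matrix, self.pattern_weights, self._site_to_pattern = patterns
        row_of = {t: i for i, t in enumerate(aln.taxa)}
        k = model.alphabet.size
        # tip states per node, with "missing" mapped to extra state k
        self._tip_states = [None] * len(self._nodes)
        for i, n in enumerate(self._nodes):
            if n.is_tip:
                states = pattern_matrix[row_of[n.label]].copy()
                states[states < 0] = k
                self._tip_states[i] = states
        self.n_patterns = pattern_matrix.shape[1]
        self.k = k
        self._scale = self.tree.n_tips > _SCALING_TIP_THRESHOLD
        self._set_model(model)

    # -- model plumbing ----------------------------------------------------

    def _set_model(self, model: SubstitutionModel) -> None:
        self.model = model
        self.eig = model.eigensystem()
        cats = model.rate_categories()
        self.rates = cats.rates
        self.cat_weights = cats.weights
        self.log_cat_weights = np.log(np.maximum(cats.weights, 1e-300))
        self.C = cats.k
        # eigen operators for the per-edge objective
        self._sqrtpiV = self.eig.sqrt_pi[:, None] * self.eig.V
        self._missing_row = (self.eig.sqrt_pi @ self.eig.V)[None, :]
        self._cache_valid = False

    def _pmats(self, t: float) -> np.ndarray:
        return self.eig.probabilities(t, self.rates)

    # -- downward (post-order) pass ----------------------------------------

    def _down_pass(self) -> None:
        C, P, k = self.C, self.n_patterns, self.k
        n = len(self._nodes)
        self._partial = [None] * n
        self._plog = [None] * n  # per-(category, pattern) log-scales, or None
        self._contrib = [None] * n  # child's contribution, seen from its parent
        for i, node in enumerate(self._nodes):
            if node.is_tip and i != self._root:
                continue
            M = None
            slog = None
            for c in self._children[i]:
                Pc = self._pmats(self.lengths[c])  # (C, k, k)
                if self._tip_states[c] is not None:
                    Pext = np.concatenate([Pc, np.ones((C, k, 1))], axis=2)
                    contrib = Pext[:, :, self._tip_states[c]].transpose(0, 2, 1)
                else:
                    contrib = np.matmul(self._partial[c], Pc.transpose(0, 2, 1))
                    if self._plog[c] is not None:
                        slog = (slog if slog is not None else 0.0) + self._plog[c]
                self._contrib[c] = contrib
                M = contrib.copy() if M is None else M.__imul__(contrib)
            if self._scale:
                scale = M.max(axis=2)
                safe = np.where(scale > 0, scale, 1.0)
                M /= safe[..., None]
                with np.errstate(divide="ignore"):
                    add = np.where(scale > 0, np.log(safe), _NEG_INF)
                slog = add if slog is None else slog + add
            self._partial[i] = M
            self._plog[i] = slog
        self._cache_valid = True

    def _pattern_log_likelihoods(self) -> np.ndarray:
        if not self._cache_valid:
            self._down_pass()
        root_partial = self._partial[self._root]
        if root_partial is None:  # single-tip tree
            raise LikelihoodError("tree must have at least one internal node")
        L = root_partial @ self.eig.pi  # (C, P)
        with np.errstate(divide="ignore"):
            A = self.log_cat_weights[:, None] + np.log(L)
        if self._plog[self._root] is not None:
            A += self._plog[self._root]
        return _logsumexp_rows(A)

    def log_likelihood(self) -> float:
        pat = self._pattern_log_likelihoods()
        if not np.isfinite(pat).all():
            logger.warning(
                "alignment has impossible columns under this tree/model; "
                "log-likelihood is -inf"
            )
        return float((self.pattern_weights * pat).sum())

    def site_log_likelihoods(self) -> np.ndarray:
        return self._pattern_log_likelihoods()[self._site_to_pattern]

    def site_category_posteriors(self) -> np.ndarray:
        """(n_sites, C) posterior weight of each rate category per site."""
        if not self._cache_valid:
            self._down_pass()
        L = self._partial[self._root] @ self.eig.pi
        with np.errstate(divide="ignore"):
            A = self.log_cat_weights[:, None] + np.log(L)
        if self._plog[self._root] is not None:
            A += self._plog[self._root]
        A = A - _logsumexp_rows(A)[None, :]
        return np.exp(A).T[self._site_to_pattern]

    # -- upward (pre-order) pass and per-edge objective ----------------------

    def _up_pass(self) -> None:
        """Outside partials: for each edge, the likelihood of everything
        outside the child's subtree as a function of the state at the
        parent end (``_excl``); transported through the edge for internal
        children (``_out``)."""
        C, P, k = self.C, self.n_patterns, self.k
        n = len(self._nodes)
        self._out = [None] * n
        self._outlog = [None] * n
        self._excl = [None] * n
        self._excllog = [None] * n
        self._out[self._root] = np.ones((C, P, k))
        self._outlog[self._root] = None
        for i in reversed(range(n)):  # preorder = reversed postorder
            node = self._nodes[i]
            if node.is_tip and i != self._root:
                continue
            cs = self._children[i]
            base = self._out[i]
            baselog = self._outlog[i]
            # exclude-one products via prefix/suffix accumulation
            prefix = [base]
            for c in cs[:-1]:
                prefix.append(prefix[-1] * self._contrib[c])
            suffix = None
            for j in reversed(range(len(cs))):
                c = cs[j]
                self._excl[c] = prefix[j] if suffix is None else prefix[j] * suffix
                self._excllog[c] = baselog
                suffix = (
                    self._contrib[c]
                    if suffix is None
                    else suffix * self._contrib[c]
                )
            if self._scale:
                # recompute exclusion logs exactly (rare path: scaling on)
                for j, c in enumerate(cs):
                    olog = baselog
                    for s in cs:
                        if s != c and self._plog[s] is not None:
                            olog = (olog if olog is not None else 0.0) + self._plog[s]
                    O = self._excl[c]
                    scale = O.max(axis=2)
                    safe = np.where(scale > 0, scale, 1.0)
                    self._excl[c] = O / safe[..., None]
                    with np.errstate(divide="ignore"):
                        add = np.where(scale > 0, np.log(safe), _NEG_INF)
                    olog = add if olog is None else olog + add
                    self._excllog[c] = olog
            for c in cs:
                if self._tip_states[c] is None:
                    # transported through the edge as seen from the child
                    # side (reverse orientation), so the equilibrium
                    # weighting in the edge objective lands at the child
                    Pc = self._pmats(self.lengths[c])
                    self._out[c] = np.matmul(self._excl[c], Pc.transpose(0, 2, 1))
                    self._outlog[c] = self._excllog[c]

    def _edge_ingredients(self, i: int):
        """Eigen-space products H (C,P,k) and per-pattern mix weights.

        Returns (H, W, shift) with W (C,P) or (C,1) such that the pattern
        likelihood at edge length t is sum_c W_cp * (H_cp . e^{lam t r_c}),
        to be logged and shifted by ``shift``.
        """
        A = np.matmul(self._excl[i] * self.eig.sqrt_pi, self.eig.V)
        slog = self._excllog[i]
        if self._tip_states[i] is not None:
            Bext = np.concatenate([self._sqrtpiV, self._missing_row], axis=0)
            B = Bext[self._tip_states[i]][None, :, :]  # (1, P, k) broadcast
        else:
            B = np.matmul(self._partial[i] * self.eig.sqrt_pi, self.eig.V)
            if self._plog[i] is not None:
                slog = (slog if slog is not None else 0.0) + self._plog[i]
        H = A * B
        if slog is None:
            W = np.exp(self.log_cat_weights)[:, None]  # (C, 1)
            shift = 0.0
        else:
            logw = self.log_cat_weights[:, None] + slog
            shift = logw.max(axis=0)
            W = np.exp(logw - shift)
        return H, W, shift

    def _edge_log_likelihood(self, H, W, shift, t: float) -> float:
        E = np.exp(np.outer(self.rates * t, self.eig.eigenvalues))  # (C, k)
        mix = 0.0
        for c in range(self.C):
            Lc = H[c] @ E[c]
            mix = mix + W[c] * Lc
        np.clip(mix, 0.0, None, out=mix)
        with np.errstate(divide="ignore"):
            pat = np.log(mix) + shift
        return float(self.pattern_weights @ pat)

    def _edge_grid_log_likelihoods(self, H, W, shift, grid: np.ndarray) -> np.ndarray:
        """Edge log-likelihood at every grid length at once; (G,)."""
        E = np.exp(
            grid[:, None, None] * self.rates[None, :, None] * self.eig.eigenvalues
        )  # (G, C, k)
        mix = 0.0
        for c in range(self.C):
            Lc = H[c] @ E[:, c, :].T  # (P, G)
            mix = mix + W[c][..., None] * Lc
        np.clip(mix, 0.0, None, out=mix)
        with np.errstate(divide="ignore"):
            pat = np.log(mix)
            if np.ndim(shift):
                pat += shift[:, None]
        return self.pattern_weights @ pat  # (G,)

    # -- optimization --------------------------------------------------------

    def optimize_branch_lengths(
        self,
        max_cycles: int = 50,
        tol: float = 1e-6,
        xatol: float = 1e-7,
        bounds: tuple[float, float] = BRANCH_BOUNDS,
    ) -> float:
        """Coordinate-wise branch-length optimization.

        Each cycle refreshes the directional partials once and optimizes
        every edge against them (a Jacobi-style sweep); the cycle is
        accepted only if the exact log-likelihood improved, otherwise it is
        redone edge-by-edge with fresh partials (a slower Gauss-Seidel
        sweep that cannot decrease the likelihood). Stops when a cycle
        gains less than ``tol`` or after ``max_cycles``.
        """
        current = self.log_likelihood()
        self.converged = False
        for _ in range(max_cycles):
            snapshot = self.lengths.copy()
            self._sweep(bounds, xatol)
            self._cache_valid = False
            new = self.log_likelihood()
            if new < current - 1e-9:
                self.lengths = snapshot
                self._cache_valid = False
                new = self._sweep_sequential(bounds, xatol)
            if new - current < tol:
                current = max(new, current)
                self.converged = True
                break
            current = new
        else:
            logger.info("branch-length optimization hit the cycle cap (maxiter)")
        self._write_lengths()
        return current

    def grid_sweeps(self, cycles: int = 2, grid: np.ndarray = _COARSE_GRID) -> float:
        """Fast coarse optimization: per edge, pick the best of a log-spaced
        grid of lengths (vectorized), with one parabolic refinement in
        log-length. Used to rank topologies before exact refinement."""
        for _ in range(cycles):
            if not self._cache_valid:
                self._down_pass()
            self._up_pass()
            for i in range(len(self._nodes) - 1):
                H, W, shift = self._edge_ingredients(i)
                vals = self._edge_grid_log_likelihoods(H, W, shift, grid)
                j = int(np.argmax(vals))
                best_t, best_v = grid[j], vals[j]
                if 0 < j < len(grid) - 1 and np.isfinite(vals[j - 1 : j + 2]).all():
                    x = np.log(grid[j - 1 : j + 2])
                    y = vals[j - 1 : j + 2]
                    denom = (y[0] - y[1]) * (x[2] - x[1]) + (y[2] - y[1]) * (x[1] - x[0])
                    if denom < 0:
                        num = (y[0] - y[1]) * (x[2] - x[1]) ** 2 - (y[2] - y[1]) * (
                            x[1] - x[0]
                        ) ** 2
                        cand = np.exp(x[1] - 0.5 * num / denom)
                        cand = float(np.clip(cand, BRANCH_BOUNDS[0], BRANCH_BOUNDS[1]))
                        v = self._edge_log_likelihood(H, W, shift, cand)
                        if v > best_v:
                            best_t, best_v = cand, v
                self.lengths[i] = best_t
            self._cache_valid = False
        lnl = self.log_likelihood()
        self._write_lengths()
        return lnl

    def _sweep(self, bounds, xatol) -> None:
        if not self._cache_valid:
            self._down_pass()
        self._up_pass()
        for i in range(len(self._nodes) - 1):
            H, W, shift = self._edge_ingredients(i)
            res = minimize_scalar(
                lambda t: -self._edge_log_likelihood(H, W, shift, t),
                bounds=bounds,
                method="bounded",
                options={"xatol": xatol},
            )
            if -res.fun >= self._edge_log_likelihood(H, W, shift, self.lengths[i]):
                self.lengths[i] = res.x

    def _sweep_sequential(self, bounds, xatol) -> float:
        for i in range(len(self._nodes) - 1):
            self._down_pass()
            self._up_pass()
            H, W, shift = self._edge_ingredients(i)
            base = self._edge_log_likelihood(H, W, shift, self.lengths[i])
            res = minimize_scalar(
                lambda t: -self._edge_log_likelihood(H, W, shift, t),
                bounds=bounds,
                method="bounded",
                options={"xatol": xatol},
            )
            if -res.fun > base:
                self.lengths[i] = res.x
            self._cache_valid = False
        return self.log_likelihood()

    def _write_lengths(self) -> None:
        for i, node in enumerate(self._nodes):
            if node is not self.tree.root:
                node.length = float(self.lengths[i])

    # -- free model parameters ----------------------------------------------

    def fit(
        self,
        free: tuple[str, ...] = (),
        max_rounds: int = 10,
        tol: float = 1e-4,
        branch_cycles: int = 5,
        final_branch_tol: float = 1e-6,
    ) -> LikelihoodResult:
        """Interleave branch-length cycles with model-parameter updates.

        ``free`` may contain ``"alpha"`` (Gamma shape, bounded [0.02, 100]),
        ``"p_inv"`` (bounded [0, 0.99]) and ``"gtr"`` (the five free GTR
        exchangeabilities, optimized on log scale).
        """
        unknown = set(free) - {"alpha", "p_inv", "gtr"}
        if unknown:
            raise LikelihoodError(f"unknown free parameters: {sorted(unknown)}")
        if "alpha" in free and self.model.gamma_shape is None:
            raise LikelihoodError("alpha is not free: model has no Gamma component")
        if "gtr" in free and not self.model.name.startswith("GTR"):
            raise LikelihoodError("gtr rates are only free in the GTR family")
        current = self.optimize_branch_lengths(max_cycles=branch_cycles, tol=tol)
        for _ in range(max_rounds):
            before = current
            if "alpha" in free:
                current = self._fit_scalar(
                    "alpha", np.log(0.02), np.log(100.0), transform=np.exp
                )
            if "p_inv" in free:
                current = self._fit_scalar("p_inv", 0.0, 0.99)
            if "gtr" in free:
                current = self._fit_gtr()
            current = self.optimize_branch_lengths(max_cycles=branch_cycles, tol=tol)
            if current - before < tol:
                break
        current = self.optimize_branch_lengths(tol=final_branch_tol)
        return self.result(current)

    def _apply_param(self, name: str, value: float) -> None:
        key = "gamma_shape" if name == "alpha" else name
        self._set_model(replace(self.model, **{key: value}))

    def _fit_scalar(self, name, lo, hi, transform=None) -> float:
        def neg(x):
            self._apply_param(name, transform(x) if transform else x)
            return -self.log_likelihood()

        res = minimize_scalar(
            neg, bounds=(lo, hi), method="bounded", options={"xatol": 1e-4}
        )
        self._apply_param(name, transform(res.x) if transform else res.x)
        return -res.fun

    def _fit_gtr(self) -> float:
        # order AC, AG, AT, CG, CT with GT fixed at 1
        current = self.model.exchangeabilities
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3)]
        x0 = np.log([max(current[i, j], 1e-6) for i, j in pairs])

        def rebuild(x):
            rates = np.append(np.exp(x), 1.0)
            model = gtr(
                rates,
                self.model.frequencies,
                gamma_shape=self.model.gamma_shape,
                n_categories=self.model.n_categories,
                p_inv=self.model.p_inv,
            )
            self._set_model(
                replace(
                    model,
                    name=self.model.name,
                    n_free_parameters=self.model.n_free_parameters,
                )
            )

        def neg(x):
            rebuild(x)
            return -self.log_likelihood()

        res = minimize(neg, x0, method="L-BFGS-B", options={"maxiter": 50})
        rebuild(res.x)
        return self.log_likelihood()

    # -- results --------------------------------------------------------------

    @property
    def n_branches(self) -> int:
        return len(self._nodes) - 1

    def result(self, lnl: float | None = None) -> LikelihoodResult:
        if lnl is None:
            lnl = self.log_likelihood()
        self._write_lengths()
        return LikelihoodResult(
            log_likelihood=lnl,
            per_site=self.site_log_likelihoods(),
            tree=self.tree,
            model=self.model,
            n_free_parameters=self.model.n_free_parameters + self.n_branches,
            converged=getattr(self, "converged", True),
        )

    def root_partials(self):
        """(partials (C,P,k), log-scales (C,P) or None, pattern map) at the
        basal node. Used by ancestral reconstruction on star trees."""
        if not self._cache_valid:
            self._down_pass()
        return (
            self._partial[self._root],
            self._plog[self._root],
            self._site_to_pattern,
        )


def write_site_table(engine: TreeLikelihood, handle) -> None:
    """Per-site TSV: 1-based site, lnL, posterior weight of each category."""
    lnl = engine.site_log_likelihoods()
    post = engine.site_category_posteriors()
    cats = "\t".join(f"cat{c + 1}_posterior" for c in range(engine.C))
    handle.write(f"site\tlog_likelihood\t{cats}\n")
    for i in range(len(lnl)):
        cells = "\t".join(f"{p:.6g}" for p in post[i])
        handle.write(f"{i + 1}\t{lnl[i]:.10g}\t{cells}\n")


# -- functional wrappers -----------------------------------------------------


def log_likelihood(
    tree: Tree, aln: Alignment, model: SubstitutionModel
) -> LikelihoodResult:
    engine = TreeLikelihood(tree, aln, model)
    return engine.result(engine.log_likelihood())


def optimize_branch_lengths(
    tree: Tree, aln: Alignment, model: SubstitutionModel, **kw
) -> tuple[Tree, LikelihoodResult]:
    engine = TreeLikelihood(tree, aln, model)
    lnl = engine.optimize_branch_lengths(**kw)
    result = engine.result(lnl)
    return result.tree, result


def fit_model_parameters(
    tree: Tree,
    aln: Alignment,
    model: SubstitutionModel,
    free: tuple[str, ...] = ("alpha",),
    **kw,
) -> LikelihoodResult:
    return TreeLikelihood(tree, aln, model).fit(free=free, **kw)


def _free_params_for(model: SubstitutionModel) -> tuple[str, ...]:
    free = []
    if model.gamma_shape is not None:
        free.append("alpha")
    if model.p_inv > 0:
        free.append("p_inv")
    if model.name.startswith("GTR"):
        free.append("gtr")
    return tuple(free)


def aic_select(
    aln: Alignment,
    tree: Tree,
    candidate_models,
    **fit_kw,
) -> pd.DataFrame:
    """Fit each candidate on the tree and rank by AIC = 2k - 2 lnL.

    ``k`` counts free model parameters plus free branch lengths. Ties are
    broken by fewer parameters, then by model name. Candidates may be
    model strings (parsed against the alignment) or model objects.
    """
    candidates = list(candidate_models)
    if len(candidates) < 2:
        raise LikelihoodError("AIC selection needs at least 2 candidate models")
    rows = []
    for cand in candidates:
        if isinstance(cand, str):
            from .substmodels import parse_model

            model = parse_model(cand, aln)
        else:
            model = cand
        res = TreeLikelihood(tree, aln, model).fit(
            free=_free_params_for(model), **fit_kw
        )
        rows.append(
            {
                "model": model.name,
                "log_likelihood": res.log_likelihood,
                "n_parameters": res.n_free_parameters,
                "aic": 2.0 * res.n_free_parameters - 2.0 * res.log_likelihood,
            }
        )
    table = pd.DataFrame(rows).sort_values(
        ["aic", "n_parameters", "model"], kind="mergesort", ignore_index=True
    )
    table["delta_aic"] = table["aic"] - table["aic"].iloc[0]
    return table
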