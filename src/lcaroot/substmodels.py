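"""Time-reversible substitution models with +Gamma, +I and +F extensions.

A model is specified by a symmetric exchangeability matrix S, equilibrium
frequencies pi, an optional discrete-Gamma shape alpha with k rate
categories, and a proportion of invariant sites p_inv. The instantaneous
rate matrix is

    Q_ij = S_ij * pi_j   (i != j),      Q_ii = -sum_j Q_ij,

rescaled so the expected rate at equilibrium is one substitution per site
(before the Gamma/invariant adjustment). Transition probabilities are
computed through the pi-weighted symmetric eigendecomposition, which is
numerically exact for reversible Q.

Shipped empirical matrices: LG (packaged ``data/lg.dat`` in PAML layout).
Parametric families: JC (4- or 20-state) and GTR for nucleotides. Model
strings such as ``"LG+G4+I+F"``, ``"GTR+G4"`` or ``"JC"`` are parsed by
:func:`parse_model`.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, replace

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .alignment import AMINO_ACID, NUCLEOTIDE, Alignment, Alphabet

__all__ = [
    "SubstitutionModel",
    "RateCategories",
    "build_rate_matrix",
    "transition_probabilities",
    "discrete_gamma_rates",
    "empirical_frequencies",
    "Eigensystem",
    "jc",
    "gtr",
    "lg",
    "parse_model",
    "lg_exchangeabilities",
]

FREQ_FLOOR = 1e-6


@dataclass(frozen=True)
class RateCategories:
    """Discrete rate categories: positive (or zero) rates with weights.

    Weights sum to 1 and the weighted mean rate is 1, so branch lengths stay
    in expected substitutions per site. An invariant-sites fraction appears
    as a rate-0 category with weight p_inv, the Gamma rates scaled up by
    1/(1-p_inv) to preserve the unit mean.
    """

    rates: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.rates, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if r.shape != w.shape or r.ndim != 1:
            raise ValueError("rates and weights must be 1-D and equal length")
        if (r < 0).any() or (w < 0).any():
            raise ValueError("rates and weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError(f"weights sum to {w.sum()}, not 1")
        if abs((w * r).sum() - 1.0) > 1e-12:
            raise ValueError(f"mean rate is {(w * r).sum()}, not 1")
        object.__setattr__(self, "rates", r)
        object.__setattr__(self, "weights", w)

    @property
    def k(self) -> int:
        return len(self.rates)


def discrete_gamma_rates(alpha: float, k: int) -> RateCategories:
    """Mean-preserving discretization of Gamma(alpha, alpha) into k classes.

    Each class has weight 1/k; its rate is the mean of the Gamma density
    over the corresponding equiprobable quantile bin, so the weighted mean
    is exactly 1 (the small numerical residue is renormalized away).
    """
    if alpha <= 0:
        raise ValueError(f"gamma shape must be positive, got {alpha}")
    if k < 1:
        raise ValueError(f"need at least one category, got {k}")
    if k == 1:
        return RateCategories(np.array([1.0]), np.array([1.0]))
    edges = gamma_dist.ppf(np.linspace(0.0, 1.0, k + 1), a=alpha, scale=1.0 / alpha)
    # E[X | a < X < b] * P(a < X < b) = P_reg(alpha+1, rate*b) - P_reg(alpha+1, rate*a)
    upper = gammainc(alpha + 1.0, alpha * edges[1:])
    lower = gammainc(alpha + 1.0, alpha * edges[:-1])
    rates = k * (upper - lower)
    rates = rates / (rates.mean())
    return RateCategories(rates, np.full(k, 1.0 / k))


def with_invariant(cats: RateCategories, p_inv: float) -> RateCategories:
    """Add a rate-0 invariant category with weight ``p_inv``."""
    if not 0.0 <= p_inv < 1.0:
        raise ValueError(f"p_inv must be in [0, 1), got {p_inv}")
    if p_inv == 0.0:
        return cats
    rates = np.concatenate([[0.0], cats.rates / (1.0 - p_inv)])
    weights = np.concatenate([[p_inv], cats.weights * (1.0 - p_inv)])
    return RateCategories(rates, weights)


@dataclass(frozen=True)
class SubstitutionModel:
    """Exchangeabilities + frequencies + rate heterogeneity parameters."""

    alphabet: Alphabet
    exchangeabilities: np.ndarray
    frequencies: np.ndarray
    gamma_shape: float | None = None
    n_categories: int = 4
    p_inv: float = 0.0
    name: str = "custom"
    #: free parameters contributed by the model itself (exchangeabilities,
    #: frequencies if empirical, gamma shape, p_inv) — used by AIC.
    n_free_parameters: int = 0

    def __post_init__(self) -> None:
        S = np.asarray(self.exchangeabilities, dtype=float)
        pi = np.asarray(self.frequencies, dtype=float)
        k = self.alphabet.size
        if S.shape != (k, k):
            raise ValueError(f"exchangeability matrix must be {k}x{k}")
        if not np.allclose(S, S.T, rtol=0, atol=1e-10):
            raise ValueError("exchangeability matrix must be symmetric")
        if (S[~np.eye(k, dtype=bool)] < 0).any():
            raise ValueError("exchangeabilities must be non-negative")
        if pi.shape != (k,) or (pi < 0).any():
            raise ValueError("frequencies must be a non-negative length-k vector")
        if abs(pi.sum() - 1.0) > 1e-12:
            raise ValueError(f"frequencies sum to {pi.sum():.15f}, not 1")
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ValueError("gamma shape must be positive")
        if not 0.0 <= self.p_inv < 1.0:
            raise ValueError("p_inv must be in [0, 1)")
        off = ~np.eye(k, dtype=bool)
        if ((pi == 0.0)[None, :] & (S > 0) & off).any():
            raise ValueError("zero frequency with nonzero exchangeability")
        object.__setattr__(self, "exchangeabilities", S)
        object.__setattr__(self, "frequencies", pi)

    def rate_matrix(self) -> np.ndarray:
        return build_rate_matrix(self)

    def rate_categories(self) -> RateCategories:
        if self.gamma_shape is None:
            cats = RateCategories(np.array([1.0]), np.array([1.0]))
        else:
            cats = discrete_gamma_rates(self.gamma_shape, self.n_categories)
        return with_invariant(cats, self.p_inv)

    def with_frequencies(self, pi: np.ndarray, plus_f: bool = True) -> "SubstitutionModel":
        extra = self.alphabet.size - 1 if plus_f else 0
        return replace(
            self, frequencies=np.asarray(pi, float), n_free_parameters=self.n_free_parameters + extra
        )

    def eigensystem(self) -> "Eigensystem":
        return Eigensystem(self.rate_matrix(), self.frequencies)


def build_rate_matrix(model: SubstitutionModel) -> np.ndarray:
    """Q = S*diag(pi) off-diagonal, zero row sums, unit expected rate."""
    S = model.exchangeabilities
    pi = model.frequencies
    Q = S * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    rate = -(pi * np.diag(Q)).sum()
    if rate <= 0:
        raise ValueError("degenerate rate matrix: zero total rate")
    return Q / rate


class Eigensystem:
    """pi-weighted symmetric eigendecomposition of a reversible Q.

    With D = diag(pi), the matrix D^{1/2} Q D^{-1/2} is symmetric; its
    eigendecomposition V diag(lam) V^T gives

        P(t) = D^{-1/2} V exp(lam t) V^T D^{1/2}.
    """

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        pi = np.asarray(pi, dtype=float)
        self.pi = pi
        self.sqrt_pi = np.sqrt(pi)
        self.inv_sqrt_pi = 1.0 / self.sqrt_pi
        sym = (Q * self.sqrt_pi[:, None]) * self.inv_sqrt_pi[None, :]
        sym = 0.5 * (sym + sym.T)
        lam, V = np.linalg.eigh(sym)
        self.eigenvalues = lam
        self.V = V
        #: left/right operators so that P(t) = right @ diag(e^{lam t}) @ left
        self.right = self.inv_sqrt_pi[:, None] * V
        self.left = V.T * self.sqrt_pi[None, :]

    def probability(self, t: float, rate: float = 1.0) -> np.ndarray:
        if t < 0:
            raise ValueError(f"branch length must be non-negative, got {t}")
        if t * rate == 0.0:  # exact: P(0) = I (also the invariant category)
            return np.eye(len(self.pi))
        P = (self.right * np.exp(self.eigenvalues * t * rate)) @ self.left
        np.clip(P, 0.0, None, out=P)
        return P

    def probabilities(self, t: float, rates: np.ndarray) -> np.ndarray:
        """Stack of P(t * r) for each rate r; shape (len(rates), k, k)."""
        if t < 0:
            raise ValueError(f"branch length must be non-negative, got {t}")
        rates = np.asarray(rates, dtype=float)
        k = len(self.pi)
        E = np.exp(np.outer(rates * t, self.eigenvalues))  # (C, k)
        P = np.matmul(self.right[None, :, :] * E[:, None, :], self.left)
        np.clip(P, 0.0, None, out=P)
        zero = rates * t == 0.0
        if zero.any():  # exact: P(0) = I (also the invariant category)
            P[zero] = np.eye(k)
        return P


def transition_probabilities(
    Q: np.ndarray,
    t: float,
    rate: float = 1.0,
    frequencies: np.ndarray | None = None,
) -> np.ndarray:
    """P = exp(Q t rate). If ``frequencies`` is given, uses the symmetric
    eigendecomposition (exact for reversible Q); otherwise scipy's expm."""
    if t < 0:
        raise ValueError(f"branch length must be non-negative, got {t}")
    if frequencies is not None:
        return Eigensystem(np.asarray(Q, float), frequencies).probability(t, rate)
    from scipy.linalg import expm

    return expm(np.asarray(Q, float) * t * rate)


def empirical_frequencies(aln: Alignment, floor: float = FREQ_FLOOR) -> np.ndarray:
    """Observed state proportions over all non-gap, non-missing residues.

    Zero-count states are floored at ``floor`` and the vector renormalized,
    keeping Q irreducible on short alignments.
    """
    m = aln.matrix()
    k = aln.alphabet.size
    counts = np.bincount(m[m >= 0].ravel(), minlength=k).astype(float)
    if counts.sum() == 0:
        raise ValueError("alignment contains only gap/missing symbols")
    pi = counts / counts.sum()
    pi = np.maximum(pi, floor)
    return pi / pi.sum()


# -- model factories --------------------------------------------------------


def _uniform(k: int) -> np.ndarray:
    return np.full(k, 1.0 / k)


def jc(alphabet: Alphabet = NUCLEOTIDE, **kw) -> SubstitutionModel:
    """Jukes–Cantor: equal exchangeabilities, uniform frequencies."""
    k = alphabet.size
    S = np.ones((k, k))
    np.fill_diagonal(S, 0.0)
    return SubstitutionModel(
        alphabet=alphabet, exchangeabilities=S, frequencies=_uniform(k),
        name="JC", n_free_parameters=0, **kw,
    )


def gtr(
    rates: np.ndarray | None = None,
    frequencies: np.ndarray | None = None,
    **kw,
) -> SubstitutionModel:
    """General time-reversible nucleotide model.

    ``rates`` are the 6 exchangeabilities in order AC, AG, AT, CG, CT, GT
    (GT is the conventional reference and is not counted as free).
    """
    if rates is None:
        rates = np.ones(6)
    rates = np.asarray(rates, dtype=float)
    if rates.shape != (6,) or (rates <= 0).any():
        raise ValueError("GTR needs 6 positive exchangeabilities")
    S = np.zeros((4, 4))
    pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    for r, (i, j) in zip(rates, pairs):
        S[i, j] = S[j, i] = r
    pi = _uniform(4) if frequencies is None else np.asarray(frequencies, float)
    # 5 free exchangeabilities (GT fixed); frequencies counted only via +F
    return SubstitutionModel(
        alphabet=NUCLEOTIDE, exchangeabilities=S, frequencies=pi,
        name="GTR", n_free_parameters=5, **kw,
    )


def lg_exchangeabilities() -> tuple[np.ndarray, np.ndarray]:
    """LG exchangeability matrix and its model frequencies (PAML order)."""
    text = (
        importlib.resources.files("lcaroot").joinpath("data/lg.dat").read_text()
    )
    rows = [line.split() for line in text.splitlines() if line.strip()]
    tri, freq_row = rows[:19], rows[19]
    S = np.zeros((20, 20))
    for i, row in enumerate(tri, start=1):
        for j, value in enumerate(row):
            S[i, j] = S[j, i] = float(value)
    pi = np.array([float(x) for x in freq_row])
    pi = pi / pi.sum()
    return S, pi


def lg(frequencies: np.ndarray | None = None, **kw) -> SubstitutionModel:
    """Le–Gascuel amino-acid model; optional empirical (+F) frequencies."""
    S, pi_model = lg_exchangeabilities()
    pi = pi_model if frequencies is None else np.asarray(frequencies, float)
    return SubstitutionModel(
        alphabet=AMINO_ACID, exchangeabilities=S, frequencies=pi,
        name="LG", n_free_parameters=0, **kw,
    )


def parse_model(spec: str, alignment: Alignment | None = None) -> SubstitutionModel:
    """Parse a model string such as ``LG+G4+I+F`` or ``GTR+G4`` or ``JC``.

    ``+F`` takes empirical frequencies from ``alignment`` (required then).
    ``+G``/``+G<k>`` enables discrete-Gamma rates with an initial shape of 1
    (fit it with the likelihood engine); ``+I`` enables an invariant-sites
    category starting at 0 (likewise a free parameter when fitted).
    """
    parts = spec.strip().upper().split("+")
    family, extras = parts[0], parts[1:]
    gamma_k = None
    plus_i = plus_f = False
    for token in extras:
        if token.startswith("G"):
            gamma_k = int(token[1:]) if len(token) > 1 else 4
        elif token == "I":
            plus_i = True
        elif token == "F":
            plus_f = True
        else:
            raise ValueError(f"unknown model component {token!r} in {spec!r}")
    if family == "JC":
        model = jc(NUCLEOTIDE if alignment is None or alignment.alphabet.size == 4 else AMINO_ACID)
    elif family == "GTR":
        model = gtr()
    elif family == "LG":
        model = lg()
    else:
        raise ValueError(f"unknown model family {family!r} in {spec!r}")
    extra_params = model.n_free_parameters
    name = family
    if gamma_k is not None:
        model = replace(model, gamma_shape=1.0, n_categories=gamma_k)
        extra_params += 1
        name += f"+G{gamma_k}"
    if plus_i:
        model = replace(model, p_inv=1e-6)
        extra_params += 1
        name += "+I"
    if plus_f:
        if alignment is None:
            raise ValueError("+F requires an alignment for empirical frequencies")
        if alignment.alphabet.name != model.alphabet.name:
            raise ValueError("alignment alphabet does not match model family")
        pi = empirical_frequencies(alignment)
        model = replace(model, frequencies=pi)
        extra_params += model.alphabet.size - 1
        name += "+F"
    return replace(model, name=name, n_free_parameters=extra_params)
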