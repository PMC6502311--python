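"""Diploid multiplicative fitness with epistatic dominance.

An individual heterozygous for derived mutations at loci in set G1 and
homozygous at loci in G2 has fitness

    W(G1, G2) = prod_{i in G1} (1 + h_i s_i) * prod_{i in G2} (1 + s_i)
              * prod_{{i,j} in G1}        (1 + alpha1 * eps_ij)
              * prod_{i in G1, j in G2}   (1 + alpha2 * eps_ij)
              * prod_{{i,j} in G2}        (1 + eps_ij)

where each unordered pair contributes exactly one factor.  ``alpha1``
and ``alpha2`` scale epistasis when both or one of the interacting
loci are heterozygous (epistatic dominance); homozygous-by-homozygous
interactions act at full strength.  The ancestor (no derived
mutations) has fitness exactly 1.  Any individual factor that falls
below 0 — a composite more than lethal — is clamped to 0, making the
genotype lethal.

F1 hybrid fitness is measured relative to the arithmetic mean of the
two parental species: the hybrid is heterozygous for the union of the
mutations fixed in either population, each parent homozygous for its
own set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from epistasim.network import EpistasisNetwork


@dataclass(frozen=True)
class DominanceParams:
    """Dominance of independent (h) and epistatic (alpha1, alpha2) effects.

    ``alpha1`` scales interactions between two heterozygous loci,
    ``alpha2`` those between a heterozygous and a homozygous locus.
    ``alpha1 = 1/4, alpha2 = 1/2`` correspond to additive epistasis
    (each derived-allele copy contributing equally); ``h_default`` is
    used for loci whose network does not override it.
    """

    h_default: float = 0.5
    alpha1: float = 0.25
    alpha2: float = 0.5

    def __post_init__(self) -> None:
        if not 0 <= self.alpha1 <= 1:
            raise ValueError("alpha1 must lie in [0, 1]")
        if not 0 <= self.alpha2 <= 1:
            raise ValueError("alpha2 must lie in [0, 1]")


@dataclass(frozen=True)
class GenotypeSpec:
    """Loci heterozygous (het_loci) and homozygous (hom_loci) for mutations."""

    het_loci: frozenset[str]
    hom_loci: frozenset[str]

    def __init__(self, het_loci: Iterable[str] = (), hom_loci: Iterable[str] = ()):
        object.__setattr__(self, "het_loci", frozenset(het_loci))
        object.__setattr__(self, "hom_loci", frozenset(hom_loci))
        if self.het_loci & self.hom_loci:
            raise ValueError(
                f"loci cannot be both het and hom: {sorted(self.het_loci & self.hom_loci)}"
            )


@dataclass(frozen=True)
class EffectiveCoefficients:
    """Background-dependent selection (sigma) and dominance (omega)."""

    sigma: float
    omega: float


def _factor(x: float) -> float:
    # composite effects below -1 make the genotype lethal, not negative-fit
    return max(x, 0.0)


def genotype_fitness(
    network: EpistasisNetwork,
    genotype: GenotypeSpec,
    dom: DominanceParams | None = None,
) -> float:
    """Absolute fitness of a genotype on the network (ancestor = 1)."""
    dom = dom or DominanceParams()
    het = sorted(network.index(l) for l in genotype.het_loci)
    hom = sorted(network.index(l) for l in genotype.hom_loci)

    w = 1.0
    for i in het:
        h_i = network.h[i] if network.h is not None else dom.h_default
        w *= _factor(1.0 + h_i * network.s[i])
    for i in hom:
        w *= _factor(1.0 + network.s[i])

    # one factor per unordered pair
    for a_pos, i in enumerate(het):
        for j in het[a_pos + 1:]:
            w *= _factor(1.0 + dom.alpha1 * network.epsilon_by_index(i, j))
        for j in hom:
            w *= _factor(1.0 + dom.alpha2 * network.epsilon_by_index(i, j))
    for a_pos, i in enumerate(hom):
        for j in hom[a_pos + 1:]:
            w *= _factor(1.0 + network.epsilon_by_index(i, j))
    return w


def relative_hybrid_fitness(
    network: EpistasisNetwork,
    fixed_A: Iterable[str],
    fixed_B: Iterable[str],
    dom: DominanceParams | None = None,
) -> float:
    """F1 hybrid fitness relative to the mean of the two parents.

    The F1 is heterozygous for every mutation fixed in either
    population; each parent is homozygous for its own set.  Values
    above 1 indicate heterosis, below 1 postzygotic isolation.
    """
    dom = dom or DominanceParams()
    A, B = frozenset(fixed_A), frozenset(fixed_B)
    if A & B:
        raise ValueError(f"populations share fixed loci: {sorted(A & B)}")
    hybrid = genotype_fitness(network, GenotypeSpec(het_loci=A | B), dom)
    w_a = genotype_fitness(network, GenotypeSpec(hom_loci=A), dom)
    w_b = genotype_fitness(network, GenotypeSpec(hom_loci=B), dom)
    parent_mean = 0.5 * (w_a + w_b)
    if parent_mean == 0:
        raise ZeroDivisionError("both parental genotypes are lethal")
    return hybrid / parent_mean


def effective_selection(
    network: EpistasisNetwork,
    locus: str,
    background: Iterable[str],
    dom: DominanceParams | None = None,
) -> EffectiveCoefficients:
    """Net selection on a new mutation given the fixed background.

    A new mutation at locus i arising in a population fixed for the
    set A is heterozygous while every background mutation is
    homozygous, so

        sigma_i|A = (1 + s_i) * prod_{j in A} (1 + eps_ij) - 1
        omega_i|A = [(1 + h_i s_i) * prod_{j in A} (1 + alpha2 eps_ij) - 1] / sigma_i|A

    with each factor clamped at 0.  With an empty background sigma is
    s_i and omega is h_i; when sigma is exactly 0 omega is taken as
    h_i (the continuous limit).
    """
    dom = dom or DominanceParams()
    i = network.index(locus)
    bg = [network.index(l) for l in background]
    if i in bg:
        raise ValueError(f"locus {locus!r} already fixed in the background")

    hom_prod = _factor(1.0 + network.s[i])
    het_prod = _factor(1.0 + network.h[i] * network.s[i])
    for j in bg:
        e = network.epsilon_by_index(i, j)
        hom_prod *= _factor(1.0 + e)
        het_prod *= _factor(1.0 + dom.alpha2 * e)
    sigma = hom_prod - 1.0
    if sigma == 0.0:
        omega = float(network.h[i])
    else:
        omega = (het_prod - 1.0) / sigma
    return EffectiveCoefficients(sigma=float(sigma), omega=float(omega))


# ---------------------------------------------------------------------------
# Vectorised background products used by the divergence simulator
# ---------------------------------------------------------------------------


def background_products(
    network: EpistasisNetwork,
    dom: DominanceParams,
) -> "BackgroundProducts":
    return BackgroundProducts(network, dom)


class BackgroundProducts:
    """Running per-locus products over a growing fixed background.

    Maintains, for every locus i, ``prod_j (1 + eps_ij)`` and
    ``prod_j (1 + alpha2 eps_ij)`` over the background fixed so far,
    with the same factor clamping as :func:`effective_selection`, so
    effective coefficients for all candidate loci are available in
    O(neighbours) per fixation instead of O(background).
    """

    def __init__(self, network: EpistasisNetwork, dom: DominanceParams) -> None:
        self.network = network
        self.dom = dom
        n = network.n_loci
        self.hom = np.maximum(1.0 + network.s, 0.0)
        self.het = np.maximum(1.0 + network.h * network.s, 0.0)

    def add_fixed(self, j: int) -> np.ndarray:
        """Fold locus j into the background; returns affected locus indices."""
        neigh, eps = self.network.adjacency()[j]
        if neigh.size:
            self.hom[neigh] *= np.maximum(1.0 + eps, 0.0)
            self.het[neigh] *= np.maximum(1.0 + self.dom.alpha2 * eps, 0.0)
        return neigh

    def sigma(self, idx: np.ndarray | Sequence[int]) -> np.ndarray:
        return self.hom[idx] - 1.0

    def het_selection(self, idx: np.ndarray | Sequence[int]) -> np.ndarray:
        """Selection coefficient of the heterozygote, (1+h s) prod - 1."""
        return self.het[idx] - 1.0
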