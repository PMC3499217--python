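"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from first principles, without
reusing any code path from the package under test.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations, permutations

import numpy as np


# ---------------------------------------------------------------------------
# Polya-urn / Dirichlet-multinomial predictive for one biallelic locus
# ---------------------------------------------------------------------------


def polya_genotype_prob(
    genotype: int, n_alt: int, n_obs: int, tau: Fraction = Fraction(1, 2)
) -> Fraction:
    """Exact predictive probability of drawing a genotype (alt dosage) as two
    sequential Polya-urn draws from reference counts plus a per-allele
    prior mass ``tau``."""
    n_ref = n_obs - n_alt
    total = n_obs + 2 * tau

    def draw(alt_count: int, ref_count: int, want_alt: bool) -> Fraction:
        mass = Fraction(alt_count) + tau if want_alt else Fraction(ref_count) + tau
        return mass / (Fraction(alt_count + ref_count) + 2 * tau)

    if genotype == 2:
        return draw(n_alt, n_ref, True) * draw(n_alt + 1, n_ref, True)
    if genotype == 0:
        return draw(n_alt, n_ref, False) * draw(n_alt, n_ref + 1, False)
    if genotype == 1:
        # alt-then-ref plus ref-then-alt orderings
        return draw(n_alt, n_ref, True) * draw(n_alt + 1, n_ref, False) + draw(
            n_alt, n_ref, False
        ) * draw(n_alt, n_ref + 1, True)
    raise ValueError(genotype)


# ---------------------------------------------------------------------------
# Weir & Cockerham (1984) theta, scalar reference implementation
# ---------------------------------------------------------------------------


def wc_theta_components(pops: list[list[int]]) -> tuple[float, float, float]:
    """Variance components (a, b, c) for one biallelic locus.

    ``pops`` holds, per population, the list of genotype codes (alt
    dosage 0/1/2) of its sampled individuals.  Plain-python transcription
    of the 1984 component formulas, kept scalar on purpose.
    """
    r = len(pops)
    n = [len(p) for p in pops]
    p_hat = [sum(pop) / (2.0 * len(pop)) for pop in pops]
    h_hat = [sum(1 for g in pop if g == 1) / len(pop) for pop in pops]

    nbar = sum(n) / r
    nc = (r * nbar - sum(ni**2 for ni in n) / (r * nbar)) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p_hat)) / (r * nbar)
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p_hat)) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n, h_hat)) / (r * nbar)

    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar)
        - (r - 1) / r * s2
        - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2.0
    return a, b, c


def wc_theta(pops: list[list[int]]) -> float:
    a, b, c = wc_theta_components(pops)
    if a + b + c == 0:
        return float("nan")
    return a / (a + b + c)


# ---------------------------------------------------------------------------
# small-tree least-squares topology oracle
# ---------------------------------------------------------------------------


def _pairdist(dist: dict[tuple[str, str], float], x: str, y: str) -> float:
    if x == y:
        return 0.0
    return dist[(x, y)] if (x, y) in dist else dist[(y, x)]


def quartet_split(dist: dict[tuple[str, str], float], quartet: list[str]):
    """Brute-force the supported split of one quartet by enumerating all
    three topologies under the four-point condition; returns the pair that
    sits together, or None if no topology wins strictly."""
    a, b, c, d = quartet
    sums = {
        frozenset([a, b]): _pairdist(dist, a, b) + _pairdist(dist, c, d),
        frozenset([a, c]): _pairdist(dist, a, c) + _pairdist(dist, b, d),
        frozenset([a, d]): _pairdist(dist, a, d) + _pairdist(dist, b, c),
    }
    ranked = sorted(sums.items(), key=lambda kv: kv[1])
    if ranked[1][1] - ranked[0][1] <= 1e-12:
        return None
    return ranked[0][0]


def enumerate_tree_bipartitions(
    dist: dict[tuple[str, str], float], taxa: list[str]
) -> set[frozenset[str]]:
    """All non-trivial bipartitions of the tree implied by an additive
    matrix, recovered by exhaustive quartet enumeration: a candidate side S
    is an edge of the tree iff every quartet with two taxa drawn from each
    side supports keeping the sides apart."""
    out: set[frozenset[str]] = set()
    taxa = list(taxa)
    for k in range(2, len(taxa) - 1):
        for side in combinations(taxa, k):
            side_set = set(side)
            other = [t for t in taxa if t not in side_set]
            ok = True
            for s1, s2 in combinations(side, 2):
                for o1, o2 in combinations(other, 2):
                    if quartet_split(dist, [s1, s2, o1, o2]) != frozenset([s1, s2]):
                        ok = False
                        break
                if not ok:
                    break
            if ok:
                ref = min(taxa)
                out.add(
                    frozenset(other) if ref in side_set else frozenset(side)
                )
    return out


def tree_distances(adjacency: dict[str, list[tuple[str, float]]]):
    """All-pairs path lengths in an explicitly specified weighted tree."""
    names = [n for n in adjacency if not n.startswith("_")]
    out = {}
    for src in names:
        dist = {src: 0.0}
        stack = [src]
        while stack:
            node = stack.pop()
            for nbr, w in adjacency[node]:
                if nbr not in dist:
                    dist[nbr] = dist[node] + w
                    stack.append(nbr)
        for dst in names:
            if src < dst:
                out[(src, dst)] = dist[dst]
    return out
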