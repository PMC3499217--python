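"""Population differentiation and relationship statistics.

Implements the Weir & Cockerham (1984) variance-component estimator of
F_ST (multi-locus values aggregate as ratio-of-sums), the Reynolds, Weir &
Cockerham (1983) coancestry distance in its frequency-only, locus-summed
form (PHYLIP ``gendist`` convention), Saitou-Nei neighbour joining with a
deterministic tie-break, locus-bootstrap branch support, and two-locus r^2
from unphased genotypes via EM haplotype-frequency estimation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import EntityLookupError, ValidationError
from .genotype_io import MISSING, AlleleFrequencyTable, GenotypeDataset

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Weir & Cockerham theta
# ---------------------------------------------------------------------------


def _pop_locus_summaries(
    data: GenotypeDataset, breeds: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per population x locus: sample size n_i (individuals), alt-allele
    frequency p_i and observed heterozygote frequency h_i."""
    n = np.empty((len(breeds), data.n_loci))
    p = np.empty_like(n)
    h = np.empty_like(n)
    for k, breed in enumerate(breeds):
        calls = data.calls[data.sample_indices(breed)]
        obs = calls != MISSING
        cnt = obs.sum(axis=0)
        n[k] = cnt
        with np.errstate(invalid="ignore", divide="ignore"):
            p[k] = np.where(obs, calls, 0).sum(axis=0) / (2.0 * cnt)
            h[k] = (calls == 1).sum(axis=0) / cnt
        p[k, cnt == 0] = np.nan
        h[k, cnt == 0] = np.nan
    return n, p, h


def _wc_components(
    n: np.ndarray, p: np.ndarray, h: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Weir & Cockerham (1984) per-locus variance components a, b, c.

    Inputs are (r populations x L loci) arrays; loci where any population
    has no data, or with mean sample size <= 1, are flagged invalid.
    """
    r = n.shape[0]
    valid = (n > 0).all(axis=0)
    nbar = n.mean(axis=0)
    valid &= nbar > 1.0
    nbar = np.where(valid, nbar, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n**2).sum(axis=0) / (r * nbar)) / (r - 1.0)
        pbar = (n * p).sum(axis=0) / (r * nbar)
        s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1.0) * nbar)
        hbar = (n * h).sum(axis=0) / (r * nbar)
        inner = pbar * (1 - pbar) - (r - 1.0) / r * s2
        a = (nbar / nc) * (s2 - (inner - hbar / 4.0) / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (inner - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar)
        c = hbar / 2.0
    # nc can hit zero when all data sit in one population; treat as invalid
    valid &= np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    return a, b, c, valid


def wc_fst(data: GenotypeDataset, breed_a: str, breed_b: str) -> float:
    """Multi-locus Weir-Cockerham theta between two breeds.

    Ratio of locus-summed among-population components to locus-summed
    totals; monomorphic loci contribute zero to both sums.  Returns NaN
    when no locus is informative.
    """
    for breed in (breed_a, breed_b):
        if data.sample_indices(breed).size < 2:
            raise ValidationError(f"breed {breed!r} needs >= 2 samples for theta")
    n, p, h = _pop_locus_summaries(data, [breed_a, breed_b])
    a, b, c, valid = _wc_components(n, p, h)
    num = np.nansum(np.where(valid, a, 0.0))
    den = np.nansum(np.where(valid, a + b + c, 0.0))
    if den == 0.0:
        return float("nan")
    return float(num / den)


@dataclass
class PairwiseStatMatrix:
    """Symmetric between-breed statistic matrix with per-breed row means."""

    breeds: list[str]
    values: np.ndarray
    kind: str  # "wc_fst" or "reynolds"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.breeds), len(self.breeds)):
            raise ValidationError("matrix shape does not match breed list")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValidationError("matrix must be symmetric")
        self.values = v

    def value(self, a: str, b: str) -> float:
        i, j = self.breeds.index(a), self.breeds.index(b)
        return float(self.values[i, j])

    def breed_means(self) -> pd.DataFrame:
        """Mean and SD of each breed's off-diagonal row."""
        off = self.values.copy()
        np.fill_diagonal(off, np.nan)
        return pd.DataFrame(
            {
                "mean": np.nanmean(off, axis=1),
                "sd": np.nanstd(off, axis=1, ddof=1),
            },
            index=self.breeds,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.breeds, columns=self.breeds)

    def to_csv(self, path: str | Path) -> None:
        """Lower-triangle layout with a trailing ``mean (sd)`` column."""
        means = self.breed_means()
        rows = []
        for i, breed in enumerate(self.breeds):
            row: dict[str, object] = {"breed": breed}
            for j in range(i):
                row[self.breeds[j]] = round(float(self.values[i, j]), 6)
            row["mean (sd)"] = (
                f"{means['mean'][breed]:.2f} ({means['sd'][breed]:.2f})"
            )
            rows.append(row)
        pd.DataFrame(rows, columns=["breed"] + self.breeds[:-1] + ["mean (sd)"]).to_csv(
            path, index=False
        )


def fst_matrix(
    data: GenotypeDataset, breeds: Sequence[str] | None = None
) -> PairwiseStatMatrix:
    breeds = list(breeds) if breeds is not None else data.breed_names()
    if len(breeds) < 2:
        raise ValidationError("need >= 2 breeds")
    m = np.zeros((len(breeds), len(breeds)))
    for i, j in combinations(range(len(breeds)), 2):
        m[i, j] = m[j, i] = wc_fst(data, breeds[i], breeds[j])
    return PairwiseStatMatrix(breeds, m, "wc_fst")


# ---------------------------------------------------------------------------
# Reynolds distance
# ---------------------------------------------------------------------------


def _reynolds_locus_terms(
    fa: np.ndarray, fb: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus numerator/denominator of the frequency-only Reynolds
    distance for two breeds: num = sum_a (p1a - p2a)^2 / 2, den = 1 -
    sum_a p1a p2a.  Loci where either frequency is undefined are invalid."""
    valid = np.isfinite(fa) & np.isfinite(fb)
    num = (fa - fb) ** 2  # biallelic: sum over the two alleles, halved
    den = 1.0 - (fa * fb + (1.0 - fa) * (1.0 - fb))
    return num, den, valid


def reynolds_distance(
    freq_a: AlleleFrequencyTable | np.ndarray, freq_b: AlleleFrequencyTable | np.ndarray
) -> float:
    fa = freq_a.freq_alt if isinstance(freq_a, AlleleFrequencyTable) else np.asarray(freq_a, float)
    fb = freq_b.freq_alt if isinstance(freq_b, AlleleFrequencyTable) else np.asarray(freq_b, float)
    num, den, valid = _reynolds_locus_terms(fa, fb)
    total_den = den[valid].sum()
    if total_den == 0.0:
        return 0.0
    return float(num[valid].sum() / total_den)


def reynolds_matrix(
    data: GenotypeDataset, breeds: Sequence[str] | None = None
) -> PairwiseStatMatrix:
    breeds = list(breeds) if breeds is not None else data.breed_names()
    if len(breeds) < 2:
        raise ValidationError("need >= 2 breeds")
    from .genotype_io import estimate_frequencies

    freqs = {b: estimate_frequencies(data, b).freq_alt for b in breeds}
    m = np.zeros((len(breeds), len(breeds)))
    for i, j in combinations(range(len(breeds)), 2):
        m[i, j] = m[j, i] = reynolds_distance(freqs[breeds[i]], freqs[breeds[j]])
    return PairwiseStatMatrix(breeds, m, "reynolds")


# ---------------------------------------------------------------------------
# neighbour joining
# ---------------------------------------------------------------------------


class PhyloTree:
    """An unrooted tree over breed leaves, stored as a weighted adjacency.

    Internal nodes are integers >= number of leaves; leaves are 0..n-1 and
    map to ``leaf_names``.  ``support`` maps internal-edge bipartitions
    (canonical leaf-name frozensets) to percentages in [0, 100].
    """

    def __init__(self, leaf_names: Sequence[str]) -> None:
        self.leaf_names = list(leaf_names)
        self.adj: dict[int, dict[int, float]] = {i: {} for i in range(len(leaf_names))}
        self.support: dict[frozenset[str], float] = {}
        self.clamped_deficit: float = 0.0

    def add_node(self) -> int:
        node = max(self.adj) + 1 if self.adj else 0
        self.adj[node] = {}
        return node

    def add_edge(self, u: int, v: int, length: float) -> None:
        if length < 0:
            self.clamped_deficit += -length
            length = 0.0
        self.adj[u][v] = length
        self.adj[v][u] = length

    # -- queries ---------------------------------------------------------

    def _leafset_beyond(self, u: int, v: int) -> frozenset[str]:
        """Leaves reachable from v without passing through u."""
        seen, stack, leaves = {u, v}, [v], []
        while stack:
            node = stack.pop()
            if node < len(self.leaf_names):
                leaves.append(self.leaf_names[node])
            for nbr in self.adj[node]:
                if nbr not in seen:
                    seen.add(nbr)
                    stack.append(nbr)
        return frozenset(leaves)

    def bipartitions(self) -> set[frozenset[str]]:
        """Canonical non-trivial bipartitions (the side lacking the first
        leaf name, for a stable representation)."""
        ref = min(self.leaf_names)
        out = set()
        n_leaves = len(self.leaf_names)
        for u in self.adj:
            for v in self.adj[u]:
                if u < v and u >= n_leaves and v >= n_leaves:
                    side = self._leafset_beyond(u, v)
                    if ref in side:
                        side = frozenset(self.leaf_names) - side
                    out.add(side)
        return out

    def path_length(self, name_a: str, name_b: str) -> float:
        a = self.leaf_names.index(name_a)
        b = self.leaf_names.index(name_b)
        dist = {a: 0.0}
        stack = [a]
        while stack:
            node = stack.pop()
            for nbr, w in self.adj[node].items():
                if nbr not in dist:
                    dist[nbr] = dist[node] + w
                    stack.append(nbr)
        return dist[b]

    # -- serialisation ---------------------------------------------------

    def _newick_node(self, node: int, parent: int | None) -> str:
        children = [n for n in self.adj[node] if n != parent]
        if not children:
            return self.leaf_names[node]
        parts = []
        for child in children:
            sub = self._newick_node(child, node)
            parts.append(f"{sub}:{self.adj[node][child]:.6f}")
        label = ""
        if parent is not None and self.support:
            side = self._leafset_beyond(parent, node)
            ref = min(self.leaf_names)
            key = side if ref not in side else frozenset(self.leaf_names) - side
            if key in self.support:
                label = f"{self.support[key]:.0f}"
        return f"({','.join(parts)}){label}"

    def newick(self) -> str:
        root = max(self.adj)  # final join; a trifurcation for unrooted trees
        return self._newick_node(root, None) + ";"


def nj_tree(matrix: PairwiseStatMatrix | pd.DataFrame) -> PhyloTree:
    """Saitou-Nei neighbour joining with lowest-index tie-breaking.

    Negative branch lengths are clamped to zero; the total clamped
    deficit is recorded on the returned tree and logged.
    """
    if isinstance(matrix, PairwiseStatMatrix):
        names = matrix.breeds
        d = matrix.values.copy()
    else:
        names = list(matrix.index)
        d = matrix.to_numpy(dtype=float).copy()
    n = len(names)
    if n < 3:
        raise ValidationError("neighbour joining needs >= 3 taxa")
    if not np.isfinite(d).all():
        raise ValidationError("distance matrix contains non-finite entries")

    tree = PhyloTree(names)
    active: list[int] = list(range(n))  # node ids in tree
    dist = d

    while len(active) > 3:
        r = len(active)
        totals = dist.sum(axis=1)
        q = (r - 2) * dist - totals[:, None] - totals[None, :]
        np.fill_diagonal(q, np.inf)
        flat = np.argmin(q)  # first minimum -> lowest (i, j) in row-major order
        i, j = divmod(flat, r)
        if i > j:
            i, j = j, i
        li = 0.5 * dist[i, j] + (totals[i] - totals[j]) / (2.0 * (r - 2))
        lj = dist[i, j] - li
        new = tree.add_node()
        tree.add_edge(active[i], new, li)
        tree.add_edge(active[j], new, lj)

        d_new = 0.5 * (dist[i, :] + dist[j, :] - dist[i, j])
        keep = [k for k in range(r) if k not in (i, j)]
        nd = np.empty((r - 1, r - 1))
        nd[:-1, :-1] = dist[np.ix_(keep, keep)]
        nd[-1, :-1] = d_new[keep]
        nd[:-1, -1] = d_new[keep]
        nd[-1, -1] = 0.0
        dist = nd
        active = [active[k] for k in keep] + [new]

    # final three-point closed form
    a, b, c = active
    dab, dac, dbc = dist[0, 1], dist[0, 2], dist[1, 2]
    center = tree.add_node()
    tree.add_edge(a, center, 0.5 * (dab + dac - dbc))
    tree.add_edge(b, center, 0.5 * (dab + dbc - dac))
    tree.add_edge(c, center, 0.5 * (dac + dbc - dab))
    if tree.clamped_deficit > 0:
        logger.info(
            "clamped negative NJ branch lengths (total deficit %.6g)",
            tree.clamped_deficit,
        )
    return tree


def bootstrap_support(
    data: GenotypeDataset,
    panel_loci: Sequence[str] | None = None,
    n_reps: int = 1000,
    seed: int | None = None,
) -> PhyloTree:
    """Full-data Reynolds NJ tree annotated with locus-bootstrap support.

    Loci are resampled with replacement ``n_reps`` times; the support of
    each internal edge of the full-data tree is the percentage of
    replicate trees containing the same bipartition.
    """
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    if panel_loci is not None:
        data = data.subset_loci(panel_loci)
    breeds = data.breed_names()
    from .genotype_io import estimate_frequencies

    freqs = np.vstack([estimate_frequencies(data, b).freq_alt for b in breeds])
    pairs = list(combinations(range(len(breeds)), 2))
    L = data.n_loci
    num = np.empty((len(pairs), L))
    den = np.empty((len(pairs), L))
    valid = np.empty((len(pairs), L), dtype=bool)
    for k, (i, j) in enumerate(pairs):
        num[k], den[k], valid[k] = _reynolds_locus_terms(freqs[i], freqs[j])
    num = np.where(valid, num, 0.0)
    den = np.where(valid, den, 0.0)

    def matrix_from(idx: np.ndarray) -> np.ndarray:
        m = np.zeros((len(breeds), len(breeds)))
        ns = num[:, idx].sum(axis=1)
        ds = den[:, idx].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(ds > 0, ns / ds, 0.0)
        for k, (i, j) in enumerate(pairs):
            m[i, j] = m[j, i] = vals[k]
        return m

    full = nj_tree(PairwiseStatMatrix(breeds, matrix_from(np.arange(L)), "reynolds"))
    target = full.bipartitions()
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        idx = rng.integers(0, L, size=L)
        rep = nj_tree(PairwiseStatMatrix(breeds, matrix_from(idx), "reynolds"))
        for bp in rep.bipartitions():
            if bp in counts:
                counts[bp] += 1
    full.support = {bp: 100.0 * c / n_reps for bp, c in counts.items()}
    return full


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LdResult:
    locus_a: str
    locus_b: str
    breed: str
    r_squared: float  # NaN when undefined (monomorphic locus / no data)
    em_converged: bool = True

    @property
    def defined(self) -> bool:
        return math.isfinite(self.r_squared)


def _em_haplotype_freqs(
    counts: np.ndarray, tol: float = 1e-8, max_iter: int = 1000
) -> tuple[np.ndarray, bool]:
    """EM haplotype frequencies (f_AB, f_Ab, f_aB, f_ab) from a 3x3 table of
    two-locus genotype counts, where allele A/B = alternate allele and
    index = alt dosage at each locus."""
    n_total = counts.sum()
    # known haplotype contributions: every genotype except double het is phased
    p1 = (counts * np.arange(3)[:, None]).sum() / (2 * n_total)
    p2 = (counts * np.arange(3)[None, :]).sum() / (2 * n_total)
    f = np.array(
        [p1 * p2, p1 * (1 - p2), (1 - p1) * p2, (1 - p1) * (1 - p2)], dtype=float
    )
    f = np.clip(f, 1e-12, None)
    f /= f.sum()

    def loglik(f: np.ndarray) -> float:
        fAB, fAb, faB, fab = f
        probs = np.array(
            [
                [fab**2, 2 * fab * faB, faB**2],
                [2 * fab * fAb, 2 * (fAB * fab + fAb * faB), 2 * faB * fAB],
                [fAb**2, 2 * fAb * fAB, fAB**2],
            ]
        )
        with np.errstate(divide="ignore"):
            lp = np.log(probs, out=np.full_like(probs, -np.inf), where=probs > 0)
        mask = counts > 0
        return float((counts[mask] * lp[mask]).sum())

    prev = loglik(f)
    converged = False
    for _ in range(max_iter):
        fAB, fAb, faB, fab = f
        # expected haplotype counts; only the double heterozygote is ambiguous
        denom = fAB * fab + fAb * faB
        w = fAB * fab / denom if denom > 0 else 0.5
        nAB = 2 * counts[2, 2] + counts[2, 1] + counts[1, 2] + counts[1, 1] * w
        nAb = 2 * counts[2, 0] + counts[2, 1] + counts[1, 0] + counts[1, 1] * (1 - w)
        naB = 2 * counts[0, 2] + counts[0, 1] + counts[1, 2] + counts[1, 1] * (1 - w)
        nab = 2 * counts[0, 0] + counts[0, 1] + counts[1, 0] + counts[1, 1] * w
        f = np.array([nAB, nAb, naB, nab]) / (2 * n_total)
        cur = loglik(f)
        if abs(cur - prev) < tol:
            converged = True
            break
        prev = cur
    return f, converged


def r2_pair(
    data: GenotypeDataset, breed: str, locus_a: str, locus_b: str
) -> LdResult:
    """Squared allelic correlation between two loci within one breed.

    Haplotype frequencies are estimated from unphased genotypes by EM;
    r^2 = D^2 / (p(1-p) q(1-q)).  Monomorphic loci (or no jointly observed
    genotypes) yield a NaN sentinel.
    """
    idx = data.sample_indices(breed)
    ga = data.calls[idx, data.locus_index(locus_a)]
    gb = data.calls[idx, data.locus_index(locus_b)]
    both = (ga != MISSING) & (gb != MISSING)
    ga, gb = ga[both], gb[both]
    if ga.size == 0:
        return LdResult(locus_a, locus_b, breed, float("nan"))
    counts = np.zeros((3, 3))
    np.add.at(counts, (ga, gb), 1)
    p1 = ga.mean() / 2.0
    p2 = gb.mean() / 2.0
    if p1 in (0.0, 1.0) or p2 in (0.0, 1.0):
        return LdResult(locus_a, locus_b, breed, float("nan"))
    f, converged = _em_haplotype_freqs(counts)
    pA = f[0] + f[1]
    pB = f[0] + f[2]
    denom = pA * (1 - pA) * pB * (1 - pB)
    if denom <= 0:
        return LdResult(locus_a, locus_b, breed, float("nan"), converged)
    d_coef = f[0] - pA * pB
    return LdResult(locus_a, locus_b, breed, float(d_coef**2 / denom), converged)
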