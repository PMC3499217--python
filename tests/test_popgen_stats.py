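import itertools

import numpy as np
import pytest

from breedauth.errors import ValidationError
from breedauth.genotype_io import MISSING
from breedauth.popgen_stats import (
    PairwiseStatMatrix,
    bootstrap_support,
    fst_matrix,
    nj_tree,
    r2_pair,
    reynolds_distance,
    reynolds_matrix,
    wc_fst,
)
from breedauth.synthetic_data import ClosePair, SimScenario, simulate_dataset

from conftest import make_dataset
from oracles import enumerate_tree_bipartitions, tree_distances, wc_theta


# ---------------------------------------------------------------------------
# Weir & Cockerham theta
# ---------------------------------------------------------------------------


def test_fixed_difference_theta_is_one():
    data = make_dataset([[2]] * 5 + [[0]] * 5, ["A"] * 5 + ["B"] * 5)
    assert wc_fst(data, "A", "B") == pytest.approx(1.0)


def test_null_split_theta_near_zero(rng):
    p = rng.uniform(0.1, 0.9, size=2000)
    calls = rng.binomial(2, p, size=(200, 2000)).astype(np.int8)
    data = make_dataset(calls, ["A"] * 100 + ["B"] * 100)
    assert abs(wc_fst(data, "A", "B")) < 0.02


def test_theta_matches_scalar_oracle_small_grid():
    """Exhaustive one-locus instances with n <= 5 per population against the
    independently coded variance-component oracle."""
    def genotype_lists(n):
        for n0 in range(n + 1):
            for n1 in range(n + 1 - n0):
                yield [0] * n0 + [1] * n1 + [2] * (n - n0 - n1)

    for na in (2, 3, 5):
        for nb in (2, 4):
            for ga in genotype_lists(na):
                for gb in genotype_lists(nb):
                    expected = wc_theta([ga, gb])
                    if not np.isfinite(expected):
                        continue
                    calls = [[g] for g in ga] + [[g] for g in gb]
                    data = make_dataset(calls, ["A"] * na + ["B"] * nb)
                    got = wc_fst(data, "A", "B")
                    assert got == pytest.approx(expected, abs=1e-12), (ga, gb)


def test_theta_multilocus_is_ratio_of_sums(rng):
    calls = rng.integers(0, 3, size=(12, 4)).astype(np.int8)
    data = make_dataset(calls, ["A"] * 6 + ["B"] * 6)
    from oracles import wc_theta_components

    num = den = 0.0
    for j in range(4):
        ga = list(calls[:6, j])
        gb = list(calls[6:, j])
        a, b, c = wc_theta_components([ga, gb])
        num += a
        den += a + b + c
    assert wc_fst(data, "A", "B") == pytest.approx(num / den, abs=1e-12)


def test_theta_handles_missing_data():
    calls = [[2], [2], [MISSING], [0], [0], [MISSING]]
    data = make_dataset(calls, ["A"] * 3 + ["B"] * 3)
    # equivalent to a clean fixed-difference design with n=2 per pop
    clean = make_dataset([[2], [2], [0], [0]], ["A"] * 2 + ["B"] * 2)
    assert wc_fst(data, "A", "B") == pytest.approx(wc_fst(clean, "A", "B"))


def test_theta_requires_two_samples():
    data = make_dataset([[0], [2]], ["A", "B"])
    with pytest.raises(ValidationError):
        wc_fst(data, "A", "B")


def test_monomorphic_only_is_nan():
    data = make_dataset([[0]] * 4, ["A"] * 2 + ["B"] * 2)
    assert np.isnan(wc_fst(data, "A", "B"))


def test_fst_matrix_structure(rng):
    calls = rng.integers(0, 3, size=(12, 30)).astype(np.int8)
    data = make_dataset(calls, ["A"] * 4 + ["B"] * 4 + ["C"] * 4)
    m = fst_matrix(data)
    assert np.allclose(m.values, m.values.T)
    assert np.all(np.diag(m.values) == 0)
    means = m.breed_means()
    assert list(means.index) == ["A", "B", "C"]


def test_identical_populations_matrix_near_zero(rng):
    p = rng.uniform(0.2, 0.8, size=500)
    calls = rng.binomial(2, p, size=(90, 500)).astype(np.int8)
    data = make_dataset(calls, ["A"] * 30 + ["B"] * 30 + ["C"] * 30)
    m = fst_matrix(data)
    off = m.values[np.triu_indices(3, 1)]
    assert np.all(np.abs(off) < 0.02)


def test_realized_theta_monotone_in_f():
    thetas = []
    for k, f in enumerate([0.05, 0.2, 0.4, 0.6]):
        sc = SimScenario(
            n_breeds=2,
            samples_per_breed=(60, 60),
            n_loci=2000,
            breed_F=(f, f),
            seed=300 + k,
        )
        data, _ = simulate_dataset(sc)
        thetas.append(wc_fst(data, "BR01", "BR02"))
    assert thetas == sorted(thetas)


# ---------------------------------------------------------------------------
# Reynolds distance
# ---------------------------------------------------------------------------


def test_reynolds_identical_zero():
    f = np.array([0.2, 0.5, 0.9])
    assert reynolds_distance(f, f) == pytest.approx(0.0)


def test_reynolds_opposite_fixed_is_one():
    f1 = np.array([1.0, 1.0, 1.0])
    f2 = np.array([0.0, 0.0, 0.0])
    assert reynolds_distance(f1, f2) == pytest.approx(1.0)


def test_reynolds_locus_aggregation_closed_form():
    f1 = np.array([0.8, 0.1])
    f2 = np.array([0.3, 0.6])
    num = sum((a - b) ** 2 for a, b in zip(f1, f2))
    den = sum(1 - (a * b + (1 - a) * (1 - b)) for a, b in zip(f1, f2))
    assert reynolds_distance(f1, f2) == pytest.approx(num / den, abs=1e-12)


def test_reynolds_matrix_symmetric(rng):
    calls = rng.integers(0, 3, size=(12, 20)).astype(np.int8)
    data = make_dataset(calls, ["A"] * 4 + ["B"] * 4 + ["C"] * 4)
    m = reynolds_matrix(data)
    assert np.allclose(m.values, m.values.T)
    assert m.value("A", "B") == m.value("B", "A")


# ---------------------------------------------------------------------------
# neighbour joining
# ---------------------------------------------------------------------------


def _matrix(names, dist):
    n = len(names)
    m = np.zeros((n, n))
    for (a, b), v in dist.items():
        i, j = names.index(a), names.index(b)
        m[i, j] = m[j, i] = v
    return PairwiseStatMatrix(names, m, "reynolds")


def test_nj_three_taxon_closed_form():
    names = ["A", "B", "C"]
    dist = {("A", "B"): 3.0, ("A", "C"): 4.0, ("B", "C"): 5.0}
    tree = nj_tree(_matrix(names, dist))
    for (a, b), v in dist.items():
        assert tree.path_length(a, b) == pytest.approx(v, abs=1e-9)


def test_nj_recovers_additive_four_taxon_tree():
    adj = {
        "A": [("_x", 1.0)],
        "B": [("_x", 2.0)],
        "C": [("_y", 3.0)],
        "D": [("_y", 1.5)],
        "_x": [("A", 1.0), ("B", 2.0), ("_y", 0.7)],
        "_y": [("C", 3.0), ("D", 1.5), ("_x", 0.7)],
    }
    dist = tree_distances(adj)
    names = ["A", "B", "C", "D"]
    tree = nj_tree(_matrix(names, dist))
    # topology matches the brute-force quartet-enumeration oracle
    assert tree.bipartitions() == enumerate_tree_bipartitions(dist, names)
    # additive matrix is reproduced exactly by path lengths
    for (a, b), v in dist.items():
        assert tree.path_length(a, b) == pytest.approx(v, abs=1e-9)


def test_nj_recovers_additive_five_taxon_tree():
    adj = {
        "A": [("_x", 0.4)],
        "B": [("_x", 1.1)],
        "C": [("_y", 0.9)],
        "D": [("_z", 1.3)],
        "E": [("_z", 0.6)],
        "_x": [("A", 0.4), ("B", 1.1), ("_y", 0.5)],
        "_y": [("C", 0.9), ("_x", 0.5), ("_z", 0.8)],
        "_z": [("D", 1.3), ("E", 0.6), ("_y", 0.8)],
    }
    dist = tree_distances(adj)
    names = ["A", "B", "C", "D", "E"]
    tree = nj_tree(_matrix(names, dist))
    assert tree.bipartitions() == enumerate_tree_bipartitions(dist, names)
    for (a, b), v in dist.items():
        assert tree.path_length(a, b) == pytest.approx(v, abs=1e-9)


def test_nj_equidistant_tie_break_deterministic():
    names = ["A", "B", "C", "D"]
    dist = {pair: 1.0 for pair in itertools.combinations(names, 2)}
    t1 = nj_tree(_matrix(names, dist))
    t2 = nj_tree(_matrix(names, dist))
    assert t1.newick() == t2.newick()


def test_nj_negative_branch_clamped():
    names = ["A", "B", "C", "D"]
    # strongly non-additive matrix provokes a negative NJ branch
    dist = {
        ("A", "B"): 0.1,
        ("A", "C"): 1.0,
        ("A", "D"): 1.0,
        ("B", "C"): 1.0,
        ("B", "D"): 1.0,
        ("C", "D"): 0.05,
    }
    tree = nj_tree(_matrix(names, dist))
    lengths = [w for u in tree.adj for w in tree.adj[u].values()]
    assert min(lengths) >= 0.0


def test_nj_rejects_nonfinite():
    names = ["A", "B", "C"]
    m = np.zeros((3, 3))
    m[0, 1] = m[1, 0] = np.nan
    with pytest.raises(ValidationError):
        nj_tree(PairwiseStatMatrix(names, m, "reynolds"))


def test_newick_parses_with_dendropy():
    import dendropy

    names = ["A", "B", "C", "D", "E"]
    rng = np.random.default_rng(5)
    m = rng.uniform(0.5, 1.5, (5, 5))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0)
    tree = nj_tree(PairwiseStatMatrix(names, m, "reynolds"))
    parsed = dendropy.Tree.get(data=tree.newick(), schema="newick")
    assert {l.taxon.label for l in parsed.leaf_node_iter()} == set(names)


# ---------------------------------------------------------------------------
# bootstrap support
# ---------------------------------------------------------------------------


def _clade_scenario(seed=42):
    return SimScenario(
        n_breeds=5,
        samples_per_breed=(30,) * 5,
        n_loci=600,
        breed_F=(0.5, 0.5, 0.5, 0.5, 0.5),
        close_pairs=(ClosePair("BR01", "BR02", f_shared=0.45, f_pair=0.05),),
        seed=seed,
    )


def test_clean_clade_gets_high_support():
    data, _ = simulate_dataset(_clade_scenario())
    tree = bootstrap_support(data, n_reps=200, seed=1)
    key = frozenset(data.breed_names()) - frozenset({"BR01", "BR02"})
    # canonical side excludes the first leaf name BR01
    assert tree.support[key] >= 95.0


def test_bootstrap_deterministic_under_seed():
    data, _ = simulate_dataset(_clade_scenario())
    t1 = bootstrap_support(data, n_reps=50, seed=9)
    t2 = bootstrap_support(data, n_reps=50, seed=9)
    assert t1.support == t2.support
    assert t1.newick() == t2.newick()


def test_star_radiation_low_support():
    sc = SimScenario(
        n_breeds=6,
        samples_per_breed=(25,) * 6,
        n_loci=400,
        breed_F=(0.3,) * 6,
        seed=77,
    )
    data, _ = simulate_dataset(sc)
    tree = bootstrap_support(data, n_reps=100, seed=2)
    # a simultaneous radiation yields mostly weak internal support
    assert np.median(list(tree.support.values())) < 50.0


def test_supports_are_percentages():
    data, _ = simulate_dataset(_clade_scenario(7))
    tree = bootstrap_support(data, n_reps=30, seed=3)
    assert all(0.0 <= v <= 100.0 for v in tree.support.values())


def test_bootstrap_invalid_reps():
    data, _ = simulate_dataset(_clade_scenario())
    with pytest.raises(ValidationError):
        bootstrap_support(data, n_reps=0, seed=1)


# ---------------------------------------------------------------------------
# r^2 linkage disequilibrium
# ---------------------------------------------------------------------------


def test_duplicated_locus_r2_one(rng):
    g = rng.binomial(2, 0.4, size=50).astype(np.int8)
    data = make_dataset(np.column_stack([g, g]), ["A"] * 50)
    res = r2_pair(data, "A", "L001", "L002")
    assert res.r_squared == pytest.approx(1.0, abs=1e-9)
    assert res.em_converged


def test_monomorphic_locus_undefined():
    data = make_dataset([[0, 1], [0, 1], [0, 0], [0, 2]], ["A"] * 4)
    res = r2_pair(data, "A", "L001", "L002")
    assert not res.defined


def test_phase_unambiguous_table_matches_closed_form():
    """Without double heterozygotes every haplotype is observable, so EM
    must match the closed-form r^2 on phased counts to 1e-10."""
    # genotype pairs built from explicit haplotypes: AB/AB, AB/ab, Ab/aB
    # avoided; use (2,2), (2,0), (0,2), (0,0), (1,0), ...
    pairs = [(2, 2)] * 10 + [(0, 0)] * 12 + [(2, 0)] * 5 + [(1, 0)] * 3
    calls = np.array(pairs, dtype=np.int8)
    data = make_dataset(calls, ["A"] * len(pairs))
    # phased haplotype counts
    hap = {"AB": 0, "Ab": 0, "aB": 0, "ab": 0}
    for g1, g2 in pairs:
        assert not (g1 == 1 and g2 == 1)
        for copy in range(2):
            a1 = "A" if (g1 == 2 or (g1 == 1 and copy == 0)) else "a"
            a2 = "B" if (g2 == 2 or (g2 == 1 and copy == 0)) else "b"
            hap[("A" if a1 == "A" else "a") + ("B" if a2 == "B" else "b")] += 1
    total = sum(hap.values())
    fAB = hap["AB"] / total
    pA = (hap["AB"] + hap["Ab"]) / total
    pB = (hap["AB"] + hap["aB"]) / total
    d = fAB - pA * pB
    expected = d * d / (pA * (1 - pA) * pB * (1 - pB))
    res = r2_pair(data, "A", "L001", "L002")
    assert res.r_squared == pytest.approx(expected, abs=1e-10)


def test_r2_invariant_under_allele_relabelling(rng):
    g1 = rng.binomial(2, 0.4, size=80).astype(np.int8)
    g2 = np.clip(g1 + rng.integers(-1, 2, size=80), 0, 2).astype(np.int8)
    data = make_dataset(np.column_stack([g1, g2]), ["A"] * 80)
    flipped = make_dataset(np.column_stack([2 - g1, g2]), ["A"] * 80)
    r1 = r2_pair(data, "A", "L001", "L002")
    r2 = r2_pair(flipped, "A", "L001", "L002")
    assert r1.r_squared == pytest.approx(r2.r_squared, abs=1e-9)
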