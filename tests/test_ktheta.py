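"""K/theta arithmetic, special rules, and tree-guided delimitation."""

import math

import dendropy
import numpy as np
import pytest

from otudelim.ktheta import k_theta, ktheta_delimit
from otudelim.simulate import SimulationConfig, simulate_dataset
from otudelim.distances import k2p_matrix
from otudelim.nj import midpoint_root

from conftest import make_matrix


def pair_matrix(theta_a, theta_b, K, na=3, nb=3):
    """Constant within/between distances for exact ratio arithmetic."""
    ids = [f"a{i}" for i in range(na)] + [f"b{i}" for i in range(nb)]
    n = na + nb
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if i < na and j < na:
                d[i, j] = d[j, i] = theta_a
            elif i >= na and j >= na:
                d[i, j] = d[j, i] = theta_b
            else:
                d[i, j] = d[j, i] = K
    return make_matrix(d, ids=ids), ids[:na], ids[na:]


def test_ratio_distinct():
    m, a, b = pair_matrix(0.01, 0.02, 0.10)
    r = k_theta(m, a, b)
    assert r.theta_a == pytest.approx(0.01) and r.theta_b == pytest.approx(0.02)
    assert r.ratio == pytest.approx(5.0) and r.distinct and r.rule_applied == "ratio"


def test_ratio_not_distinct():
    m, a, b = pair_matrix(0.01, 0.02, 0.05)
    r = k_theta(m, a, b)
    assert r.ratio == pytest.approx(2.5) and not r.distinct


def test_shared_haplotype_zero_K():
    m, a, b = pair_matrix(0.01, 0.02, 0.0)
    r = k_theta(m, a, b)
    assert r.ratio == 0.0 and not r.distinct


def test_theta_rules_reported():
    m, a, b = pair_matrix(0.01, 0.02, 0.10)
    r = k_theta(m, a, b)
    assert r.ratio_max == pytest.approx(0.10 / 0.02)
    assert r.ratio_min == pytest.approx(0.10 / 0.01)
    pooled = (3 * 0.01 + 3 * 0.02) / 6
    assert r.ratio_pooled == pytest.approx(0.10 / pooled)
    assert k_theta(m, a, b, theta_rule="min").ratio == pytest.approx(10.0)


def test_theta_zero_rule():
    m, a, b = pair_matrix(0.0, 0.0, 0.05)
    r = k_theta(m, a, b)
    assert r.rule_applied == "theta_zero" and r.distinct
    m0, a0, b0 = pair_matrix(0.0, 0.0, 0.0)
    r0 = k_theta(m0, a0, b0)
    assert r0.rule_applied == "theta_zero" and not r0.distinct


def test_singleton_rules():
    m, a, b = pair_matrix(0.01, 0.02, 0.10, na=1, nb=3)
    r = k_theta(m, a, b)
    assert r.theta_a is None and r.rule_applied == "singleton"
    assert r.distinct  # 0.10 / 0.02 = 5 >= 4 against the sister theta
    m2, a2, b2 = pair_matrix(0.0, 0.0, 0.003, na=1, nb=1)
    r2 = k_theta(m2, a2, b2)
    assert r2.rule_applied == "singleton" and r2.distinct is None


def test_overlap_and_empty_rejected():
    m, a, b = pair_matrix(0.01, 0.02, 0.10)
    with pytest.raises(ValueError, match="overlap"):
        k_theta(m, a, a)
    with pytest.raises(ValueError, match="nonempty"):
        k_theta(m, a, [])


def test_distinct_monotone_in_K():
    last = False
    for K in np.linspace(0.0, 0.2, 21):
        m, a, b = pair_matrix(0.01, 0.02, float(K))
        r = k_theta(m, a, b)
        assert not (last and not r.distinct)  # never flips back to not-distinct
        last = bool(r.distinct)


@pytest.mark.parametrize("seed", range(10))
def test_verdict_matches_bruteforce(seed):
    """theta and K recomputed from raw pairs agree with the result."""
    rng = np.random.default_rng(seed)
    n = 8
    d = rng.uniform(0, 0.2, size=(n, n))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0)
    m = make_matrix(d)
    a, b = m.ids[:4], m.ids[4:]
    r = k_theta(m, a, b)
    ia, ib = [m.index(s) for s in a], [m.index(s) for s in b]
    theta_a = np.mean([d[x, y] for i, x in enumerate(ia) for y in ia[i + 1:]])
    theta_b = np.mean([d[x, y] for i, x in enumerate(ib) for y in ib[i + 1:]])
    K = min(d[x, y] for x in ia for y in ib)
    assert r.theta_a == pytest.approx(theta_a)
    assert r.theta_b == pytest.approx(theta_b)
    assert r.K == pytest.approx(K)
    assert r.distinct == (K / max(theta_a, theta_b) >= 4.0)


def rooted(nwk):
    t = dendropy.Tree.get(data=nwk, schema="newick", preserve_underscores=True)
    t.is_rooted = True
    return t


def test_delimit_two_clades():
    ok = 0
    for seed in range(10):
        cfg = SimulationConfig(n_species=2, samples_per_species=5, seq_length=650,
                               theta_within=0.005, d_between=0.10, seed=seed)
        aln, truth = simulate_dataset(cfg)
        m = k2p_matrix(aln).apply_saturation_policy()
        part = ktheta_delimit(truth.true_tree, m)
        ok += part.n_otus == 2
    assert ok >= 9


def test_delimit_single_species_star():
    ok = 0
    for seed in range(10):
        cfg = SimulationConfig(n_species=2, samples_per_species=6, seq_length=2000,
                               theta_within=0.01, d_between=0.10, seed=100 + seed)
        aln, truth = simulate_dataset(cfg)
        keep = [s for s in aln.ids if s.startswith("sp01")]
        sub = aln.subset(keep)
        m = k2p_matrix(sub)
        tree = truth.true_tree.extract_tree_with_taxa_labels(keep)
        tree.is_rooted = True
        part = ktheta_delimit(tree, m)
        ok += part.n_otus == 1
    assert ok >= 9


def test_delimit_theta_zero_clade_split():
    # clade of identical samples sister to a diverse clade, K at species scale
    ids = ["z1", "z2", "z3", "v1", "v2", "v3"]
    d = np.zeros((6, 6))
    for i in range(3, 6):
        for j in range(i + 1, 6):
            d[i, j] = d[j, i] = 0.01
    for i in range(3):
        for j in range(3, 6):
            d[i, j] = d[j, i] = 0.08
    m = make_matrix(d, ids=ids)
    tree = rooted("((z1:0,z2:0,z3:0):0.04,(v1:0.005,v2:0.005,v3:0.005):0.04);")
    part = ktheta_delimit(tree, m)
    groups = {frozenset(g) for g in part.groups().values()}
    assert groups == {frozenset({"z1", "z2", "z3"}), frozenset({"v1", "v2", "v3"})}


def test_delimit_all_equal_distances_one_otu():
    d = np.full((6, 6), 0.01)
    np.fill_diagonal(d, 0)
    ids = [f"t{i}" for i in range(6)]
    m = make_matrix(d, ids=ids)
    tree = rooted("((t0:1,t1:1):1,((t2:1,t3:1):1,(t4:1,t5:1):1):1);")
    assert ktheta_delimit(tree, m).n_otus == 1


def test_leaf_mismatch_error():
    d = np.zeros((3, 3))
    m = make_matrix(d, ids=["a", "b", "c"])
    tree = rooted("((a:1,b:1):1,x:1);")
    with pytest.raises(ValueError, match="mismatch"):
        ktheta_delimit(tree, m)
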