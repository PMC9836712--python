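"""Neighbor-joining correctness and bootstrap behaviour."""

import numpy as np
import pytest

from otudelim.distances import k2p_matrix
from otudelim.model import BarcodeAlignment, SequenceRecord
from otudelim.nj import (
    BootstrapConfig, _nj_core, bootstrap_support, nj, tree_splits,
)
from otudelim.simulate import SimulationConfig, simulate_dataset

from conftest import make_matrix, random_additive_matrix


def branch_lengths(tree):
    return {
        lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()
    }


def test_three_taxon_lengths():
    d = np.array([[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]])
    tree = nj(make_matrix(d, ids=["A", "B", "C"]))
    bl = branch_lengths(tree)
    assert bl["A"] == pytest.approx(0.05)
    assert bl["B"] == pytest.approx(0.15)
    assert bl["C"] == pytest.approx(0.25)


def test_four_taxon_additive():
    ids = ["A", "B", "C", "D"]
    d = np.array([[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float)
    core = _nj_core(d, ids)
    assert core.splits() == {frozenset({"C", "D"})}  # the AB|CD split
    # internal edge length 1, all path distances reproduced exactly
    internal = [
        bl for node, kids in core.children.items() if node != core.center
        for _, bl in kids
    ]
    tree = nj(make_matrix(d, ids=ids))
    pdm = tree.phylogenetic_distance_matrix()
    tax = {t.label: t for t in tree.taxon_namespace}
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            if i < j:
                assert pdm.patristic_distance(tax[a], tax[b]) == pytest.approx(d[i, j])
    # the AB ancestor hangs off the center with the internal edge
    center_lengths = sorted(bl for _, bl in core.children[core.center])
    assert 1.0 in [pytest.approx(v) for v in center_lengths] or any(
        abs(v - 1.0) < 1e-12 for v in center_lengths
    )


@pytest.mark.parametrize("seed", range(20))
def test_additive_consistency(seed):
    """NJ recovers the generating topology exactly on additive matrices."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 13))
    d, ids, want = random_additive_matrix(rng, n)
    core = _nj_core(d, ids)
    assert core.splits() == want


def test_matches_scikit_bio():
    """Cross-check topology against scikit-bio's independent NJ."""
    import io
    from skbio import DistanceMatrix as SkbioDM
    from skbio.tree import nj as skbio_nj
    import dendropy

    rng = np.random.default_rng(3)
    d, ids, _ = random_additive_matrix(rng, 8)
    noise = rng.uniform(0, 0.05, size=d.shape)
    noise = (noise + noise.T) / 2
    np.fill_diagonal(noise, 0)
    d = d + noise
    ours = nj(make_matrix(d, ids=ids))
    theirs_nwk = skbio_nj(SkbioDM(d, ids)).write(io.StringIO()).getvalue()
    theirs = dendropy.Tree.get(data=theirs_nwk, schema="newick")
    theirs.is_rooted = False
    assert tree_splits(ours) == tree_splits(theirs)


def test_total_length_invariant_to_order():
    rng = np.random.default_rng(5)
    d, ids, _ = random_additive_matrix(rng, 7)
    ref = None
    for _ in range(20):
        perm = rng.permutation(len(ids))
        m = make_matrix(d[np.ix_(perm, perm)], ids=[ids[k] for k in perm])
        total = sum(
            e.length for e in nj(m).preorder_edge_iter() if e.length is not None
        )
        if ref is None:
            ref = total
        assert total == pytest.approx(ref, abs=1e-9)


def test_undefined_entries_rejected():
    d = np.zeros((3, 3))
    defined = np.ones((3, 3), bool)
    defined[0, 1] = defined[1, 0] = False
    with pytest.raises(ValueError, match="saturation_policy"):
        nj(make_matrix(d, defined=defined))


def test_negative_branches_clamped():
    # star-ish matrix that produces a negative NJ estimate
    d = np.array([
        [0, 0.1, 0.1, 0.3],
        [0.1, 0, 0.1, 0.3],
        [0.1, 0.1, 0, 0.3],
        [0.3, 0.3, 0.3, 0],
    ])
    tree = nj(make_matrix(d))
    for e in tree.preorder_edge_iter():
        assert e.length is None or e.length >= 0


def make_aln(seqs):
    return BarcodeAlignment([SequenceRecord(f"s{i}", s) for i, s in enumerate(seqs)])


def column_type_alignment():
    """Only two informative column types -> every replicate has the same
    topology, so both nontrivial splits get 100% support."""
    cols = []
    cols += [("G", "G", "A", "A", "A")] * 15  # supports {s0,s1}
    cols += [("A", "A", "A", "G", "G")] * 15  # supports {s3,s4}
    cols += [("A",) * 5] * 70
    seqs = ["".join(c[i] for c in cols) for i in range(5)]
    return make_aln(seqs)


def test_bootstrap_invariant_topology_full_support():
    tree = bootstrap_support(column_type_alignment(),
                             BootstrapConfig(replicates=20, seed=0))
    labels = [
        nd.label for nd in tree.preorder_node_iter()
        if not nd.is_leaf() and nd.label is not None
    ]
    assert labels and all(float(l) == 100 for l in labels)


def test_bootstrap_single_replicate_degenerate():
    tree = bootstrap_support(column_type_alignment(),
                             BootstrapConfig(replicates=1, seed=1))
    for nd in tree.preorder_node_iter():
        if not nd.is_leaf() and nd.label is not None:
            assert float(nd.label) in (0.0, 100.0)


def test_bootstrap_reproducible_and_cluster_support():
    cfg = SimulationConfig(n_species=2, samples_per_species=5, seq_length=500,
                           theta_within=0.004, d_between=0.10, seed=9)
    aln, _ = simulate_dataset(cfg)
    t1 = bootstrap_support(aln, BootstrapConfig(replicates=100, seed=4))
    t2 = bootstrap_support(aln, BootstrapConfig(replicates=100, seed=4))
    assert t1.as_string(schema="newick") == t2.as_string(schema="newick")
    # the two 5-sample clusters are a bipartition with near-total support
    supports = {}
    leaves = sorted(lf.taxon.label for lf in t1.leaf_node_iter())
    cluster = frozenset(l for l in leaves if l.startswith("sp02"))
    for nd in t1.preorder_node_iter():
        if nd.is_leaf() or nd.label is None:
            continue
        ls = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        supports[ls] = float(nd.label)
        supports[frozenset(leaves) - ls] = float(nd.label)
    assert supports.get(cluster, 0.0) >= 95.0
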