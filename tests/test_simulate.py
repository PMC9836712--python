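"""Simulator contracts: determinism, parameter recovery, planted structure."""

import math

import dendropy
import numpy as np
import pytest

from otudelim.distances import k2p_matrix, k2p_pair, group_distance_summary
from otudelim.simulate import (
    SimulationConfig, emit_dataset, evolve_sequences, mackerel_like,
    simulate_dataset,
)
from otudelim.stats import sequence_summary


def test_seed_mandatory():
    cfg = SimulationConfig(n_species=3, seed=None)
    with pytest.raises(ValueError, match="seed"):
        simulate_dataset(cfg)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        SimulationConfig(theta_within=0.2, d_between=0.1, seed=1)
    with pytest.raises(ValueError):
        SimulationConfig(base_freqs=(0.5, 0.5, 0.5, 0.5), seed=1)
    with pytest.raises(ValueError):
        SimulationConfig(cryptic=(("nope", 2, 0.04),), seed=1)
    with pytest.raises(ValueError):
        SimulationConfig(n_species=1, seed=1)


def test_same_seed_identical_bytes(tmp_path):
    cfg = SimulationConfig(n_species=3, samples_per_species=4, seq_length=300, seed=7)
    for k in (1, 2):
        aln, truth = simulate_dataset(cfg)
        emit_dataset(aln, truth, tmp_path / f"run{k}", cfg)
    for name in ("alignment.fasta", "metadata.tsv", "true_partition.tsv",
                 "label_partition.tsv", "true_tree.nwk", "config.yaml"):
        assert (tmp_path / "run1" / name).read_bytes() == \
            (tmp_path / "run2" / name).read_bytes()


def test_truth_partitions_consistent():
    cfg = SimulationConfig(n_species=4, samples_per_species=5,
                           cryptic=(("sp02", 2, 0.05),), seed=3)
    aln, truth = simulate_dataset(cfg)
    assert truth.true_partition.samples == set(aln.ids)
    assert truth.label_partition.samples == set(aln.ids)
    # cryptic lineages refine the label partition: same label, >=2 lineages
    assert truth.true_partition.n_otus == 5
    assert truth.label_partition.n_otus == 4
    # true partition refines labels (no mislabeling configured)
    label_of = aln.labels
    for grp in truth.true_partition.groups().values():
        assert len({label_of[s] for s in grp}) == 1


def test_mislabeling_breaks_refinement():
    cfg = SimulationConfig(n_species=4, samples_per_species=5,
                           mislabel_rate=0.2, seed=3)
    aln, truth = simulate_dataset(cfg)
    label_of = aln.labels
    mixed = sum(
        len({label_of[s] for s in grp}) > 1
        for grp in truth.true_partition.groups().values()
    )
    assert mixed >= 1


def test_distance_structure_recovery():
    """Monte-Carlo check of configured within/between scales at large L."""
    within, between = [], []
    for seed in range(6):
        cfg = SimulationConfig(n_species=5, samples_per_species=6,
                               seq_length=10000, theta_within=0.005,
                               d_between=0.10, seed=seed)
        aln, _ = simulate_dataset(cfg)
        g = group_distance_summary(k2p_matrix(aln), aln.require_labels())
        within.append(g.overall_within_mean)
        between.append(g.overall_between_mean)
    assert np.mean(within) == pytest.approx(0.005, rel=0.20)
    # mean between is d_between plus the within-tip contribution (~theta)
    assert np.mean(between) == pytest.approx(0.105, rel=0.10)


def test_min_between_divergence_floor():
    cfg = SimulationConfig(n_species=6, samples_per_species=2, seq_length=650,
                           theta_within=0.0, d_between=0.10, seed=9)
    aln, truth = simulate_dataset(cfg)
    pdm = truth.true_tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in truth.true_tree.taxon_namespace}
    labels = aln.labels
    cross = [
        pdm.patristic_distance(taxa[a], taxa[b])
        for i, a in enumerate(aln.ids) for b in aln.ids[i + 1:]
        if labels[a] != labels[b]
    ]
    assert min(cross) >= 2 * 0.4 * 0.10 - 1e-9


def test_evolve_zero_length_tree():
    t = dendropy.Tree.get(data="(a:0.0,b:0.0);", schema="newick")
    t.is_rooted = True
    seqs = evolve_sequences(t, 500, kappa=3.0,
                            base_freqs=(0.25, 0.25, 0.25, 0.25), seed=1)
    assert seqs["a"] == seqs["b"]


def test_evolve_negative_branch_rejected():
    t = dendropy.Tree.get(data="(a:-0.1,b:0.1);", schema="newick")
    t.is_rooted = True
    with pytest.raises(ValueError, match="negative"):
        evolve_sequences(t, 100, 3.0, (0.25,) * 4, seed=1)


def test_evolve_pairwise_distance_unbiased():
    """Two leaves at path length 0.1: K2P estimate within binomial error."""
    t = dendropy.Tree.get(data="(a:0.05,b:0.05);", schema="newick")
    t.is_rooted = True
    seqs = evolve_sequences(t, 100_000, kappa=3.0,
                            base_freqs=(0.25, 0.25, 0.25, 0.25), seed=2)
    d = k2p_pair(seqs["a"], seqs["b"]).d
    assert d == pytest.approx(0.10, abs=0.005)


def test_evolve_kappa_raises_ts_tv():
    t = dendropy.Tree.get(data="(a:0.05,b:0.05);", schema="newick")
    t.is_rooted = True
    ratios = []
    for kappa in (1.0, 10.0):
        seqs = evolve_sequences(t, 50_000, kappa=kappa,
                                base_freqs=(0.25,) * 4, seed=5)
        r = k2p_pair(seqs["a"], seqs["b"])
        ratios.append(r.P / r.Q)
    assert ratios[1] > ratios[0]


def test_mackerel_like_shape():
    cfg = mackerel_like(2)
    aln, truth = simulate_dataset(cfg)
    assert len(aln) == 150
    assert truth.label_partition.n_otus == 14
    # 14 species + 3 extra cryptic lineages
    assert truth.true_partition.n_otus == 17
    cs = sequence_summary(aln)
    assert 2.0 < cs.ts_tv_ratio < 4.5
    assert 0.48 < cs.at_content < 0.56


def test_merged_pair_close():
    cfg = mackerel_like(4)
    aln, truth = simulate_dataset(cfg)
    m = k2p_matrix(aln)
    labels = aln.labels
    a_ids = [s for s in aln.ids if labels[s] == "sp04"]
    b_ids = [s for s in aln.ids if labels[s] == "sp05"]
    cross = [m.get(x, y) for x in a_ids for y in b_ids]
    assert np.mean(cross) < 0.03  # merged pair far below species scale
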