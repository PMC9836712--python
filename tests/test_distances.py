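"""K2P pair/matrix behaviour and grouped distance summaries."""

import math

import numpy as np
import pytest

from otudelim.distances import (
    DistanceMatrix, group_distance_summary, k2p_matrix, k2p_pair,
)
from otudelim.model import BarcodeAlignment, SequenceRecord

from conftest import make_matrix


def brute_k2p(seq1: str, seq2: str):
    """Site-by-site counting + direct formula, independent of the library path."""
    ts = tv = n = 0
    for a, b in zip(seq1.upper(), seq2.upper()):
        if a not in "ACGT" or b not in "ACGT":
            continue
        n += 1
        if a != b:
            if {a, b} in ({"A", "G"}, {"C", "T"}):
                ts += 1
            else:
                tv += 1
    if n == 0:
        return None
    P, Q = ts / n, tv / n
    w1, w2 = 1 - 2 * P - Q, 1 - 2 * Q
    if w1 <= 0 or w2 <= 0:
        return math.nan
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def test_identical_sequences():
    r = k2p_pair("A" * 100, "A" * 100)
    assert (r.d, r.P, r.Q) == (0.0, 0.0, 0.0)
    assert r.n_compared == 100 and r.defined


def test_closed_form_value():
    # 100 sites, 10 transitions, 5 transversions
    seq1 = "A" * 100
    seq2 = "G" * 10 + "C" * 5 + "A" * 85
    r = k2p_pair(seq1, seq2)
    expected = -0.5 * math.log(0.75) - 0.25 * math.log(0.90)
    assert r.d == pytest.approx(0.17018, abs=1e-5)
    assert r.d == pytest.approx(expected, abs=1e-12)


def test_saturation_flagged():
    seq1 = "A" * 100
    seq2 = "G" * 45 + "C" * 15 + "A" * 40  # P=0.45, Q=0.15 -> 1-2P-Q < 0
    r = k2p_pair(seq1, seq2)
    assert not r.defined and r.reason == "saturation"
    assert math.isnan(r.d)


def test_no_sites_and_floor():
    r = k2p_pair("NNNN", "ACGT")
    assert not r.defined and r.reason == "no_sites"
    r2 = k2p_pair("ACGT" * 10, "ACGT" * 10, min_sites=100)
    assert not r2.defined and r2.reason == "min_sites"


@pytest.mark.parametrize("seed", range(10))
def test_random_pairs_match_bruteforce(seed):
    rng = np.random.default_rng(seed)
    chars = np.array(list("ACGTN-"))
    for _ in range(100):
        L = int(rng.integers(50, 300))
        s1 = "".join(rng.choice(chars, L, p=[0.24, 0.24, 0.24, 0.24, 0.02, 0.02]))
        s2 = "".join(rng.choice(chars, L, p=[0.24, 0.24, 0.24, 0.24, 0.02, 0.02]))
        got = k2p_pair(s1, s2)
        want = brute_k2p(s1, s2)
        if want is None:
            assert not got.defined
        elif math.isnan(want):
            assert not got.defined
        else:
            assert got.d == pytest.approx(want, abs=1e-12)


def test_matrix_symmetry_and_diagonal(toy_alignment):
    m = k2p_matrix(toy_alignment)
    assert np.allclose(m.d, m.d.T, equal_nan=True)
    assert np.all(np.diag(m.d) == 0)
    iu = np.triu_indices(4, 1)
    ok = m.defined[iu]
    # defined distances dominate the raw mismatch proportion
    assert np.all(m.d[iu][ok] >= (m.P + m.Q)[iu][ok] - 1e-12)
    # the s2-s4 and s1-s4 comparisons (3 transitions in 6 sites) are saturated
    assert not m.is_defined("s2", "s4")
    assert not m.is_defined("s1", "s4")
    assert m.n_undefined_pairs == 2


def test_zero_matrix_for_identical():
    aln = BarcodeAlignment([SequenceRecord(f"s{i}", "ACGTAC") for i in range(3)])
    m = k2p_matrix(aln)
    assert np.all(m.d == 0) and np.all(m.defined)


def test_jc_limit_agreement():
    """With transition:transversion counts at the 1:2 neutral ratio, K2P is
    within 5% of the Jukes-Cantor distance for d <= 0.2."""
    for p in np.linspace(0.01, 0.17, 9):
        n = 3000
        ts = int(round(p * n / 3))
        tv = 2 * ts
        seq1 = "A" * n
        seq2 = "G" * ts + "C" * tv + "A" * (n - ts - tv)
        d_k2p = k2p_pair(seq1, seq2).d
        p_obs = (ts + tv) / n
        d_jc = -0.75 * math.log(1 - 4 * p_obs / 3)
        if d_jc <= 0.2:
            assert abs(d_k2p - d_jc) / d_jc < 0.05


def test_saturation_policies():
    d = np.array([[0, 0.1, np.nan], [0.1, 0, 0.2], [np.nan, 0.2, 0]])
    defined = ~np.isnan(d)
    m = make_matrix(np.nan_to_num(d), defined=defined)
    m.d[~defined] = np.nan
    with pytest.raises(ValueError):
        m.apply_saturation_policy("error")
    dropped = m.apply_saturation_policy("drop_pair")
    assert dropped.n_undefined_pairs == 0 and len(dropped) == 2
    capped = m.apply_saturation_policy("cap_at_max")
    assert len(capped) == 3 and capped.get("t0", "t2") == pytest.approx(0.2)


def test_group_summary_arithmetic():
    # two groups of 2: within {0.01}, {0.02}; between all 0.10
    d = np.array([
        [0, 0.01, 0.10, 0.10],
        [0.01, 0, 0.10, 0.10],
        [0.10, 0.10, 0, 0.02],
        [0.10, 0.10, 0.02, 0],
    ])
    m = make_matrix(d, ids=["a1", "a2", "b1", "b2"])
    g = group_distance_summary(m, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
    assert g.overall_within_mean == pytest.approx(0.015)
    assert g.overall_between_mean == pytest.approx(0.10)
    assert g.ratio == pytest.approx(0.10 / 0.015)
    assert list(g.within["mean"]) == pytest.approx([0.01, 0.02])


def test_single_group_no_between():
    d = np.array([[0, 0.01], [0.01, 0]])
    g = group_distance_summary(make_matrix(d), {"t0": "A", "t1": "A"})
    assert g.between.empty and math.isnan(g.overall_between_mean)


def test_singleton_group_and_undefined_excluded():
    d = np.array([[0, 0.5, 0.1], [0.5, 0, 0.1], [0.1, 0.1, 0]])
    defined = np.ones((3, 3), bool)
    defined[0, 1] = defined[1, 0] = False
    m = make_matrix(d, ids=["a1", "a2", "b1"], defined=defined)
    g = group_distance_summary(m, {"a1": "A", "a2": "A", "b1": "B"})
    assert g.n_undefined_excluded == 1
    a_row = g.within[g.within["group"] == "A"].iloc[0]
    assert a_row["n_pairs"] == 0 and math.isnan(a_row["mean"])


def test_ungrouped_sample_error():
    d = np.zeros((2, 2))
    with pytest.raises(ValueError, match="t1"):
        group_distance_summary(make_matrix(d), {"t0": "A"})


def test_within_mean_recovers_theta():
    """Grand mean within-species distance matches the configured theta."""
    from otudelim.simulate import SimulationConfig, simulate_dataset

    means = []
    for seed in range(8):
        cfg = SimulationConfig(n_species=4, samples_per_species=6, seq_length=4000,
                               theta_within=0.006, d_between=0.10, seed=seed)
        aln, _ = simulate_dataset(cfg)
        g = group_distance_summary(k2p_matrix(aln), aln.require_labels())
        means.append(g.overall_within_mean)
    assert np.mean(means) == pytest.approx(0.006, rel=0.20)
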