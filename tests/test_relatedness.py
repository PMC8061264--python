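import math

import numpy as np
import pandas as pd
import pytest

from perchmon.gmatrix import MISSING, GenotypeMatrix
from perchmon.relatedness import (
    assign_parent_pairs,
    cluster_full_sibs,
    estimate_allele_freqs,
    match_identities,
    pair_lod,
)


def _mat(rows, prefix="i"):
    rows = np.asarray(rows, dtype=np.int8)
    return GenotypeMatrix(
        ids=np.array([f"{prefix}{k}" for k in range(rows.shape[0])], dtype=object),
        loci=np.array([f"L{k}" for k in range(rows.shape[1])], dtype=object),
        dosage=rows,
    )


# ---------------------------------------------------------------------------
# trio LOD vs exhaustive enumeration oracle
# ---------------------------------------------------------------------------
def _lod_oracle(off, dam, sire, freqs, e):
    """Brute-force 3x3x3 genotype-error enumeration, plain Python."""

    def hwe(p):
        return [(1 - p) ** 2, 2 * p * (1 - p), p * p]

    def err(true, obs):
        return 1 - e if true == obs else e / 2

    def mendel(td, ts, to):
        pd_, ps_ = td / 2, ts / 2
        return [
            (1 - pd_) * (1 - ps_),
            pd_ * (1 - ps_) + (1 - pd_) * ps_,
            pd_ * ps_,
        ][to]

    total = 0.0
    for l in range(len(off)):
        if off[l] == MISSING:
            continue
        pri = hwe(freqs[l])
        num = 0.0
        for td in range(3):
            for ts in range(3):
                for to in range(3):
                    term = pri[td] * pri[ts] * mendel(td, ts, to) * err(to, off[l])
                    if dam[l] != MISSING:
                        term *= err(td, dam[l])
                    if sire[l] != MISSING:
                        term *= err(ts, sire[l])
                    num += term
            den_o = sum(pri[t] * err(t, off[l]) for t in range(3))
        den_d = (
            sum(pri[t] * err(t, dam[l]) for t in range(3))
            if dam[l] != MISSING else 1.0
        )
        den_s = (
            sum(pri[t] * err(t, sire[l]) for t in range(3))
            if sire[l] != MISSING else 1.0
        )
        total += math.log(num) - math.log(den_o) - math.log(den_d) - math.log(den_s)
    return total


def test_pair_lod_equals_enumeration_oracle():
    rng = np.random.default_rng(8)
    freqs = rng.uniform(0.1, 0.9, 20)
    for _ in range(5):
        off = rng.integers(0, 3, 20).astype(np.int8)
        dam = rng.integers(0, 3, 20).astype(np.int8)
        sire = rng.integers(0, 3, 20).astype(np.int8)
        off[rng.random(20) < 0.15] = MISSING
        dam[rng.random(20) < 0.15] = MISSING
        got = pair_lod(off, dam, sire, freqs, error_rate=1e-4)
        want = _lod_oracle(off, dam, sire, freqs, 1e-4)
        assert got == pytest.approx(want, rel=1e-10)


def test_forced_heterozygote_and_mendelian_table():
    """dam 0 x sire 2 makes offspring 1 near-certain; 1 x 1 gives (1/4,1/2,1/4)."""
    freqs = np.full(1, 0.5)
    lod_het = pair_lod(np.array([1]), np.array([0]), np.array([2]), freqs)
    lod_hom = pair_lod(np.array([0]), np.array([0]), np.array([2]), freqs)
    assert lod_het > 0 > lod_hom  # exclusion is an e-order event
    # dam 1 x sire 1: transmission = HWE at p=0.5 so the LOD term is ~0
    for g in (0, 1, 2):
        lod = pair_lod(np.array([g]), np.array([1]), np.array([1]), freqs)
        assert abs(lod) < 0.01


def test_lod_decreases_with_each_exclusion():
    freqs = np.full(30, 0.5)
    dam = np.zeros(30, dtype=np.int8)
    sire = np.zeros(30, dtype=np.int8)
    lods = []
    for n_bad in (0, 3, 6, 12):
        off = np.zeros(30, dtype=np.int8)
        off[:n_bad] = 2  # impossible for 0 x 0 parents
        lods.append(pair_lod(off, dam, sire, freqs, error_rate=1e-6))
    assert all(a > b for a, b in zip(lods, lods[1:]))


# ---------------------------------------------------------------------------
# assignment with simulated pedigree
# ---------------------------------------------------------------------------
def _simulate_families(rng, n_pairs, L, n_off_per_pair):
    p = rng.uniform(0.1, 0.9, L)
    parents = rng.binomial(2, p, size=(2 * n_pairs, L)).astype(np.int8)
    pm = _mat(parents, prefix="P")
    pairs = pd.DataFrame(
        [dict(pair_id=f"PR{k:02d}", dam_id=f"P{2 * k}", sire_id=f"P{2 * k + 1}")
         for k in range(n_pairs)]
    )
    off, truth = [], []
    for k in range(n_pairs):
        for _ in range(n_off_per_pair):
            gd, gs = parents[2 * k], parents[2 * k + 1]
            g = (rng.binomial(1, gd / 2) + rng.binomial(1, gs / 2)).astype(np.int8)
            off.append(g)
            truth.append(f"PR{k:02d}")
    return pm, pairs, _mat(np.array(off), prefix="o"), truth, p


def test_offspring_assigned_to_true_pair_among_fifty():
    rng = np.random.default_rng(21)
    pm, pairs, om, truth, p = _simulate_families(rng, 50, 600, 1)
    res = assign_parent_pairs(om, pairs, pm, estimate_allele_freqs(pm),
                              n_sim=1500, seed=2)
    assigned = res[res.status == "assigned"]
    assert (assigned.pair_id == [truth[i] for i in assigned.index]).all()
    assert len(assigned) >= 45
    assert (assigned.confidence > 0.95).all()


def test_unrelated_offspring_left_unassigned():
    rng = np.random.default_rng(22)
    pm, pairs, _, _, p = _simulate_families(rng, 20, 600, 1)
    stranger = _mat(rng.binomial(2, p, size=(3, 600)).astype(np.int8), prefix="u")
    res = assign_parent_pairs(stranger, pairs, pm, estimate_allele_freqs(pm),
                              n_sim=1000, seed=3)
    assert (res.pair_id.isna()).all()


# ---------------------------------------------------------------------------
# identity
# ---------------------------------------------------------------------------
def test_identical_rows_form_one_group():
    rng = np.random.default_rng(1)
    g = rng.integers(0, 3, size=(1, 200)).astype(np.int8)
    m = _mat(np.vstack([g, g, rng.integers(0, 3, size=(1, 200))]), prefix="s")
    groups, excluded = match_identities(m)
    assert set(groups.sample_id) == {"s0", "s1"}
    assert groups.group_id.nunique() == 1


def test_fifty_one_mismatches_do_not_merge():
    """At the 1120-locus identity panel, 51 mismatched loci break the match."""
    rng = np.random.default_rng(2)
    a = rng.integers(0, 3, size=1120).astype(np.int8)
    b = a.copy()
    flip = rng.choice(1120, size=51, replace=False)
    b[flip] = (a[flip] + 1) % 3
    groups, _ = match_identities(_mat(np.vstack([a, b]), prefix="s"))
    assert groups.empty


def test_planted_duplicate_with_half_percent_error_recovered():
    rng = np.random.default_rng(4)
    base = rng.integers(0, 3, size=(6, 1120)).astype(np.int8)
    dup = base[0].copy()
    flip = rng.random(1120) < 0.005
    dup[flip] = (dup[flip] + rng.integers(1, 3, int(flip.sum()))) % 3
    m = _mat(np.vstack([base, dup]), prefix="s")
    groups, _ = match_identities(m)
    assert set(groups.sample_id) == {"s0", "s6"}


def test_low_call_rate_samples_excluded():
    rng = np.random.default_rng(5)
    g = rng.integers(0, 3, size=(3, 100)).astype(np.int8)
    g[2, :60] = MISSING
    groups, excluded = match_identities(_mat(g, prefix="s"))
    assert list(excluded.sample_id) == ["s2"]


def test_recapture_vs_mislabel_classification():
    rng = np.random.default_rng(6)
    a = rng.integers(0, 3, size=300).astype(np.int8)
    b = rng.integers(0, 3, size=300).astype(np.int8)
    m = _mat(np.vstack([a, a, b, b]), prefix="s")
    meta = pd.DataFrame(
        dict(role=["monitoring", "monitoring", "monitoring", "broodstock"],
             capture_year=[2016, 2018, 2017, np.nan]),
        index=["s0", "s1", "s2", "s3"],
    )
    groups, _ = match_identities(m, metadata=meta)
    kinds = groups.groupby("group_id").kind.first()
    assert set(kinds) == {"recapture", "mislabel_suspect"}


# ---------------------------------------------------------------------------
# sibship
# ---------------------------------------------------------------------------
def test_simulated_families_partitioned_exactly():
    rng = np.random.default_rng(30)
    pm, pairs, om, truth, p = _simulate_families(rng, 10, 600, 4)
    part = cluster_full_sibs(om, estimate_allele_freqs(om), seed=9, n_cal=800)
    got = part.assignments.set_index("sample_id").group_id
    # same-family iff same-group, for every pair of offspring
    ids = list(om.ids)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            same_truth = truth[i] == truth[j]
            same_group = got[ids[i]] == got[ids[j]]
            assert same_truth == same_group
    conf = part.assignments.groupby("group_id").confidence.first()
    assert (conf > 0.98).all()


def test_unrelated_pair_not_merged_and_partition_exhaustive():
    rng = np.random.default_rng(31)
    p = rng.uniform(0.1, 0.9, 600)
    g = rng.binomial(2, p, size=(2, 600)).astype(np.int8)
    part = cluster_full_sibs(_mat(g), p, seed=1, n_cal=500)
    assert part.assignments.group_id.nunique() == 2
    assert set(part.assignments.sample_id) == {"i0", "i1"}
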