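import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from perchmon.gmatrix import MISSING
from perchmon.popgen_stats import mean_fst, per_locus_fst
from perchmon.relatedness import _exclusion_table
from perchmon.simdata import (
    SimConfig,
    largest_remainder,
    simulate_breeding_program,
    simulate_dataset,
    simulate_sources,
)

from conftest import small_config


# ---------------------------------------------------------------------------
# apportionment
# ---------------------------------------------------------------------------
def test_largest_remainder_hand_examples():
    np.testing.assert_array_equal(largest_remainder([500], 1000), [1000])
    np.testing.assert_array_equal(largest_remainder([100, 300], 1000), [250, 750])
    np.testing.assert_array_equal(largest_remainder([1, 1, 1], 100), [34, 33, 33])
    np.testing.assert_array_equal(largest_remainder([0, 5], 7), [0, 7])


@given(
    counts=st.lists(st.integers(0, 5000), min_size=1, max_size=12),
    total=st.integers(0, 50_000),
)
@settings(max_examples=200, deadline=None, derandomize=True)
def test_largest_remainder_conserves_and_bounds(counts, total):
    if sum(counts) == 0:
        if total > 0:
            with pytest.raises(ValueError):
                largest_remainder(counts, total)
        return
    shares = largest_remainder(counts, total)
    assert shares.sum() == total
    assert (shares >= 0).all()
    quota = np.asarray(counts, float) / sum(counts) * total
    assert np.all(np.abs(shares - quota) < 1.0)  # within one unit of quota
    assert all(s == 0 for s, c in zip(shares, counts) if c == 0)


# ---------------------------------------------------------------------------
# source differentiation
# ---------------------------------------------------------------------------
def test_identical_sources_give_fst_centred_at_zero():
    cfg = small_config(fst_target=0.0, n_loci=500, n_founders_per_source=80)
    founders, freqs = simulate_sources(cfg)
    np.testing.assert_array_equal(freqs["D"], freqs["Y"])
    pool_d = founders.subset(individuals=[i for i in founders.ids if i[0] == "D"])
    pool_y = founders.subset(individuals=[i for i in founders.ids if i[0] == "Y"])
    assert abs(mean_fst(pool_d, pool_y)) < 0.01


def test_realized_fst_matches_target():
    cfg = small_config(fst_target=0.05, n_loci=1000, n_founders_per_source=100,
                       seed=77)
    founders, _ = simulate_sources(cfg)
    pool_d = founders.subset(individuals=[i for i in founders.ids if i[0] == "D"])
    pool_y = founders.subset(individuals=[i for i in founders.ids if i[0] == "Y"])
    realized = mean_fst(pool_d, pool_y)
    assert abs(realized - 0.05) < 0.01


def test_differentiated_tail_exists(study):
    """A few hundred loci should exceed the 0.02 ancestry-informative cutoff."""
    pD = study.truth.source_freqs["D"]
    pY = study.truth.source_freqs["Y"]
    pbar = (pD + pY) / 2
    fst_param = (pD - pY) ** 2 / (2 * pbar * (1 - pbar) + 1e-12)
    assert (fst_param >= 0.02).sum() > 200


# ---------------------------------------------------------------------------
# breeding programme
# ---------------------------------------------------------------------------
def test_forced_heterozygote_transmission():
    """Dam dosage 0 x sire dosage 2 must give dosage-1 offspring pre-error."""
    from perchmon.simdata import _mendelian_draw

    rng = np.random.default_rng(0)
    gd = np.zeros(50, dtype=np.int8)
    gs = np.full(50, 2, dtype=np.int8)
    off = _mendelian_draw(gd, gs, rng)
    assert (off == 1).all()


def test_fingerling_attribution_sums_to_season_totals():
    cfg = small_config()
    rng = np.random.default_rng(cfg.seed)
    founders, _ = simulate_sources(cfg, rng)
    pairs = simulate_breeding_program(cfg, founders, rng)
    for plan in cfg.seasons:
        sub = pairs[pairs.season == plan.season]
        assert sub.fingerlings.sum() == plan.stocked
        assert (sub.groupby("cross_type").size().reindex(
            [c for c in plan.pairs if plan.pairs[c] > 0]).to_dict()
            == {c: n for c, n in plan.pairs.items() if n > 0})


def test_noise_free_offspring_are_mendelian_consistent():
    """With zero error and missingness every genotype obeys its pedigree."""
    cfg = small_config(
        genotyping_error_rate=1e-12,  # error model requires e > 0
        missing_rate=0.0,
        high_missing_locus_fraction=0.0,
        recruitment_rate=0.0,
        seed=5,
    )
    ds = simulate_dataset(cfg)
    X = _exclusion_table()
    s2f = ds.truth.sample_map.set_index("sample_id")["fish_id"]
    ind = ds.truth.individuals.set_index("fish_id")
    brood = {
        s[2:]: ds.genotypes.row(s) for s in ds.genotypes.ids if s.startswith("B_")
    }
    checked = 0
    for s in ds.genotypes.ids:
        if not s.startswith("M"):
            continue
        fish = s2f[s]
        rec = ind.loc[fish]
        if rec.origin != "stocked" or rec.dam not in brood or rec.sire not in brood:
            continue
        off = ds.genotypes.row(s)
        gd, gs = brood[rec.dam], brood[rec.sire]
        ok = (off != MISSING) & (gd != MISSING) & (gs != MISSING)
        assert X[gd[ok], gs[ok], off[ok]].sum() == 0
        checked += 1
    assert checked > 5


# ---------------------------------------------------------------------------
# monitoring and truth
# ---------------------------------------------------------------------------
def test_fixed_seed_is_byte_identical():
    cfg = small_config(seed=99)
    a = simulate_dataset(cfg)
    b = simulate_dataset(small_config(seed=99))
    np.testing.assert_array_equal(a.genotypes.dosage, b.genotypes.dosage)
    pd.testing.assert_frame_equal(a.samples, b.samples)
    pd.testing.assert_frame_equal(a.truth.individuals, b.truth.individuals)


def test_capture_age_bias_and_fate_consistency(study):
    """Captured fish were alive at capture age; age-0 captures are rare."""
    s2f = study.truth.sample_map.set_index("sample_id")["fish_id"]
    ind = study.truth.individuals.set_index("fish_id")
    mon = study.samples[study.samples.role == "monitoring"]
    ages = []
    for row in mon.itertuples():
        rec = ind.loc[s2f[row.sample_id]]
        age = row.capture_year - rec.birth_year - 2 / 3
        assert age >= 0
        assert rec.death_age >= np.ceil(age)  # alive-at-age is consistent
        ages.append(age)
    ages = np.asarray(ages)
    assert (ages < 1).mean() < 0.2  # young-of-year under-represented


def test_truth_covers_every_monitored_sample(study):
    mapped = set(study.truth.sample_map.sample_id)
    assert set(study.samples.sample_id) <= mapped
    fish = set(study.truth.individuals.fish_id)
    assert set(study.truth.sample_map.fish_id) <= fish


def test_recruit_ancestry_ranking_follows_survival_offsets(study):
    """Configured YxY > DxY > DxD offsets must rank sampled recruit ancestry."""
    s2f = study.truth.sample_map.set_index("sample_id")["fish_id"]
    ind = study.truth.individuals.set_index("fish_id")
    mon = study.samples[study.samples.role == "monitoring"]
    local = [
        ind.loc[s2f[s]].cross_cat
        for s in mon.sample_id
        if ind.loc[s2f[s]].origin == "locally_born"
    ]
    counts = pd.Series(local).value_counts()
    assert counts.get("YxY", 0) >= counts.get("DxY", 0) >= counts.get("DxD", 0)


def test_config_validation():
    with pytest.raises(ValueError):
        small_config(capture_prob_by_age=(0.02, 0.02, 0.02, 0.02, 0.02, 0.02))
    with pytest.raises(ValueError):
        small_config(missing_rate=1.5)
    with pytest.raises(ValueError):
        simulate_sources(small_config(fst_target=0.6))


def test_config_yaml_round_trip(tmp_path):
    cfg = small_config()
    p = tmp_path / "cfg.yaml"
    cfg.to_yaml(p)
    back = SimConfig.from_yaml(p)
    assert back == cfg


def test_dataset_write_load_round_trip(tmp_path):
    ds = simulate_dataset(small_config(seed=3))
    ds.write_dir(tmp_path / "d")
    back = ds.load_dir(tmp_path / "d")
    np.testing.assert_array_equal(back.genotypes.dosage, ds.genotypes.dosage)
    assert len(back.pairs) == len(ds.pairs)
    assert back.config.seed == ds.config.seed
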