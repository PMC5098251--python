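"""Error-prone library generation and the planted affinity landscape."""

import math

import numpy as np
import pytest
from scipy import stats

from besdsim.library import (
    AffinityLandscape,
    ConfigError,
    MutagenesisConfig,
    Pool,
    generate_library,
    rerandomize,
    true_kd,
)


# -- mutagenesis --------------------------------------------------------------


def test_library_mean_mutations_close_to_target(parent):
    config = MutagenesisConfig(mean_mutations=1.7, seed=7)
    pool = generate_library(parent, 10_000, config)
    counts = np.repeat(
        [len(g) for g in pool.genotypes], pool.counts
    )
    assert pool.total == 10_000
    # Poisson(1.7), n = 10000: SE of the mean is sqrt(1.7/1e4) ~ 0.013
    assert abs(counts.mean() - 1.7) < 0.05


def test_mutation_count_distribution_is_poisson(parent):
    """Chi-squared goodness of fit of per-clone counts against Poisson(1.7)."""
    config = MutagenesisConfig(mean_mutations=1.7, seed=11)
    pool = generate_library(parent, 50_000, config)
    counts = np.repeat([len(g) for g in pool.genotypes], pool.counts)
    n = counts.size
    kmax = 7  # bins 0..6 and 7+
    observed = np.array(
        [(counts == k).sum() for k in range(kmax)] + [(counts >= kmax).sum()]
    )
    pmf = stats.poisson.pmf(np.arange(kmax), 1.7)
    expected = n * np.append(pmf, 1 - pmf.sum())
    chi2 = ((observed - expected) ** 2 / expected).sum()
    # 7 degrees of freedom (8 bins, fixed theoretical rate)
    assert chi2 < stats.chi2.ppf(0.999, df=7)


def test_positions_unique_within_clone(parent):
    config = MutagenesisConfig(mean_mutations=4.0, seed=3)
    pool = generate_library(parent, 2_000, config)
    for g in pool.genotypes:
        keys = [(m.chain, m.index) for m in g]
        assert len(keys) == len(set(keys))
        assert keys == sorted(keys)


def test_substitution_targets_uniform_over_alternatives(parent):
    """At a fixed position, the 19 alternatives appear near-uniformly."""
    config = MutagenesisConfig(mean_mutations=1.7, seed=5)
    pool = generate_library(parent, 50_000, config)
    tally = {}
    for g, c in zip(pool.genotypes, pool.counts):
        for m in g:
            tally[m.variant_aa] = tally.get(m.variant_aa, 0) + int(c)
    total = sum(tally.values())
    # every residue appears as a target somewhere; shares are coarse
    # because parent composition varies, but no target should be absent
    assert len(tally) == 20  # all residues reachable as variants
    assert min(tally.values()) > 0.01 * total


def test_library_deterministic_under_seed(parent):
    a = generate_library(parent, 500, MutagenesisConfig(seed=42))
    b = generate_library(parent, 500, MutagenesisConfig(seed=42))
    assert a.genotypes == b.genotypes
    assert (a.counts == b.counts).all()
    c = generate_library(parent, 500, MutagenesisConfig(seed=43))
    assert c.genotypes != a.genotypes


def test_substitution_weights_respected(parent):
    weights = {"A": {"V": 1.0}}  # every parent alanine must become valine
    config = MutagenesisConfig(
        mean_mutations=2.0, substitution_weights=weights, seed=9
    )
    pool = generate_library(parent, 3_000, config)
    for g in pool.genotypes:
        for m in g:
            if m.parent_aa == "A":
                assert m.variant_aa == "V"


def test_invalid_configs_rejected():
    with pytest.raises(ConfigError):
        MutagenesisConfig(mean_mutations=0)
    with pytest.raises(ConfigError):
        MutagenesisConfig(substitution_weights={"A": {"V": -1.0}})
    with pytest.raises(ConfigError):
        AffinityLandscape(parent_kd=-1)
    with pytest.raises(ConfigError):
        AffinityLandscape(epistasis_penalty=0.5)
    with pytest.raises(ConfigError):
        AffinityLandscape(clade1=frozenset({"VH S25P"}))  # effect missing


# -- landscape ----------------------------------------------------------------


def test_parent_kd_and_single_effects(parent, landscape):
    assert landscape.kd(()) == pytest.approx(8.6)
    s25p = parent.mutation("VH", "25", "P")
    assert landscape.kd((s25p,)) == pytest.approx(8.6 * 0.25)


def test_full_clade1_set_gain(parent, landscape, r4as_set):
    """The seven-mutation serine-lineage consensus is worth ~95-fold."""
    from besdsim.sequence import Mutation

    muts = [Mutation.from_string(s, parent) for s in r4as_set]
    kd = landscape.kd(muts)
    gain = landscape.parent_kd / kd
    expected = 1.0
    for f in (0.25, 0.70, 0.70, 0.70, 0.25, 0.70, 0.70):
        expected /= f
    assert gain == pytest.approx(expected)
    assert 90 < gain < 100


def test_effects_multiply_independently(parent, landscape):
    a = parent.mutation("VH", "25", "P")
    b = parent.mutation("VL", "55", "L")
    assert landscape.kd((a, b)) == pytest.approx(
        landscape.parent_kd * 0.25 * 0.70
    )


def test_cross_clade_epistasis_penalty(parent, landscape):
    y50s = parent.mutation("VL", "50", "S")  # clade-1 exclusive
    y50h_like = parent.mutation("VH", "8", "S")  # clade-2 exclusive (G8S)
    combined = landscape.kd((y50s, y50h_like))
    within = landscape.parent_kd * 0.25 * 0.95
    assert combined == pytest.approx(within * 10.0)


def test_shared_mutation_does_not_trigger_penalty(parent, landscape):
    # VH S25P belongs to both clades; pairing it with either side is clean
    s25p = parent.mutation("VH", "25", "P")
    g8s = parent.mutation("VH", "8", "S")
    assert landscape.kd((s25p, g8s)) == pytest.approx(
        landscape.parent_kd * 0.25 * 0.95
    )


def test_background_effects_reproducible_and_bounded(landscape):
    keys = [f"VH A{i}V" for i in range(1, 400)]
    folds = [landscape.background_effect(k) for k in keys]
    again = [landscape.background_effect(k) for k in keys]
    assert folds == again
    assert all(0.8 <= f <= 5.0 for f in folds)
    neutral = sum(f == 1.0 for f in folds) / len(folds)
    assert 0.70 < neutral < 0.90  # hashed categories near 80% neutral


def test_true_kd_accepts_records_and_genotypes(parent, landscape):
    from besdsim.sequence import VariantRecord

    g = (parent.mutation("VH", "25", "P"),)
    rec = VariantRecord.from_mutations(parent, g, "x")
    assert true_kd(rec, landscape) == true_kd(g, landscape)


# -- pool ---------------------------------------------------------------------


def test_pool_invariants():
    g1, g2 = (), None
    pool = Pool([()], [3])
    assert pool.total == 3 and pool.unique_count == 1
    assert pool.parent_frequency() == 1.0
    with pytest.raises(ValueError):
        Pool([], [])
    with pytest.raises(ValueError):
        Pool([()], [0])


def test_pool_merge_sums_counts(parent):
    a = parent.mutation("VH", "25", "P")
    p1 = Pool([(), (a,)], [2, 1])
    p2 = Pool([(a,)], [4])
    merged = p1.merge(p2)
    tally = dict(zip(merged.genotypes, merged.counts))
    assert tally[()] == 2 and tally[(a,)] == 5
    assert merged.total == 7


def test_pool_record_round_trip(parent):
    a = parent.mutation("VL", "50", "S")
    pool = Pool([(), (a,)], [5, 2])
    records = pool.to_records(parent)
    back = Pool.from_records(records)
    assert dict(zip(back.genotypes, back.counts)) == dict(
        zip(pool.genotypes, pool.counts)
    )


# -- rerandomization ----------------------------------------------------------


def test_rerandomize_adds_poisson_mutations(parent, rng):
    a = parent.mutation("VH", "25", "P")
    pool = Pool([(a,)], [10])
    config = MutagenesisConfig(mean_mutations=1.7)
    out = rerandomize(pool, parent, 20_000, config, rng)
    added = np.repeat(
        [len(g) for g in out.genotypes], out.counts
    ).mean()
    # base has 1 mutation; additions are Poisson(1.7) minus rare
    # collisions/reversions at the occupied position
    assert out.total == 20_000
    assert 2.5 < added < 2.85


def test_rerandomize_preserves_base_when_no_hit(parent, rng):
    a = parent.mutation("VH", "25", "P")
    pool = Pool([(a,)], [1])
    out = rerandomize(
        pool, parent, 5_000, MutagenesisConfig(mean_mutations=0.5), rng
    )
    # most clones keep the base mutation (only a direct hit can change it)
    carrying = sum(
        int(c) for g, c in zip(out.genotypes, out.counts)
        if any(m.position == ("VH", "25") and m.variant_aa == "P" for m in g)
    )
    assert carrying / out.total > 0.95


def test_rerandomize_samples_proportional_to_counts(parent, rng):
    a = parent.mutation("VH", "25", "P")
    b = parent.mutation("VL", "50", "S")
    pool = Pool([(a,), (b,)], [9, 1])
    out = rerandomize(
        pool, parent, 20_000, MutagenesisConfig(mean_mutations=0.1), rng
    )
    with_a = sum(
        int(c) for g, c in zip(out.genotypes, out.counts)
        if any(m.position == ("VH", "25") for m in g)
    )
    assert with_a / out.total == pytest.approx(0.9, abs=0.02)
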