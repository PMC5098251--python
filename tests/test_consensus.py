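"""Frequencies, hotspots, trees, clades and consensus assembly."""

import numpy as np
import pytest

from besdsim.consensus import (
    AmbiguousConsensusError,
    analyze_output,
    build_tree,
    call_hotspots,
    clade_consensus,
    dominant_mutations,
    evaluate_designs,
    hamming_matrix,
    mutation_frequencies,
    partition_clades,
    unique_records,
)
from besdsim.sequence import VariantRecord


def _rec(parent, id, mut_strings, count=1):
    from besdsim.sequence import Mutation

    muts = [Mutation.from_string(s, parent) for s in mut_strings]
    return VariantRecord.from_mutations(parent, muts, id, count)


# -- frequencies and hotspots -------------------------------------------------


def test_frequencies_hand_computed(parent):
    records = [
        _rec(parent, "a", ["VH S25P", "VL Y50S"]),
        _rec(parent, "b", ["VH S25P"]),
        _rec(parent, "c", []),
        _rec(parent, "d", ["VL Y50H"]),
    ]
    table = mutation_frequencies(records, parent)
    assert table.n_sequences == 4
    assert table.fraction[("VH", "25")] == pytest.approx(0.5)
    assert table.fraction[("VL", "50")] == pytest.approx(0.5)
    assert table.fraction[("VH", "8")] == 0.0
    assert table.residue_counts[("VL", "50")] == {"S": 1, "H": 1}


def test_frequencies_weighted_by_count(parent):
    records = [
        _rec(parent, "a", ["VH S25P"], count=3),
        _rec(parent, "b", [], count=1),
    ]
    t = mutation_frequencies(records, parent, use_counts=True)
    assert t.fraction[("VH", "25")] == pytest.approx(0.75)
    u = mutation_frequencies(records, parent, use_counts=False)
    assert u.fraction[("VH", "25")] == pytest.approx(0.5)


def test_hotspot_threshold_strictly_greater(parent):
    # exactly 20% must NOT be a hotspot; just above must be
    records = [_rec(parent, f"m{i}", ["VH S25P"]) for i in range(20)]
    records += [_rec(parent, f"w{i}", []) for i in range(80)]
    t = mutation_frequencies(records, parent)
    assert t.fraction[("VH", "25")] == pytest.approx(0.20)
    assert ("VH", "25") not in call_hotspots(t)
    records.append(_rec(parent, "extra", ["VH S25P"]))
    t2 = mutation_frequencies(records, parent)
    assert ("VH", "25") in call_hotspots(t2)


def test_hotspots_in_numbering_order(parent):
    records = [
        _rec(parent, "a", ["VL Y50S", "VH S25P"]),
        _rec(parent, "b", ["VL Y50S", "VH S25P"]),
        _rec(parent, "c", []),
    ]
    hs = call_hotspots(mutation_frequencies(records, parent))
    assert hs == [("VH", "25"), ("VL", "50")]  # VH before VL


def test_dominance_and_bifurcation(parent):
    records = (
        [_rec(parent, f"s{i}", ["VL Y50S"]) for i in range(9)]
        + [_rec(parent, f"h{i}", ["VL Y50H"]) for i in range(1)]
        + [_rec(parent, f"p{i}", []) for i in range(5)]
    )
    t = mutation_frequencies(records, parent)
    dom = dominant_mutations(t)
    d = dom[("VL", "50")]
    assert d.dominant == "S" and d.shares["S"] == pytest.approx(0.9)

    # a 60/40 split dominates nowhere and reports both residues
    records2 = (
        [_rec(parent, f"s{i}", ["VL Y50S"]) for i in range(6)]
        + [_rec(parent, f"h{i}", ["VL Y50H"]) for i in range(4)]
    )
    d2 = dominant_mutations(mutation_frequencies(records2, parent))[("VL", "50")]
    assert d2.dominant is None
    assert set(d2.bifurcated) == {"S", "H"}


# -- distances and trees ------------------------------------------------------


def test_hamming_matrix_hand_example(parent):
    a = _rec(parent, "a", ["VH S25P", "VL Y50S"])
    b = _rec(parent, "b", ["VH S25P"])
    c = _rec(parent, "c", ["VL Y50H"])
    dm = hamming_matrix([a, b, c])
    assert dm["a", "b"] == 1          # differ at VL 50
    assert dm["a", "c"] == 2          # VH 25 and S vs H at VL 50
    assert dm["b", "c"] == 2
    # equals brute-force distance over concatenated chains
    for x in (a, b, c):
        for y in (a, b, c):
            brute = sum(
                p != q for p, q in zip(
                    x.vh_sequence + x.vl_sequence,
                    y.vh_sequence + y.vl_sequence,
                )
            )
            assert dm[x.id, y.id] == brute


def test_nj_three_taxa_branch_lengths(parent):
    """d(AB)=2, d(AC)=d(BC)=5 gives additive branch lengths 1,1,4."""
    a = _rec(parent, "A", ["VH S25P", "VL Y50S"])
    b = _rec(parent, "B", ["VH S25P", "VL I28T"])
    c = _rec(parent, "C", ["VH G8S", "VH L20I", "VL F55L"])
    tree = build_tree([a, b, c])
    dist = tree.tip_tip_distances()
    assert dist["A", "B"] == pytest.approx(2.0)
    assert dist["A", "C"] == pytest.approx(5.0)
    assert dist["B", "C"] == pytest.approx(5.0)
    # midpoint root separates C from {A, B}
    part = partition_clades(tree, k=2)
    clades = {}
    for name, cl in part.assignment.items():
        clades.setdefault(cl, set()).add(name)
    assert {frozenset(s) for s in clades.values()} == {
        frozenset({"A", "B"}), frozenset({"C"}),
    }


def test_tree_additivity_on_separated_clades(parent, r4as_set, r4ah_set):
    """Two planted lineages are split cleanly by the k=2 partition.

    The shared mutation (VH S25P) is excluded so the lineages carry
    disjoint mutation sets: within-clade distances are then at most 4
    while every between-clade distance is 6.
    """
    rng = np.random.default_rng(5)
    clade1 = sorted(r4as_set - {"VH S25P"})  # 6 mutations
    clade2 = sorted(r4ah_set - {"VH S25P"})  # 3 mutations
    records = []
    for i in range(8):
        take = rng.choice(len(clade1), size=4, replace=False)
        records.append(_rec(parent, f"s{i}", [clade1[j] for j in take]))
    for i in range(8):
        take = rng.choice(len(clade2), size=2, replace=False)
        records.append(_rec(parent, f"h{i}", [clade2[j] for j in take]))
    tree = build_tree(records)
    part = partition_clades(tree, k=2)
    groups = {}
    for name, cl in part.assignment.items():
        groups.setdefault(cl, set()).add(name)
    prefixes = {frozenset(n[0] for n in g) for g in groups.values()}
    assert prefixes == {frozenset("s"), frozenset("h")}


def test_partition_k3_cuts_longest_edges(parent):
    a = _rec(parent, "A", ["VH S25P"])
    b = _rec(parent, "B", ["VH S25P", "VL Y50S"])
    c = _rec(parent, "C", ["VH G8S", "VH L20I", "VL Y50H", "VL F55L"])
    d = _rec(parent, "D", ["VH G8S", "VH L20I", "VL Y50H", "VL K95aE"])
    e = _rec(parent, "E", ["VH V102N", "VH G104D", "VL I28T"])
    tree = build_tree([a, b, c, d, e])
    part3 = partition_clades(tree, k=3)
    sizes = sorted(
        np.unique(list(part3.assignment.values()), return_counts=True)[1]
    )
    assert sum(sizes) == 5 and len(sizes) == 3
    with pytest.raises(ValueError):
        partition_clades(tree, k=6)


def test_trivial_tree_warns(parent):
    a = _rec(parent, "A", ["VH S25P"])
    b = _rec(parent, "B", ["VL Y50S"])
    with pytest.warns(UserWarning, match="fewer than 3"):
        tree = build_tree([a, b])
    assert {t.name for t in tree.tips()} == {"A", "B"}


# -- unique records -----------------------------------------------------------


def test_unique_records_collapse_and_order_invariance(parent):
    a1 = _rec(parent, "x1", ["VH S25P"], count=2)
    a2 = _rec(parent, "x2", ["VH S25P"], count=3)
    b = _rec(parent, "y", ["VL Y50S"])
    u_fwd = unique_records([a1, a2, b])
    u_rev = unique_records([b, a2, a1])
    assert [r.mutations for r in u_fwd] == [r.mutations for r in u_rev]
    assert [r.count for r in u_fwd] == [r.count for r in u_rev]
    assert sum(r.count for r in u_fwd) == 6
    assert len(u_fwd) == 2


# -- consensus ----------------------------------------------------------------


def test_clade_consensus_threshold_strict(parent):
    # 2 of 10 distinct genotypes carry the focal mutation: exactly 20%
    # of the clade's unique sequences, so it must NOT join the consensus
    records = [
        _rec(parent, "a", ["VH S25P", "VL F55L"]),
        _rec(parent, "b", ["VH S25P", "VL K95aE"]),
    ] + [
        _rec(parent, f"p{i}", [f"VH G8{aa}"])
        for i, aa in enumerate("ACDEFHIK")
    ]
    records = unique_records(records)
    assert len(records) == 10

    class FakePartition:
        assignment = {r.id: 1 for r in records}

        @staticmethod
        def members(clade):
            return [r.id for r in records]

    designs = clade_consensus(records, FakePartition, parent)
    assert designs[1].consensus_mutations == frozenset()

    # 3 of 10 (30%) qualifies -- but uniques collapse carriers, so build
    # distinct genotypes that share the focal mutation
    records2 = [
        _rec(parent, "a", ["VH S25P", "VL F55L"]),
        _rec(parent, "b", ["VH S25P", "VL K95aE"]),
        _rec(parent, "c", ["VH S25P"]),
    ] + [_rec(parent, f"p{i}", [f"VH G8{aa}"]) for i, aa in enumerate("ACDE")]
    records2 = unique_records(records2)

    class P2:
        assignment = {r.id: 1 for r in records2}

        @staticmethod
        def members(clade):
            return [r.id for r in records2]

    designs2 = clade_consensus(records2, P2, parent)
    assert {str(m) for m in designs2[1].consensus_mutations} == {"VH S25P"}


def test_clade_consensus_tie_raises(parent):
    records = [
        _rec(parent, "a", ["VL Y50S"]),
        _rec(parent, "b", ["VL Y50H"]),
    ]
    records = unique_records(records)

    class P:
        assignment = {r.id: 1 for r in records}

        @staticmethod
        def members(clade):
            return [r.id for r in records]

    with pytest.raises(AmbiguousConsensusError):
        clade_consensus(records, P, parent, clade_threshold=0.2)


def test_fixture_analysis_recovers_planted_designs(
    parent, landscape, r4as_set, r4ah_set
):
    from besdsim.datasets import round4_fixture

    records = round4_fixture(seed=0, parent=parent)
    report = analyze_output(records, parent, landscape=landscape)
    assert len(report.hotspots) == 8
    designs = {
        frozenset(str(m) for m in d.consensus_mutations)
        for d in report.designs.values()
    }
    assert designs == {frozenset(r4as_set), frozenset(r4ah_set)}
    # the bifurcated position reports both residues, neither dominant
    d50 = report.dominance[("VL", "50")]
    assert d50.dominant is None and set(d50.bifurcated) == {"S", "H"}
    # predicted affinities attached and better than parent
    for d in report.designs.values():
        assert d.predicted_kd is not None
        assert d.predicted_kd < landscape.parent_kd


def test_evaluate_designs_table(parent, landscape, r4as_set):
    records = [_rec(parent, "best", sorted(r4as_set))]
    report = analyze_output(
        records + [_rec(parent, "p", []), _rec(parent, "q", ["VH S25P"])],
        parent, landscape=landscape,
    )
    frame = evaluate_designs(report.designs, landscape, records[0])
    assert list(frame["name"])[:2] == ["parent", "best_selected:best"]
    parent_row = frame.iloc[0]
    assert parent_row["true_kd_nM"] == pytest.approx(landscape.parent_kd)
    assert (frame["gain_vs_parent"] > 0).all()
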