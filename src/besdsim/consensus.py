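"""Selection-output sequence analysis: hotspots, clades, consensus design.

Given a pool of sequenced clones from a late selection round, this
module computes per-position mutation frequencies, calls hotspots
(positions mutated in strictly more than 20% of the sequences),
summarises dominant substitutions per hotspot (>80% of the mutations at
a position, with a bifurcation report otherwise), partitions the unique
sequences into clades on a neighbour-joining tree built from pairwise
Hamming distances, and assembles per-clade consensus variants from the
residue-specific mutations carried by more than 20% of each clade.

The tree is a distance tree, not a maximum-likelihood phylogeny: its
only role here is to split well-separated lineages, a task for which
neighbour joining on Hamming distances is adequate; Newick output lets
users substitute an externally built tree.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .binding import kd_gain
from .library import AffinityLandscape
from .sequence import (
    Genotype,
    Mutation,
    ParentReference,
    VariantRecord,
    apply_mutations,
)


class AmbiguousConsensusError(ValueError):
    """Two mutations at one position tie within a clade."""


@dataclass
class FrequencyTable:
    """Per-position mutation statistics over a set of sequences.

    ``fraction`` maps every (chain, label) position of the parent to the
    fraction of sequences mutated there (zero included); ``residue_counts``
    holds, per position, the count of each variant residue observed.
    """

    n_sequences: int
    positions: list[tuple[str, str]]
    fraction: dict[tuple[str, str], float]
    residue_counts: dict[tuple[str, str], Counter]

    def to_frame(self, parent: ParentReference) -> pd.DataFrame:
        rows = []
        for chain, label in self.positions:
            counts = self.residue_counts[(chain, label)]
            rows.append(
                {
                    "chain": chain,
                    "label": label,
                    "region": parent.region_of(chain, label),
                    "fraction_mutated": self.fraction[(chain, label)],
                    "residue_counts": ";".join(
                        f"{aa}:{c}" for aa, c in sorted(counts.items())
                    ),
                }
            )
        return pd.DataFrame(rows)


@dataclass
class CladePartition:
    """A tree over unique sequences plus a clade assignment."""

    tree: TreeNode
    assignment: dict[str, int]  # sequence id -> clade id (1-based)
    k: int

    def members(self, clade: int) -> list[str]:
        return [name for name, c in self.assignment.items() if c == clade]


@dataclass
class ConsensusDesign:
    """Per-clade consensus mutation set and the assembled variant."""

    clade: int
    consensus_mutations: frozenset[Mutation]
    assembled_variant: VariantRecord
    predicted_kd: float | None = None


def mutation_frequencies(
    records: list[VariantRecord],
    parent: ParentReference,
    use_counts: bool = True,
) -> FrequencyTable:
    """Exact per-position mutation fractions over a pool.

    With ``use_counts`` every clone is weighted by its multiplicity
    (sequencing of the raw output); without it each unique record counts
    once.
    """
    if not records:
        raise ValueError("no records")
    positions = [
        (chain, lab) for chain, _, lab, _ in parent.positions()
    ]
    mutated: Counter = Counter()
    residues: dict[tuple[str, str], Counter] = {p: Counter() for p in positions}
    n = 0
    for rec in records:
        w = rec.count if use_counts else 1
        n += w
        for m in rec.mutations:
            mutated[m.position] += w
            residues[m.position][m.variant_aa] += w
    fraction = {p: mutated.get(p, 0) / n for p in positions}
    return FrequencyTable(n, positions, fraction, residues)


def call_hotspots(
    table: FrequencyTable, threshold: float = 0.20
) -> list[tuple[str, str]]:
    """Positions mutated in strictly more than ``threshold`` of sequences,
    in numbering-map order."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    return [p for p in table.positions if table.fraction[p] > threshold]


@dataclass
class Dominance:
    """Mutation-share summary at one hotspot position."""

    position: tuple[str, str]
    shares: dict[str, float]  # variant residue -> share of mutations
    dominant: str | None  # residue with share > dominance threshold
    bifurcated: dict[str, float]  # residues with share >= minor threshold


def dominant_mutations(
    table: FrequencyTable,
    hotspots: list[tuple[str, str]] | None = None,
    dominance_threshold: float = 0.80,
    minor_threshold: float = 0.20,
) -> dict[tuple[str, str], Dominance]:
    """Dominant or bifurcated substitutions per hotspot.

    A residue dominates when it contributes strictly more than the
    dominance threshold of all mutations at the position; otherwise the
    position is reported as bifurcated, listing every residue whose
    share reaches the minor threshold.
    """
    if hotspots is None:
        hotspots = call_hotspots(table)
    out: dict[tuple[str, str], Dominance] = {}
    for pos in hotspots:
        counts = table.residue_counts[pos]
        total = sum(counts.values())
        if total == 0:
            continue
        shares = {aa: c / total for aa, c in counts.items()}
        best_aa = max(shares, key=lambda aa: (shares[aa], aa))
        dominant = best_aa if shares[best_aa] > dominance_threshold else None
        bifurcated = (
            {} if dominant
            else {aa: s for aa, s in shares.items() if s >= minor_threshold}
        )
        out[pos] = Dominance(pos, shares, dominant, bifurcated)
    return out


# -- tree and clades ---------------------------------------------------------


def hamming_matrix(records: list[VariantRecord]) -> DistanceMatrix:
    """Pairwise Hamming distances between unique records.

    Distances are computed on the mutation sets (identical to comparing
    the concatenated chains position by position, since all records
    share the parent's chain lengths).
    """
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate record ids")
    maps = [
        {(m.chain, m.index): m.variant_aa for m in r.mutations}
        for r in records
    ]
    n = len(records)
    d = np.zeros((n, n))
    for i in range(n):
        mi = maps[i]
        for j in range(i + 1, n):
            mj = maps[j]
            diff = 0
            for key, aa in mi.items():
                if mj.get(key) != aa:
                    diff += 1
            for key in mj:
                if key not in mi:
                    diff += 1
            d[i, j] = d[j, i] = diff
    return DistanceMatrix(d, ids)


def build_tree(unique_records: list[VariantRecord]) -> TreeNode:
    """Midpoint-rooted neighbour-joining tree over unique sequences.

    Deterministic given the input order; with fewer than 3 sequences a
    trivial star tree is returned with a warning.
    """
    dm = hamming_matrix(unique_records)
    if len(unique_records) < 3:
        warnings.warn("fewer than 3 unique sequences; returning trivial tree")
        root = TreeNode(name="root", length=None)
        for r in unique_records:
            root.append(TreeNode(name=r.id, length=0.0))
        return root
    tree = nj(dm)
    # zero-length negative branches can appear on degenerate inputs
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree.root_at_midpoint()


def partition_clades(
    tree: TreeNode, k: int = 2
) -> CladePartition:
    """Split the tree's leaves into ``k`` clades.

    For ``k=2`` the two subtrees flanking the midpoint root form the
    clades.  For larger ``k`` the longest internal edges are cut first
    (falling back to terminal edges when the internal edges run out).
    Clades are numbered by decreasing size, ties broken by the smallest
    member name.
    """
    tips = [t.name for t in tree.tips()]
    if k > len(tips):
        raise ValueError(f"k={k} exceeds the number of leaves ({len(tips)})")
    if k == 2:
        children = tree.children
        groups = [
            [t.name for t in child.tips()] or [child.name]
            for child in children
        ]
        if len(groups) > 2:  # unrooted-style trifurcation fallback
            groups = sorted(groups, key=len, reverse=True)
            groups = [groups[0], sum(groups[1:], [])]
    else:
        groups = _cut_edges(tree, k)
    groups = sorted(groups, key=lambda g: (-len(g), sorted(g)[0]))
    assignment = {
        name: ci + 1 for ci, group in enumerate(groups) for name in group
    }
    return CladePartition(tree, assignment, k)


def _cut_edges(tree: TreeNode, k: int) -> list[list[str]]:
    """Leaf components after cutting the k-1 longest edges."""
    nodes = list(tree.traverse(include_self=True))
    node_id = {id(n): i for i, n in enumerate(nodes)}
    edges = []  # (length, order, child_index, parent_index, is_internal)
    for order, n in enumerate(nodes):
        if n.parent is None:
            continue
        edges.append(
            (
                n.length or 0.0,
                order,
                node_id[id(n)],
                node_id[id(n.parent)],
                not n.is_tip(),
            )
        )
    internal = sorted(
        [e for e in edges if e[4]], key=lambda e: (-e[0], e[1])
    )
    terminal = sorted(
        [e for e in edges if not e[4]], key=lambda e: (-e[0], e[1])
    )
    cut = set()
    for e in (internal + terminal)[: k - 1]:
        cut.add((e[2], e[3]))
    parent_uf = list(range(len(nodes)))

    def find(x):
        while parent_uf[x] != x:
            parent_uf[x] = parent_uf[parent_uf[x]]
            x = parent_uf[x]
        return x

    for e in edges:
        if (e[2], e[3]) not in cut:
            ra, rb = find(e[2]), find(e[3])
            if ra != rb:
                parent_uf[ra] = rb
    comps: dict[int, list[str]] = {}
    for n in nodes:
        if n.is_tip():
            comps.setdefault(find(node_id[id(n)]), []).append(n.name)
    return list(comps.values())


def unique_records(records: list[VariantRecord]) -> list[VariantRecord]:
    """Collapse a pool to unique sequences, summing multiplicities.

    Ids are reassigned deterministically (ordered by genotype) so the
    tree and clade assignment do not depend on input order.
    """
    tally: dict[Genotype, int] = {}
    seqs: dict[Genotype, tuple[str, str]] = {}
    for r in records:
        tally[r.mutations] = tally.get(r.mutations, 0) + r.count
        seqs[r.mutations] = (r.vh_sequence, r.vl_sequence)
    ordered = sorted(tally, key=lambda g: [(m.chain, m.index, m.variant_aa) for m in g])
    return [
        VariantRecord(f"u{i:04d}", seqs[g][0], seqs[g][1], g, tally[g])
        for i, g in enumerate(ordered)
    ]


def clade_consensus(
    records: list[VariantRecord],
    partition: CladePartition,
    parent: ParentReference,
    clade_threshold: float = 0.20,
    use_counts: bool = False,
    landscape: AffinityLandscape | None = None,
) -> dict[int, ConsensusDesign]:
    """Residue-specific consensus mutation set per clade.

    A mutation joins a clade's consensus when strictly more than
    ``clade_threshold`` of that clade's sequences carry it (unique
    sequences by default).  When two different substitutions at one
    position both qualify within a clade the more frequent one is kept;
    an exact tie raises :class:`AmbiguousConsensusError`.
    """
    by_id = {r.id: r for r in records}
    missing = set(partition.assignment) - set(by_id)
    if missing:
        raise ValueError(f"partition covers unknown ids: {sorted(missing)[:3]}")
    designs: dict[int, ConsensusDesign] = {}
    for clade in sorted(set(partition.assignment.values())):
        members = [by_id[i] for i in partition.members(clade)]
        n = sum(r.count for r in members) if use_counts else len(members)
        tally: Counter = Counter()
        for r in members:
            w = r.count if use_counts else 1
            for m in r.mutations:
                tally[m] += w
        passing = {m: c for m, c in tally.items() if c / n > clade_threshold}
        chosen: dict[tuple[str, int], Mutation] = {}
        for m, c in sorted(passing.items(), key=lambda kv: str(kv[0])):
            key = (m.chain, m.index)
            rival = chosen.get(key)
            if rival is None:
                chosen[key] = m
            else:
                if passing[rival] == c:
                    raise AmbiguousConsensusError(
                        f"clade {clade}: {rival} and {m} tie at "
                        f"{c}/{n} sequences; manual choice required"
                    )
                if c > passing[rival]:
                    chosen[key] = m
        consensus = frozenset(chosen.values())
        vh, vl = apply_mutations(parent, consensus)
        variant = VariantRecord(
            f"clade{clade}_consensus", vh, vl,
            tuple(sorted(consensus, key=lambda m: (m.chain, m.index))),
        )
        predicted = landscape.kd(consensus) if landscape is not None else None
        designs[clade] = ConsensusDesign(clade, consensus, variant, predicted)
    return designs


def evaluate_designs(
    designs: dict[int, ConsensusDesign],
    landscape: AffinityLandscape,
    best_selected: VariantRecord,
) -> pd.DataFrame:
    """Ground-truth comparison of consensus designs against the best
    experimentally selected clone (simulation mode only)."""
    rows = [
        {
            "name": "parent",
            "true_kd_nM": landscape.parent_kd,
            "gain_vs_parent": 1.0,
            "n_mutations": 0,
        },
        {
            "name": f"best_selected:{best_selected.id}",
            "true_kd_nM": landscape.kd(best_selected.mutations),
            "gain_vs_parent": kd_gain(
                landscape.parent_kd, landscape.kd(best_selected.mutations)
            ),
            "n_mutations": len(best_selected.mutations),
        },
    ]
    for clade, d in sorted(designs.items()):
        kd = landscape.kd(d.consensus_mutations)
        rows.append(
            {
                "name": f"clade{clade}_consensus",
                "true_kd_nM": kd,
                "gain_vs_parent": kd_gain(landscape.parent_kd, kd),
                "n_mutations": len(d.consensus_mutations),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class AnalysisReport:
    """Bundle of the full sequence-analysis stage."""

    table: FrequencyTable
    hotspots: list[tuple[str, str]]
    dominance: dict[tuple[str, str], Dominance]
    tree: TreeNode | None
    partition: CladePartition | None
    designs: dict[int, ConsensusDesign]


def analyze_output(
    records: list[VariantRecord],
    parent: ParentReference,
    hotspot_threshold: float = 0.20,
    dominance_threshold: float = 0.80,
    clade_threshold: float = 0.20,
    k: int = 2,
    landscape: AffinityLandscape | None = None,
) -> AnalysisReport:
    """Run the full analysis stage on a selection-output pool.

    Overall frequencies are computed on all sequenced clones (with
    multiplicity); clade frequencies on unique sequences, matching how
    deep sequencing of an output is conventionally summarised.
    """
    table = mutation_frequencies(records, parent, use_counts=True)
    hotspots = call_hotspots(table, hotspot_threshold)
    dominance = dominant_mutations(
        table, hotspots, dominance_threshold, hotspot_threshold
    )
    uniques = unique_records(records)
    if len(uniques) >= 3:
        tree = build_tree(uniques)
        partition = partition_clades(tree, min(k, len(uniques)))
    else:
        tree = None
        partition = CladePartition(
            TreeNode(name="root"), {r.id: 1 for r in uniques}, 1
        )
    designs = clade_consensus(
        uniques, partition, parent, clade_threshold, landscape=landscape
    )
    return AnalysisReport(table, hotspots, dominance, tree, partition, designs)
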