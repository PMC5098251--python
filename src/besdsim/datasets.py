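"""Built-in synthetic reference data.

The parent scFv shipped here is a synthetic scaffold: a deterministic
pseudo-random variable-domain pair generated with Kabat-style labels
(insertion codes included) and the residues that matter for the planted
landscape
(VH G8/L20/S25/V102/G104, VL I28/Y50/F55/K95a) fixed at their labelled
positions.  Everything that consumes the parent treats the sequence as
data, so a real antibody reference (FASTA + numbering map) can be
substituted freely.
"""

from __future__ import annotations

import numpy as np

from .library import AffinityLandscape
from .sequence import (
    AA_ALPHABET,
    Mutation,
    ParentReference,
    VariantRecord,
    apply_mutations,
)

_VH_INSERTIONS = {52: "a", 82: "abc", 100: "a"}
_VL_INSERTIONS = {27: "a", 95: "a"}

# Kabat-style region boundaries (inclusive base numbers)
_VH_CDRS = {"CDR1": (31, 35), "CDR2": (50, 65), "CDR3": (95, 102)}
_VL_CDRS = {"CDR1": (24, 34), "CDR2": (50, 56), "CDR3": (89, 97)}

# residues the planted landscape addresses; (chain, label) -> parent aa
_FIXED_RESIDUES = {
    ("VH", "8"): "G",
    ("VH", "20"): "L",
    ("VH", "25"): "S",
    ("VH", "102"): "V",
    ("VH", "104"): "G",
    ("VL", "28"): "I",
    ("VL", "50"): "Y",
    ("VL", "55"): "F",
    ("VL", "95a"): "K",
}


def _labels(last: int, insertions: dict[int, str]) -> list[str]:
    labels = []
    for n in range(1, last + 1):
        labels.append(str(n))
        for code in insertions.get(n, ""):
            labels.append(f"{n}{code}")
    return labels


def _regions(chain: str, labels: list[str], cdrs) -> dict:
    def base(label: str) -> int:
        digits = "".join(ch for ch in label if ch.isdigit())
        return int(digits)

    bounds = sorted((lo, hi, name) for name, (lo, hi) in cdrs.items())
    out = {}
    for lab in labels:
        b = base(lab)
        region = None
        for i, (lo, hi, name) in enumerate(bounds):
            if lo <= b <= hi:
                region = name
                break
            if b < lo:
                region = f"FR{i + 1}"
                break
        if region is None:
            region = "FR4"
        out[(chain, lab)] = region
    return out


def synthetic_parent() -> ParentReference:
    """The packaged synthetic parent scFv reference (see module docstring)."""
    vh_labels = _labels(113, _VH_INSERTIONS)
    vl_labels = _labels(107, _VL_INSERTIONS)
    rng = np.random.default_rng(271828)
    vh = [AA_ALPHABET[i] for i in rng.integers(0, 20, size=len(vh_labels))]
    vl = [AA_ALPHABET[i] for i in rng.integers(0, 20, size=len(vl_labels))]
    seqs = {"VH": vh, "VL": vl}
    labels = {"VH": vh_labels, "VL": vl_labels}
    for (chain, lab), aa in _FIXED_RESIDUES.items():
        seqs[chain][labels[chain].index(lab)] = aa
    regions = _regions("VH", vh_labels, _VH_CDRS)
    regions.update(_regions("VL", vl_labels, _VL_CDRS))
    return ParentReference(
        "".join(vh), "".join(vl), tuple(vh_labels), tuple(vl_labels), regions
    )


#: Clade-1 (serine-lineage) beneficial mutations and Kd fold-effects.
#: The two anchor substitutions are worth 4-fold each (as measured for the
#: corresponding single mutants); the remaining members ~1.4-fold, so the
#: full set is worth ~95-fold, the scale of the consensus variant's gain.
CLADE1_EFFECTS = {
    "VH S25P": 0.25,
    "VH V102N": 0.70,
    "VH G104D": 0.70,
    "VL I28T": 0.70,
    "VL Y50S": 0.25,
    "VL F55L": 0.70,
    "VL K95aE": 0.70,
}

#: Clade-2 (histidine-lineage) beneficial mutations.  The lineage shares
#: VH S25P with Clade 1 and bifurcates at VL 50.
CLADE2_EFFECTS = {
    "VH G8S": 0.95,
    "VH L20I": 0.95,
    "VL Y50H": 0.45,
}


def default_landscape(seed: int = 0) -> AffinityLandscape:
    """The default planted two-clade affinity landscape (parent Kd 8.6 nM)."""
    effects = dict(CLADE1_EFFECTS)
    effects.update(CLADE2_EFFECTS)
    return AffinityLandscape(
        parent_kd=8.6,
        effects=effects,
        clade1=frozenset(CLADE1_EFFECTS),
        clade2=frozenset(CLADE2_EFFECTS) | {"VH S25P"},
        epistasis_penalty=10.0,
        background_seed=seed,
    )


# -- structured round-IV output fixture --------------------------------------

# exact within-clade carrier counts for the planted consensus mutations;
# chosen so every bold position exceeds 20% of all 223 sequences except
# VL I28 (26% of Clade 1 only), and VL Y50 splits ~54/46 between S and H.
_CLADE1_N = 116
_CLADE2_N = 107
_CLADE1_COUNTS = {
    "VH S25P": 70,
    "VH V102N": 87,
    "VH G104D": 81,
    "VL I28T": 30,   # 30/116 = 25.9% of Clade 1; 13.5% overall
    "VL Y50S": 64,
    "VL F55L": 75,
    "VL K95aE": 81,
}
_CLADE2_COUNTS = {
    "VH G8S": 70,
    "VH L20I": 64,
    "VH S25P": 59,
    "VL Y50H": 54,
}
_BACKGROUND_RATE = 0.8  # Poisson mean background substitutions per clone


def round4_fixture(
    seed: int | None = 0,
    parent: ParentReference | None = None,
) -> list[VariantRecord]:
    """Clade-structured synthetic round-IV selection output (223 clones).

    Plants the consensus mutations of the two lineages at exact
    within-clade carrier counts (random placement), plus sparse random
    background substitutions (<5% per position overall), emulating the
    mutation-frequency structure of a sequenced fourth-round output.
    """
    parent = parent or synthetic_parent()
    rng = np.random.default_rng(seed)
    planted = {
        key: Mutation.from_string(key, parent)
        for key in {**_CLADE1_COUNTS, **_CLADE2_COUNTS}
    }
    planted_positions = {(m.chain, m.index) for m in planted.values()}
    free_positions = [
        (chain, i, lab, aa)
        for chain, i, lab, aa in parent.positions()
        if (chain, i) not in planted_positions
    ]

    genotype_sets: list[set[Mutation]] = []
    for n_clade, counts in (
        (_CLADE1_N, _CLADE1_COUNTS),
        (_CLADE2_N, _CLADE2_COUNTS),
    ):
        sets: list[set[Mutation]] = [set() for _ in range(n_clade)]
        for key, k in counts.items():
            carriers = rng.choice(n_clade, size=k, replace=False)
            for c in carriers:
                sets[c].add(planted[key])
        genotype_sets.extend(sets)

    records = []
    for i, muts in enumerate(genotype_sets):
        n_bg = rng.poisson(_BACKGROUND_RATE)
        if n_bg:
            picks = rng.choice(len(free_positions), size=n_bg, replace=False)
            for p in picks:
                chain, idx, lab, aa = free_positions[p]
                off = int(rng.integers(0, 19))
                new_aa = AA_ALPHABET[(AA_ALPHABET.index(aa) + 1 + off) % 20]
                muts.add(Mutation(chain, idx, lab, aa, new_aa))
        genotype = tuple(sorted(muts, key=lambda m: (m.chain, m.index)))
        vh, vl = apply_mutations(parent, genotype)
        clade = 1 if i < _CLADE1_N else 2
        records.append(
            VariantRecord(f"c{clade}_{i:03d}", vh, vl, genotype, 1)
        )
    return records
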