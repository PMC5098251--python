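"""Parent scFv reference, scheme labelling and substitution calling.

An scFv variable region is represented as two amino-acid chains (VH and
VL).  Positions are addressed internally by 0-based index per chain and
externally by opaque scheme labels (Kabat-style, insertion codes such as
``95a`` included).  Labels are supplied as data with the parent reference;
they are never parsed numerically, only ordered by the numbering map.

The variant model is substitution-only: every variant chain must have the
same length as the parent chain, and insertions/deletions are rejected
with :class:`IndelNotSupportedError`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_SET = frozenset(AA_ALPHABET)
CHAINS = ("VH", "VL")
REGIONS = ("FR1", "CDR1", "FR2", "CDR2", "FR3", "CDR3", "FR4")


class IndelNotSupportedError(ValueError):
    """Variant chain length differs from the parent (indels unsupported)."""


class MutationConflictError(ValueError):
    """Two mutations address the same position of the same chain."""


@dataclass(frozen=True, order=True)
class Mutation:
    """A single amino-acid substitution against the parent.

    Canonical string form is ``"<chain> <parent><label><variant>"``,
    e.g. ``"VL Y50S"``.
    """

    chain: str
    index: int  # 0-based position within the chain
    label: str  # scheme label for the position, e.g. "50" or "95a"
    parent_aa: str
    variant_aa: str

    def __post_init__(self) -> None:
        if self.chain not in CHAINS:
            raise ValueError(f"unknown chain {self.chain!r}")
        for aa in (self.parent_aa, self.variant_aa):
            if aa not in AA_SET:
                raise ValueError(f"non-standard residue {aa!r}")
        if self.parent_aa == self.variant_aa:
            raise ValueError(f"{self} is not a substitution")

    def __str__(self) -> str:
        return f"{self.chain} {self.parent_aa}{self.label}{self.variant_aa}"

    @property
    def position(self) -> tuple[str, str]:
        """Chain-qualified scheme position, e.g. ``("VL", "50")``."""
        return (self.chain, self.label)

    @classmethod
    def from_string(cls, text: str, parent: "ParentReference") -> "Mutation":
        """Parse a canonical mutation string like ``"VH S25P"``."""
        try:
            chain, body = text.split()
            parent_aa, label, variant_aa = body[0], body[1:-1], body[-1]
        except (ValueError, IndexError) as exc:
            raise ValueError(f"cannot parse mutation string {text!r}") from exc
        index = parent.index_of(chain, label)
        found = parent.chain_sequence(chain)[index]
        if found != parent_aa:
            raise ValueError(
                f"{text!r}: parent residue at {chain} {label} is {found}, "
                f"not {parent_aa}"
            )
        return cls(chain, index, label, parent_aa, variant_aa)


Genotype = tuple[Mutation, ...]
"""A clone's genotype: mutations sorted by (chain, index)."""


def as_genotype(mutations: Iterable[Mutation]) -> Genotype:
    """Normalise a mutation collection into a sorted, conflict-free tuple."""
    muts = sorted(set(mutations), key=lambda m: (m.chain, m.index))
    seen: set[tuple[str, int]] = set()
    for m in muts:
        key = (m.chain, m.index)
        if key in seen:
            raise MutationConflictError(
                f"conflicting mutations at {m.chain} {m.label}"
            )
        seen.add(key)
    return tuple(muts)


@dataclass(frozen=True)
class ParentReference:
    """Parent scFv sequences with position labels and region annotation.

    Parameters
    ----------
    vh_sequence, vl_sequence
        Amino-acid strings of the two variable domains.
    vh_labels, vl_labels
        Scheme label per residue, in sequence order.  Labels must be
        unique within each chain; uniqueness across chains is achieved by
        chain qualification (positions are addressed as (chain, label)).
    regions
        Mapping from (chain, label) to a framework/CDR tag (FR1..FR4,
        CDR1..CDR3).  Must cover every position of both chains.
    """

    vh_sequence: str
    vl_sequence: str
    vh_labels: tuple[str, ...]
    vl_labels: tuple[str, ...]
    regions: Mapping[tuple[str, str], str]
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        for chain, seq, labels in (
            ("VH", self.vh_sequence, self.vh_labels),
            ("VL", self.vl_sequence, self.vl_labels),
        ):
            if len(seq) != len(labels):
                raise ValueError(
                    f"{chain}: {len(seq)} residues but {len(labels)} labels"
                )
            if len(set(labels)) != len(labels):
                raise ValueError(f"{chain}: duplicate scheme labels")
            bad = set(seq) - AA_SET
            if bad:
                raise ValueError(f"{chain}: non-standard residues {bad}")
            for label in labels:
                if (chain, label) not in self.regions:
                    raise ValueError(f"no region for {chain} {label}")
        lookup = {
            ("VH", lab): i for i, lab in enumerate(self.vh_labels)
        }
        lookup.update({("VL", lab): i for i, lab in enumerate(self.vl_labels)})
        self._index.update(lookup)

    # -- position addressing -------------------------------------------------

    def chain_sequence(self, chain: str) -> str:
        if chain == "VH":
            return self.vh_sequence
        if chain == "VL":
            return self.vl_sequence
        raise ValueError(f"unknown chain {chain!r}")

    def chain_labels(self, chain: str) -> tuple[str, ...]:
        if chain == "VH":
            return self.vh_labels
        if chain == "VL":
            return self.vl_labels
        raise ValueError(f"unknown chain {chain!r}")

    def label_at(self, chain: str, index: int) -> str:
        return self.chain_labels(chain)[index]

    def index_of(self, chain: str, label: str) -> int:
        try:
            return self._index[(chain, label)]
        except KeyError:
            raise KeyError(f"unknown position {chain} {label}") from None

    def region_of(self, chain: str, label: str) -> str:
        try:
            return self.regions[(chain, label)]
        except KeyError:
            raise KeyError(f"unknown position {chain} {label}") from None

    def positions(self) -> Iterator[tuple[str, int, str, str]]:
        """Yield (chain, index, label, parent residue) over both chains."""
        for chain in CHAINS:
            seq = self.chain_sequence(chain)
            for i, lab in enumerate(self.chain_labels(chain)):
                yield chain, i, lab, seq[i]

    @property
    def n_positions(self) -> int:
        return len(self.vh_sequence) + len(self.vl_sequence)

    def mutation(self, chain: str, label: str, variant_aa: str) -> Mutation:
        """Construct a substitution at a labelled position."""
        index = self.index_of(chain, label)
        return Mutation(
            chain, index, label, self.chain_sequence(chain)[index], variant_aa
        )


@dataclass(frozen=True)
class VariantRecord:
    """A clone: variant chain sequences plus derived mutations and count."""

    id: str
    vh_sequence: str
    vl_sequence: str
    mutations: Genotype
    count: int = 1

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("count must be >= 1")

    @classmethod
    def from_sequences(
        cls,
        parent: ParentReference,
        vh_sequence: str,
        vl_sequence: str,
        id: str,
        count: int = 1,
    ) -> "VariantRecord":
        muts = call_mutations(parent, vh_sequence, vl_sequence)
        return cls(id, vh_sequence, vl_sequence, muts, count)

    @classmethod
    def from_mutations(
        cls,
        parent: ParentReference,
        mutations: Iterable[Mutation],
        id: str,
        count: int = 1,
    ) -> "VariantRecord":
        genotype = as_genotype(mutations)
        vh, vl = apply_mutations(parent, genotype)
        return cls(id, vh, vl, genotype, count)


def call_mutations(
    parent: ParentReference, vh_sequence: str, vl_sequence: str
) -> Genotype:
    """Call substitutions of a variant against the parent.

    Returns exactly the positions where the residues differ, labelled via
    the parent's numbering map; the empty tuple iff the sequences are
    identical.  The number of returned mutations equals the Hamming
    distance between the concatenated chains.
    """
    muts: list[Mutation] = []
    for chain, variant_seq in (("VH", vh_sequence), ("VL", vl_sequence)):
        parent_seq = parent.chain_sequence(chain)
        if len(variant_seq) != len(parent_seq):
            raise IndelNotSupportedError(
                f"{chain}: variant length {len(variant_seq)} differs from "
                f"parent length {len(parent_seq)}; indels are not supported"
            )
        bad = set(variant_seq) - AA_SET
        if bad:
            raise ValueError(f"{chain}: non-standard residues {bad}")
        labels = parent.chain_labels(chain)
        for i, (p, v) in enumerate(zip(parent_seq, variant_seq)):
            if p != v:
                muts.append(Mutation(chain, i, labels[i], p, v))
    return tuple(muts)


def apply_mutations(
    parent: ParentReference, mutations: Iterable[Mutation]
) -> tuple[str, str]:
    """Apply substitutions to the parent, returning (VH, VL) sequences.

    Round-trips with :func:`call_mutations`: calling mutations on the
    result reproduces the input set.
    """
    genotype = as_genotype(mutations)
    chains = {"VH": list(parent.vh_sequence), "VL": list(parent.vl_sequence)}
    for m in genotype:
        seq = chains[m.chain]
        if seq[m.index] != m.parent_aa:
            raise ValueError(
                f"{m}: parent residue at {m.chain} {m.label} is "
                f"{parent.chain_sequence(m.chain)[m.index]}, not {m.parent_aa}"
            )
        seq[m.index] = m.variant_aa
    return "".join(chains["VH"]), "".join(chains["VL"])


def annotate_region(mutation: Mutation, parent: ParentReference) -> str:
    """Framework/CDR tag of the mutated position."""
    return parent.region_of(mutation.chain, mutation.label)
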