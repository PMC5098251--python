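"""Error-prone library generation and the planted affinity landscape.

Mutagenesis is modelled directly at the amino-acid level: each clone
receives a Poisson-distributed number of substitutions (mean ~1.7 per
scFv for an error-prone library of the kind screened here), at positions
drawn uniformly over both chains without replacement within a clone, and
with substitution targets drawn uniformly over the 19 alternative
residues unless per-residue weights are supplied.

The affinity landscape maps genotypes to an equilibrium dissociation
constant (Kd, nM).  Planted mutation effects are multiplicative
fold-changes on Kd (<1 beneficial).  Two labelled clades of beneficial
mutations bifurcate at one light-chain position; combining beneficial
mutations exclusive to the two clades inflates Kd by a negative-epistasis
penalty.  Unplanted (background) mutations draw a reproducible effect
hashed from their identity: mostly neutral, sometimes mildly deleterious,
rarely mildly beneficial.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .sequence import (
    AA_ALPHABET,
    Genotype,
    Mutation,
    ParentReference,
    VariantRecord,
    apply_mutations,
)

PARENT_KD_NM = 8.6  # nM, default parent scFv affinity


class ConfigError(ValueError):
    """Invalid mutagenesis or landscape configuration."""


@dataclass
class MutagenesisConfig:
    """Error-prone mutagenesis parameters.

    Parameters
    ----------
    mean_mutations
        Mean amino-acid substitutions per clone (Poisson), default 1.7.
    substitution_weights
        Optional mapping ``parent residue -> {target residue: weight}``.
        ``None`` means uniform over the 19 alternatives.
    seed
        Seed for the generator when one is not passed explicitly.
    """

    mean_mutations: float = 1.7
    substitution_weights: Mapping[str, Mapping[str, float]] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.mean_mutations > 0:
            raise ConfigError("mean_mutations must be > 0")
        if self.substitution_weights is not None:
            for parent_aa, weights in self.substitution_weights.items():
                vals = [w for aa, w in weights.items() if aa != parent_aa]
                if any(w < 0 for w in vals) or not any(w > 0 for w in vals):
                    raise ConfigError(
                        f"weights for {parent_aa!r} must be nonnegative and "
                        "not all zero"
                    )


@dataclass
class AffinityLandscape:
    """Planted genotype -> Kd map with two-clade epistatic structure.

    ``effects`` keys are canonical mutation strings (``"VH S25P"``); the
    value is a multiplicative fold-change on Kd (<1 beneficial).  The
    ``clade1``/``clade2`` sets name the beneficial mutations of the two
    lineages; mutations exclusive to one clade interact negatively with
    mutations exclusive to the other (Kd inflated once by
    ``epistasis_penalty`` when a clone mixes them).
    """

    parent_kd: float = PARENT_KD_NM
    effects: dict[str, float] = field(default_factory=dict)
    clade1: frozenset[str] = frozenset()
    clade2: frozenset[str] = frozenset()
    epistasis_penalty: float = 10.0
    background_neutral: float = 0.80
    background_deleterious: float = 0.15
    deleterious_range: tuple[float, float] = (1.0, 5.0)
    beneficial_range: tuple[float, float] = (0.8, 1.0)
    background_seed: int = 0
    _cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.parent_kd <= 0:
            raise ConfigError("parent_kd must be > 0")
        if self.epistasis_penalty < 1:
            raise ConfigError("epistasis_penalty must be >= 1")
        if any(f <= 0 for f in self.effects.values()):
            raise ConfigError("all fold-effects must be > 0")
        missing = (self.clade1 | self.clade2) - set(self.effects)
        if missing:
            raise ConfigError(f"clade mutations without effects: {missing}")

    @property
    def clade1_exclusive(self) -> frozenset[str]:
        return self.clade1 - self.clade2

    @property
    def clade2_exclusive(self) -> frozenset[str]:
        return self.clade2 - self.clade1

    def background_effect(self, mutation_key: str) -> float:
        """Reproducible fold-effect for an unplanted mutation.

        Hashed deterministically from the mutation identity and the
        landscape's background seed, so no full table has to be stored.
        """
        cached = self._cache.get(mutation_key)
        if cached is not None:
            return cached
        digest = hashlib.sha256(
            f"{self.background_seed}:{mutation_key}".encode()
        ).digest()
        u = int.from_bytes(digest[:8], "big") / 2**64
        v = int.from_bytes(digest[8:16], "big") / 2**64
        if u < self.background_neutral:
            fold = 1.0
        elif u < self.background_neutral + self.background_deleterious:
            lo, hi = self.deleterious_range
            fold = lo + (hi - lo) * v
        else:
            lo, hi = self.beneficial_range
            fold = lo + (hi - lo) * v
        self._cache[mutation_key] = fold
        return fold

    def fold(self, mutation_key: str) -> float:
        planted = self.effects.get(mutation_key)
        return planted if planted is not None else self.background_effect(mutation_key)

    def kd(self, mutations: Iterable[Mutation | str]) -> float:
        """Kd in nM of a genotype (parent Kd times all fold-effects)."""
        kd = self.parent_kd
        has_c1 = has_c2 = False
        for m in mutations:
            key = str(m)
            kd *= self.fold(key)
            has_c1 = has_c1 or key in self.clade1_exclusive
            has_c2 = has_c2 or key in self.clade2_exclusive
        if has_c1 and has_c2:
            kd *= self.epistasis_penalty
        return kd


def true_kd(variant: VariantRecord | Genotype, landscape: AffinityLandscape) -> float:
    """Ground-truth Kd (nM) of a clone under the planted landscape."""
    muts = variant.mutations if isinstance(variant, VariantRecord) else variant
    return landscape.kd(muts)


class Pool:
    """A clone pool: unique genotypes with multiplicities.

    The simulator's working container; convertible to/from the
    user-facing :class:`~besdsim.sequence.VariantRecord` representation.
    """

    def __init__(self, genotypes: Sequence[Genotype], counts: Sequence[int]):
        if len(genotypes) != len(counts):
            raise ValueError("genotypes and counts length mismatch")
        if len(genotypes) == 0:
            raise ValueError("empty pool")
        self.genotypes: list[Genotype] = list(genotypes)
        self.counts = np.asarray(counts, dtype=np.int64)
        if (self.counts < 1).any():
            raise ValueError("counts must be >= 1")

    def __len__(self) -> int:
        return len(self.genotypes)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def unique_count(self) -> int:
        return len(self.genotypes)

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / self.counts.sum()

    def parent_frequency(self) -> float:
        """Frequency of the exact-parent genotype (no mutations)."""
        for g, c in zip(self.genotypes, self.counts):
            if not g:
                return float(c) / self.total
        return 0.0

    @classmethod
    def from_genotypes(cls, genotypes: Iterable[Genotype]) -> "Pool":
        tally: dict[Genotype, int] = {}
        for g in genotypes:
            tally[g] = tally.get(g, 0) + 1
        return cls(list(tally.keys()), list(tally.values()))

    @classmethod
    def from_records(cls, records: Iterable[VariantRecord]) -> "Pool":
        tally: dict[Genotype, int] = {}
        for r in records:
            tally[r.mutations] = tally.get(r.mutations, 0) + r.count
        return cls(list(tally.keys()), list(tally.values()))

    def merge(self, other: "Pool") -> "Pool":
        tally: dict[Genotype, int] = {}
        for pool in (self, other):
            for g, c in zip(pool.genotypes, pool.counts):
                tally[g] = tally.get(g, 0) + int(c)
        return Pool(list(tally.keys()), list(tally.values()))

    def to_records(self, parent: ParentReference, prefix: str = "clone") -> list[VariantRecord]:
        records = []
        for i, (g, c) in enumerate(zip(self.genotypes, self.counts)):
            vh, vl = apply_mutations(parent, g)
            records.append(
                VariantRecord(f"{prefix}{i:06d}", vh, vl, g, int(c))
            )
        return records

    def sample_records(
        self, n: int, rng: np.random.Generator, parent: ParentReference,
        prefix: str = "seq",
    ) -> list[VariantRecord]:
        """Draw n clones with replacement, proportional to counts."""
        idx = rng.choice(len(self.genotypes), size=n, p=self.frequencies)
        records = []
        for j, i in enumerate(idx):
            g = self.genotypes[i]
            vh, vl = apply_mutations(parent, g)
            records.append(VariantRecord(f"{prefix}{j:04d}", vh, vl, g, 1))
        return records


# -- mutagenesis -------------------------------------------------------------


def _position_tables(parent: ParentReference):
    """Flat position arrays over both chains for vectorised sampling."""
    chains, indices, labels, parent_aas = [], [], [], []
    for chain, i, lab, aa in parent.positions():
        chains.append(chain)
        indices.append(i)
        labels.append(lab)
        parent_aas.append(aa)
    aa_index = {aa: k for k, aa in enumerate(AA_ALPHABET)}
    parent_aa_idx = np.array([aa_index[a] for a in parent_aas])
    return chains, indices, labels, parent_aas, parent_aa_idx


def _rng_from(config: MutagenesisConfig, rng: np.random.Generator | None):
    if rng is not None:
        return rng
    return np.random.default_rng(config.seed)


def _sample_clone_positions(
    k: int, n_positions: int, rng: np.random.Generator
) -> np.ndarray:
    # without replacement within a clone; k << n_positions so rejection
    # sampling on the rare duplicate is cheaper than permutation
    pos = rng.integers(0, n_positions, size=k)
    while len(np.unique(pos)) < k:
        pos = rng.integers(0, n_positions, size=k)
    return pos


def _mutate_once(
    base: dict[tuple[str, int], Mutation] | None,
    pos: np.ndarray,
    offsets: np.ndarray,
    tables,
    parent: ParentReference,
    config: MutagenesisConfig,
    rng: np.random.Generator,
) -> Genotype:
    """Apply fresh substitutions at flat positions ``pos`` to a base genotype."""
    chains, indices, labels, parent_aas, _ = tables
    current: dict[tuple[str, int], Mutation] = dict(base) if base else {}
    for p, off in zip(pos, offsets):
        chain, idx, lab, parent_aa = chains[p], indices[p], labels[p], parent_aas[p]
        key = (chain, idx)
        existing = current.get(key)
        cur_aa = existing.variant_aa if existing is not None else parent_aa
        if config.substitution_weights is None:
            cur_idx = AA_ALPHABET.index(cur_aa)
            new_aa = AA_ALPHABET[(cur_idx + 1 + off) % 20]
        else:
            weights = config.substitution_weights.get(cur_aa)
            if weights is None:
                cur_idx = AA_ALPHABET.index(cur_aa)
                new_aa = AA_ALPHABET[(cur_idx + 1 + off) % 20]
            else:
                targets = [a for a in weights if a != cur_aa]
                w = np.array([weights[a] for a in targets], dtype=float)
                new_aa = targets[rng.choice(len(targets), p=w / w.sum())]
        if new_aa == parent_aa:  # reversion to parent removes the mutation
            current.pop(key, None)
        else:
            current[key] = Mutation(chain, idx, lab, parent_aa, new_aa)
    return tuple(sorted(current.values(), key=lambda m: (m.chain, m.index)))


def generate_library(
    parent: ParentReference,
    n_clones: int,
    config: MutagenesisConfig | None = None,
    rng: np.random.Generator | None = None,
) -> Pool:
    """Generate an error-prone library of ``n_clones`` clones.

    Per-clone substitution counts are Poisson with mean
    ``config.mean_mutations``; positions are uniform over both chains
    without replacement within a clone.  Deterministic under a fixed
    seed.
    """
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    config = config or MutagenesisConfig()
    rng = _rng_from(config, rng)
    tables = _position_tables(parent)
    n_pos = parent.n_positions

    ks = rng.poisson(config.mean_mutations, size=n_clones)
    np.minimum(ks, n_pos, out=ks)
    tally: dict[Genotype, int] = {}
    for k in ks:
        if k == 0:
            g: Genotype = ()
        else:
            pos = _sample_clone_positions(int(k), n_pos, rng)
            offsets = rng.integers(0, 19, size=int(k))
            g = _mutate_once(None, pos, offsets, tables, parent, config, rng)
        tally[g] = tally.get(g, 0) + 1
    return Pool(list(tally.keys()), list(tally.values()))


def rerandomize(
    pool: Pool,
    parent: ParentReference,
    n_clones: int,
    config: MutagenesisConfig | None = None,
    rng: np.random.Generator | None = None,
) -> Pool:
    """Re-mutagenise a selected pool (error-prone pass on the survivors).

    Each output clone is a clone sampled from the input pool
    (proportional to count) carrying a fresh Poisson-distributed set of
    additional substitutions.  A fresh substitution landing on an
    already-mutated position substitutes the current residue (and drops
    the mutation if it reverts to the parent).
    """
    if len(pool) == 0:
        raise ValueError("empty pool")
    config = config or MutagenesisConfig()
    rng = _rng_from(config, rng)
    tables = _position_tables(parent)
    n_pos = parent.n_positions
    base_dicts = [{(m.chain, m.index): m for m in g} for g in pool.genotypes]

    src = rng.choice(len(pool.genotypes), size=n_clones, p=pool.frequencies)
    ks = rng.poisson(config.mean_mutations, size=n_clones)
    np.minimum(ks, n_pos, out=ks)
    tally: dict[Genotype, int] = {}
    for i, k in zip(src, ks):
        if k == 0:
            g = pool.genotypes[i]
        else:
            pos = _sample_clone_positions(int(k), n_pos, rng)
            offsets = rng.integers(0, 19, size=int(k))
            g = _mutate_once(
                base_dicts[i], pos, offsets, tables, parent, config, rng
            )
        tally[g] = tally.get(g, 0) + 1
    return Pool(list(tally.keys()), list(tally.values()))
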