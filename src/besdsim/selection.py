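"""One bead-display selection round and the full multi-round campaign.

A round mirrors the wet workflow: clones are encapsulated onto beads
under Poisson single-occupancy statistics, each occupied bead displays
its clone at the display ceiling, beads are incubated with fluorescent
antigen, and a FACS gate recovers the genotypes of beads whose
fluorescence clears a quantile threshold.  The first round uses a
permissive gate referenced to a parent-only population (top 3% of the
parent distribution); later rounds gate on the top fraction (0.5%) of
the library itself.  DNA recovery and re-amplification are modelled as
exact: selected genotypes carry their selected counts into the next
round.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .binding import BindingParams, simulate_mfs
from .library import (
    AffinityLandscape,
    MutagenesisConfig,
    Pool,
    generate_library,
    rerandomize,
)
from .sequence import Genotype, ParentReference

#: Poisson mean giving a 30% bead occupancy (the DNA-bearing fraction the
#: single-template dilution aims for): 1 - exp(-lambda) = 0.3.
LAMBDA_30PCT_OCCUPANCY = -math.log(0.7)


class EmptySelectionError(RuntimeError):
    """No occupied bead passed the gate."""


def derive_seed(master: int, stage: str) -> int:
    """Stable per-stage seed below 2**31, hashed from the stage name."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RoundConfig:
    """Configuration of one selection round."""

    n_beads: int = 150_000
    lambda_occupancy: float = LAMBDA_30PCT_OCCUPANCY
    gate_mode: str = "library_top"  # or "parent_reference"
    gate_fraction: float = 0.005
    antigen_conc: float = 1.0
    seed: int | None = None
    template_copy_range: tuple[int, int] = (100, 1000)
    display_copies: float = 1e6
    include_multi_template: bool = False
    binding: BindingParams = field(default_factory=BindingParams)

    def __post_init__(self) -> None:
        if not 0 < self.gate_fraction < 1:
            raise ValueError("gate_fraction must be in (0, 1)")
        if self.lambda_occupancy <= 0:
            raise ValueError("lambda_occupancy must be > 0")
        if self.gate_mode not in ("parent_reference", "library_top"):
            raise ValueError(f"unknown gate_mode {self.gate_mode!r}")


@dataclass
class BeadPopulation:
    """Simulated beads: genotype assignment, copies, and fluorescence.

    ``genotype_index`` is -1 for empty beads, otherwise an index into
    ``pool.genotypes``.  Beads with two or more templates are flagged and
    excluded from sorting unless the round allows mixed display.
    """

    pool: Pool
    genotype_index: np.ndarray
    n_templates: np.ndarray
    template_copies: np.ndarray
    display_copies: np.ndarray
    fluorescence: np.ndarray | None = None

    @property
    def n_beads(self) -> int:
        return len(self.genotype_index)

    @property
    def occupied(self) -> np.ndarray:
        return self.n_templates >= 1

    @property
    def single_template(self) -> np.ndarray:
        return self.n_templates == 1

    @property
    def multi_template(self) -> np.ndarray:
        return self.n_templates >= 2


@dataclass
class RoundResult:
    """Outcome of one round: gate, realized fraction, recovered pool."""

    config: RoundConfig
    gate_threshold: float
    sorted_fraction: float
    recovered_pool: Pool
    stats: dict


def encapsulate(
    pool: Pool,
    config: RoundConfig,
    rng: np.random.Generator | int | None = None,
) -> BeadPopulation:
    """Distribute templates onto beads under Poisson occupancy.

    Per-bead template counts are Poisson(lambda_occupancy); occupied
    beads get a genotype sampled proportional to pool counts, template
    copies uniform within the configured range, and display copies at
    the ceiling.
    """
    if len(pool) == 0:
        raise ValueError("empty pool")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n_templates = rng.poisson(config.lambda_occupancy, size=config.n_beads)
    occupied = n_templates >= 1
    genotype_index = np.full(config.n_beads, -1, dtype=np.int64)
    n_occ = int(occupied.sum())
    if n_occ:
        genotype_index[occupied] = rng.choice(
            len(pool.genotypes), size=n_occ, p=pool.frequencies
        )
    lo, hi = config.template_copy_range
    template_copies = np.zeros(config.n_beads, dtype=np.int64)
    template_copies[occupied] = rng.integers(lo, hi + 1, size=n_occ)
    display = np.where(occupied, config.display_copies, 0.0)
    return BeadPopulation(
        pool, genotype_index, n_templates, template_copies, display
    )


def sort_gate(
    fluorescence_values,
    reference_values,
    config: RoundConfig,
) -> float:
    """Gate threshold (AFU) for a round.

    ``parent_reference`` mode thresholds at the (1 - gate_fraction)
    quantile of the reference (parent) population; ``library_top`` mode
    uses the library's own values.  Empirical quantile with 'higher'
    interpolation, so the threshold is always an observed value.
    """
    values = np.asarray(fluorescence_values, dtype=float)
    if values.size == 0:
        raise ValueError("empty fluorescence values")
    if config.gate_mode == "parent_reference":
        ref = np.asarray(reference_values, dtype=float)
        if ref.size == 0:
            raise ValueError("empty reference values")
        basis = ref
    else:
        basis = values
    return float(
        np.quantile(basis, 1.0 - config.gate_fraction, method="higher")
    )


def select_above(
    values: np.ndarray,
    threshold: float,
    target_count: int | None = None,
) -> np.ndarray:
    """Indices of values passing the gate.

    All values strictly above the threshold are selected; when a target
    count is given (library-top gating), values tied with the threshold
    are added in stable bead order until the target is reached.
    """
    above = np.flatnonzero(values > threshold)
    if target_count is None or len(above) >= target_count:
        return above
    ties = np.flatnonzero(values == threshold)
    need = target_count - len(above)
    return np.sort(np.concatenate([above, ties[:need]]))


def _bead_fluorescence(
    beads: BeadPopulation,
    kd_by_genotype: np.ndarray,
    config: RoundConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Fluorescence for every bead; empty beads are background-only."""
    params = replace(config.binding, antigen_conc=config.antigen_conc)
    kds = np.where(
        beads.occupied, kd_by_genotype[beads.genotype_index], 1.0
    )
    mfs = simulate_mfs(kds, params, rng)
    if (~beads.occupied).any():
        # empty beads: no displayed protein, background-only signal
        from .binding import lognormal_noise

        n_empty = int((~beads.occupied).sum())
        mfs[~beads.occupied] = params.background_mfs * lognormal_noise(
            n_empty, params.noise_cv, rng
        )
    return mfs


def run_round(
    pool: Pool,
    landscape: AffinityLandscape,
    config: RoundConfig,
    rng: np.random.Generator | int | None = None,
) -> RoundResult:
    """Run one selection round: encapsulate, measure, gate, recover."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(config.seed if rng is None else rng)
    beads = encapsulate(pool, config, rng)
    kd_by_genotype = np.array([landscape.kd(g) for g in pool.genotypes])
    beads.fluorescence = _bead_fluorescence(beads, kd_by_genotype, config, rng)

    sortable = (
        beads.occupied if config.include_multi_template
        else ~beads.multi_template
    )
    values = beads.fluorescence[sortable]
    if config.gate_mode == "parent_reference":
        ref_beads = encapsulate(
            Pool([()], [1]), config, rng
        )
        ref_kd = np.array([landscape.parent_kd])
        ref_mfs = _bead_fluorescence(ref_beads, ref_kd, config, rng)
        ref_values = ref_mfs[ref_beads.single_template]
        threshold = sort_gate(values, ref_values, config)
        sel_local = select_above(values, threshold)
    else:
        threshold = sort_gate(values, None, config)
        target = max(1, int(np.floor(values.size * config.gate_fraction)))
        sel_local = select_above(values, threshold, target)

    sortable_idx = np.flatnonzero(sortable)
    selected = sortable_idx[sel_local]
    selected = selected[beads.genotype_index[selected] >= 0]
    if selected.size == 0:
        raise EmptySelectionError(
            f"no occupied bead passed the gate at threshold {threshold:.3g}"
        )
    sorted_fraction = sel_local.size / values.size

    gidx, counts = np.unique(beads.genotype_index[selected], return_counts=True)
    recovered = Pool([pool.genotypes[i] for i in gidx], counts)
    weights = recovered.counts / recovered.total
    stats = {
        "n_selected": int(selected.size),
        "mean_true_kd": float(np.dot(kd_by_genotype[gidx], weights)),
        "min_true_kd": float(kd_by_genotype[gidx].min()),
        "parent_frequency": recovered.parent_frequency(),
        "unique_sequences": recovered.unique_count,
    }
    return RoundResult(config, threshold, sorted_fraction, recovered, stats)


def qpcr_copies_per_bead(
    copies_per_reaction: float,
    n_beads: int,
    correction: float = 0.3,
    per_occupied_bead: bool = False,
    occupied_fraction: float | None = None,
) -> float:
    """Template copies per bead from a qPCR reaction.

    As-published mode divides by the bead count and multiplies by the
    Poisson occupancy correction factor (default 0.3).  The alternative
    per-occupied-bead mode instead divides by the occupied fraction,
    giving copies per DNA-bearing bead.
    """
    if copies_per_reaction <= 0 or n_beads <= 0:
        raise ValueError("copies_per_reaction and n_beads must be > 0")
    if per_occupied_bead:
        frac = occupied_fraction if occupied_fraction is not None else correction
        if not 0 < frac <= 1:
            raise ValueError("occupied fraction must be in (0, 1]")
        return copies_per_reaction / (n_beads * frac)
    return copies_per_reaction / n_beads * correction


# -- campaign ----------------------------------------------------------------


def default_plan(
    n_rounds: int = 4,
    n_beads: int = 150_000,
    antigen_conc: float = 1.0,
) -> list[RoundConfig]:
    """The default round plan: permissive parent-referenced 3% gate in
    round I, top-0.5% library gates thereafter."""
    rounds = [
        RoundConfig(
            n_beads=n_beads,
            gate_mode="parent_reference",
            gate_fraction=0.03,
            antigen_conc=antigen_conc,
        )
    ]
    rounds += [
        RoundConfig(
            n_beads=n_beads,
            gate_mode="library_top",
            gate_fraction=0.005,
            antigen_conc=antigen_conc,
        )
        for _ in range(n_rounds - 1)
    ]
    return rounds


@dataclass
class CampaignPlan:
    """A selection campaign: library, round plan, re-randomisation points."""

    rounds: list[RoundConfig] = field(default_factory=default_plan)
    mutagenesis: MutagenesisConfig = field(default_factory=MutagenesisConfig)
    library_size: int = 150_000
    rerandomize_after: tuple[int, ...] = (2,)  # 1-based round numbers

    def __post_init__(self) -> None:
        if not self.rounds:
            raise ValueError("round plan must not be empty")
        if self.library_size < 1:
            raise ValueError("library_size must be >= 1")


@dataclass
class CampaignResult:
    """All per-round results plus the final recovered pool."""

    rounds: list[RoundResult]
    final_pool: Pool
    master_seed: int | None

    def stats_frame(self) -> pd.DataFrame:
        rows = []
        for i, r in enumerate(self.rounds, start=1):
            rows.append(
                {
                    "round": i,
                    "gate_threshold": r.gate_threshold,
                    "sorted_fraction": r.sorted_fraction,
                    **r.stats,
                }
            )
        return pd.DataFrame(rows)


def run_campaign(
    parent: ParentReference,
    landscape: AffinityLandscape,
    plan: CampaignPlan | None = None,
    master_seed: int | None = None,
    initial_pool: Pool | None = None,
) -> CampaignResult:
    """Run the full selection campaign.

    Rounds are chained: each round's recovered pool feeds the next.
    After every round listed in ``plan.rerandomize_after`` the pooled
    output of all rounds so far is re-mutagenised into a fresh library.
    Deterministic and reproducible bit-for-bit under a fixed master seed
    (per-stage seeds are hashed from stage names).
    """
    plan = plan or CampaignPlan()
    seed = 0 if master_seed is None else master_seed

    if initial_pool is None:
        lib_rng = np.random.default_rng(derive_seed(seed, "library"))
        pool = generate_library(
            parent, plan.library_size, plan.mutagenesis, lib_rng
        )
    else:
        pool = initial_pool

    results: list[RoundResult] = []
    for i, config in enumerate(plan.rounds, start=1):
        rng = np.random.default_rng(
            config.seed if config.seed is not None
            else derive_seed(seed, f"round{i}")
        )
        result = run_round(pool, landscape, config, rng)
        results.append(result)
        pool = result.recovered_pool
        if i in plan.rerandomize_after and i < len(plan.rounds):
            merged = results[0].recovered_pool
            for r in results[1:]:
                merged = merged.merge(r.recovered_pool)
            rer_rng = np.random.default_rng(derive_seed(seed, f"rerand{i}"))
            pool = rerandomize(
                merged, parent, plan.library_size, plan.mutagenesis, rer_rng
            )
    return CampaignResult(results, pool, master_seed)
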