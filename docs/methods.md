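# Methods

This document defines the models implemented in `besdsim`, the default
parameter values and the reasons for them, what the synthetic data generator
does and does not reproduce, and the numerical choices that matter.

## Sequence model

An scFv is represented as two amino-acid chains, VH and VL. Positions are
addressed internally by 0-based index and externally by opaque scheme labels
(Kabat-style strings, insertion codes such as `95a` included). Labels are
data supplied with the parent reference and are never parsed numerically;
ordering comes from the numbering map. Every position carries a
framework/CDR region tag.

The variant model is substitution-only. Variant chains must match the parent
chain lengths; insertions and deletions raise `IndelNotSupportedError`.
Consequently `call_mutations` ∘ `apply_mutations` is an exact round trip, and
the number of called mutations equals the Hamming distance between the
concatenated chains.

The packaged parent (`synthetic_parent`) is a deterministic pseudo-random
scaffold — VH of 118 residues (Kabat 1–113 plus insertions 52a, 82a–c, 100a)
and VL of 109 residues (1–107 plus 27a, 95a) — with the residues addressed by
the default landscape fixed (VH G8, L20, S25, V102, G104; VL I28, Y50, F55,
K95a). It is a stand-in, not a real antibody sequence; all code treats the
parent as data, so a real reference (FASTA + numbering TSV) can be swapped
in.

## Mutagenesis model

Error-prone mutagenesis is modelled directly at the protein level. Each
clone receives `k ~ Poisson(mean_mutations)` substitutions, positions drawn
uniformly over both chains without replacement within a clone, and targets
uniform over the 19 alternative residues (optional per-residue weight tables
are supported). The default mean is **1.7 substitutions per scFv**, the
mutation load of the error-prone library modelled here.

Modelling at the amino-acid rather than nucleotide level is a deliberate
simplification: it makes the mutation load an explicit, directly testable
parameter, at the cost of ignoring codon structure (transition/transversion
bias, codon-accessible substitution sets). The uniform-19 target choice makes
the generator's statistics exactly computable for tests.

Re-randomisation (`rerandomize`) re-mutagenises a selected pool: each output
clone is drawn from the pool proportionally to count and receives a fresh
Poisson(1.7) set of substitutions; a substitution landing on an
already-mutated position replaces the current residue and a reversion to the
parent residue removes the mutation.

## Affinity landscape

Genotype → Kd is multiplicative:

    Kd(g) = parent_kd × Π fold(m) × (epistasis_penalty if cross-clade)

- `parent_kd` defaults to **8.6 nM**.
- Planted beneficial mutations form two clades. Clade 1 (serine lineage):
  VH S25P (0.25×), VH V102N, VH G104D, VL I28T, VL Y50S (0.25×), VL F55L,
  VL K95aE (all others 0.70×) — the full set is worth ~95-fold, the scale of
  the consensus variant's measured gain, with the two anchors at 4-fold
  matching measured single-mutant gains. Clade 2 (histidine lineage) shares
  VH S25P and bifurcates at VL 50: VH G8S (0.95×), VH L20I (0.95×),
  VL Y50H (0.45×).
- Mixing mutations exclusive to the two clades multiplies Kd once by the
  `epistasis_penalty` (default 10×), making the lineages mutually exclusive
  under selection — the mechanism behind the serine/histidine bifurcation.
- Unplanted mutations receive a deterministic background effect hashed
  (SHA-256) from the mutation string and a background seed: 80% exactly
  neutral, 15% deleterious (uniform 1–5×), 5% weakly beneficial
  (uniform 0.8–1.0×). Hashing avoids storing a full 227×19 effect table
  while keeping every clone's Kd reproducible across processes.

## Binding and measurement model

Equilibrium occupancy follows the 1:1 Langmuir isotherm, `θ = L/(Kd + L)`,
with ligand depletion ignored (valid in the bead regime: ≤10^6 sites per
bead against a vast antigen reservoir). Per-bead fluorescence is

    MFS = (background + span × θ) × ε,   ε ~ lognormal, E[ε] = 1, CV = 0.13

with defaults background 2 AFU, span 2000 AFU. The 13% multiplicative CV is
the replicate scatter of normalised on-bead measurements. Empty beads emit
background-only noise.

### Titration fitting

`fit_titration` fits `y = Bmax · L/(Kd + L)` to responses normalised by
their maximum. Because the noise model is multiplicative log-normal, the
least squares is performed **on the logarithms of the responses** — the
maximum-likelihood estimator under the package's own noise model. This
matters: unweighted linear least squares lets the brightest points dominate
(their absolute noise is ~40× the dimmest points'), wastes the information
in the low-concentration points and inflates the replicate scatter of the
fitted Kd from ~12% to ~30%. With the log-domain fit, 50 replicate
titrations of the parent (true Kd 4.3 nM, 8 threefold-spaced concentrations
0.1–218.7 nM) recover a mean fitted Kd of ~4.2 nM with a replicate relative
SD of ~12%.

The plateau `Bmax` is fitted jointly with Kd by default, as saturation
binding software conventionally does; the top concentration (218.7 nM) is
sub-saturating (θ ≈ 0.98), so fixing the scale at 1
(`float_amplitude=False`) is biased and provided only for comparison. The
fit ignores the small additive background (0.1% of span), which depresses
the recovered Kd by ~2% — far inside the reported uncertainty. If any
response or concentration is non-positive the fit falls back to linear
residuals.

### Kinetics

`kd_from_rates` computes `Kd = koff/kon` with rates in the units binding
tables conventionally print (kon in 1e5 /M/s, koff in 1e-4 /s); the unit
ratio is exactly 1 nM, so the numeric ratio is already in nM.
`kd_gain(parent, variant) = parent/variant`.

## Selection model

One round (`run_round`):

1. **Encapsulation** — per-bead template counts are
   Poisson(λ = −ln 0.7 ≈ 0.357), giving 30% occupied beads, the fraction a
   single-template dilution targets. Occupied beads draw a genotype
   proportionally to pool counts and a template copy number uniform in
   100–1000; displayed protein sits at the 10^6-copy ceiling.
2. **Measurement** — every bead gets an MFS draw as above; beads carrying
   two or more templates (mixed display) are excluded from sorting by
   default.
3. **Gating** — `parent_reference` mode (round I) thresholds at the
   (1 − f) quantile of a simulated parent-only population with f = 3%;
   `library_top` mode (later rounds) takes the library's own top
   f = 0.5%, selecting strictly-above beads plus threshold ties in bead
   order up to the target count. Quantiles use the 'higher' empirical
   method so thresholds are always observed values.
4. **Recovery** — selected occupied beads contribute their genotypes with
   multiplicity; DNA recovery and re-amplification are treated as exact.

The default campaign (`CampaignPlan`) is a 150,000-clone library, four
rounds at 1 nM antigen on 150,000 beads (permissive 3% parent-referenced
gate, then three 0.5% library-top gates) with re-randomisation after round
II. A realised round-I sorted fraction below the nominal 3% is expected:
the gate is referenced to the parent population, while ~70% of the measured
events are empty background-only beads.

`qpcr_copies_per_bead` implements the template quantification arithmetic:
copies per reaction divided by bead count times the 0.3 occupancy correction
(as conventionally reported), or per-occupied-bead normalisation as an
alternative mode.

All stage seeds are derived from one master seed by hashing the stage name
(SHA-256, reduced below 2^31), so runs are bit-for-bit reproducible and
stages are statistically independent.

## Sequence analysis

- **Frequency table** — exact per-position mutated fractions; clones
  weighted by multiplicity (as deep sequencing of an output would be).
- **Hotspots** — positions mutated in strictly more than 20% of sequences.
- **Dominance** — at each hotspot, a substitution is dominant when it
  contributes >80% of the mutations there; otherwise the position is
  reported as bifurcated with all residues at ≥20% share (e.g. VL 50
  splitting ~54% S / ~46% H in the packaged fixture).
- **Tree** — neighbour joining (scikit-bio) on pairwise Hamming distances
  between unique sequences, midpoint-rooted. This is a distance tree used
  only to split well-separated lineages, not a likelihood phylogeny; the
  Newick output lets users substitute an external tree. NJ reproduces
  additive distance matrices exactly, which the tests exploit.
- **Clades** — k = 2 takes the two subtrees flanking the midpoint root;
  k > 2 cuts the longest internal edges. Unique sequences get
  deterministic ids ordered by genotype so results are input-order
  invariant.
- **Consensus** — per clade, every residue-specific mutation carried by
  strictly more than 20% of the clade's **unique** sequences joins the
  design; competing substitutions at one position resolve to the more
  frequent, and exact ties raise an error rather than guessing. The
  assembled variant and (in simulation mode) its landscape-predicted Kd are
  returned.

Overall frequencies use multiplicities while clade consensus uses unique
sequences: the former mirrors sequencing read counting, the latter prevents
a single heavily amplified clone from dictating a clade's design.

## What the synthetic data does and does not reproduce

The generator reproduces the *statistical shape* of a real campaign at desk
scale: mutation-load distribution, Poisson bead occupancy, occupancy-driven
enrichment, hotspot structure with a bifurcated position, two well-separated
clades, and titration noise. It does **not** reproduce:

- nucleotide-level mutation spectra (amino-acid-level Poisson instead);
- PCR amplification bias, sequencing errors, or chain shuffling;
- ligand depletion, avidity from multivalent display, off-rate selection
  dynamics during washes (equilibrium occupancy only);
- real antibody sequence statistics (the parent is a random scaffold with
  pinned anchor residues);
- wet-lab library complexity: the simulated library (1.5 × 10^5 clones) is
  orders of magnitude smaller than a real transformation, with consequences
  described below.

## Limitations

**Consensus-scale recovery is supply-limited at desk scale.** With a mean
load of 1.7 substitutions over 227 positions and uniform targets, any
*specific* planted substitution occurs in a clone with probability
≈ 1.7/227/19 ≈ 4 × 10⁻⁴, so a 150,000-clone library contains ~60 copies of
each planted single mutant and only a handful of planted doubles. Four
rounds of selection (plus one re-randomisation pass) therefore converge on
the best available double mutants — typically the two 4-fold anchors — and
cannot assemble seven-mutation genotypes, nor push six partner mutations
each above 20% within a clade (their within-clade frequencies sum to roughly
the mean planted load, ~1). Two consequences, both verified over a
20-campaign ensemble (`tests/test_acceptance.py`, criterion 5):

- the full planted clade-1 set is essentially never recovered as the
  consensus of a simulated campaign output (0/20 runs), and
- the consensus design beats the best selected clone only when both anchors
  clear the within-clade threshold together (9/20 runs).

Parent die-off under the stringent gates, by contrast, is robust (20/20
runs non-increasing). Recovering the full consensus set in simulation
would require library sizes and inter-round recombination far beyond desk
scale; the packaged round-IV *fixture* (which plants realistic output
frequencies directly) exists precisely to test the analysis stage in the
regime the wet experiment reaches. The corresponding acceptance test is
left failing rather than weakened, because it documents a real scale gap,
not a bug.

**Other numerical notes.**

- Quantile gates use the 'higher' method so a gate is always an observed
  fluorescence value, and tie handling is deterministic (bead order).
- NJ branch lengths can go slightly negative on noisy distance matrices;
  they are clipped to zero before midpoint rooting.
- Background landscape effects are hashed per mutation string; changing the
  background seed changes every unplanted effect coherently.
- Campaign stage seeds are independent hashes of the master seed, so
  results never depend on the order in which stages consume random numbers.
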