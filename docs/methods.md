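# Methods

This note documents the model implemented by `evocross`, the numerical and
design choices made where the model description leaves room, and what the
bundled experiments do and do not show.

## Genome and mutational operators

A genome is a circular sequence of typed units. Every unit stores the full
attribute tuple `(unit_type, beta, s, p, kcat, kcat_over_km)` whatever its
type; attributes irrelevant to the current type drift neutrally and become
functional again on a type transition. Functional regions are maximal P-(E)+
runs found by circular scan (operons); the first non-E unit ends a region, so
a promoter can never be its own operon member and a region holds at most
L − 1 enzymes.

Initial genomes hold 50 units — 10 P, 10 E, 30 NC at uniformly random
positions — with β ~ U[0, 1], tags uniform on **1..10**, |k_cat| and
k_cat/K_M log-uniform on their ranges and the k_cat sign a fair coin. The
initial tag range is a config parameter (`genome.tag_init_max`); 1..10 places
the primary resource #10 and the small primes inside the initially reachable
chemistry, which is what makes the viability-seeding lottery winnable at all.
No upper bound is imposed on tags afterwards; they random-walk by ±1
mutations.

Point mutations (rate 10⁻³ per attribute per replication): tags move ±1 with
reflection at the lower bound 1 (a decrement at 1 becomes an increment, so
tags stay in ℕ*); β gains a N(0, 0.1²) increment clamped to [0, 1]; the
decimal logs of |k_cat| and k_cat/K_M gain N(0, 0.1²) increments clamped to
their ranges. Out-of-range proposals are clamped to the boundary (the simplest
monotone rule that keeps the stated invariants literally true). The sign of
k_cat is preserved by default — log-space mutation is undefined for negative
values, so a pump cannot reverse direction by point mutation; a config switch
(`genome.allow_kcat_sign_flip`) enables sign flips for sensitivity work.
Type transitions (rate 10⁻³ per unit) redraw the type uniformly among the two
other types.

Rearrangements: per replication, each of duplication, deletion, translocation
and inversion draws an event count Binomial(L, 10⁻³) with L the parental
length (equivalent in law to independent per-unit draws, cheaper). The four
counts are then applied as a **randomly interleaved** event sequence, each
event drawing two uniform breakpoints on the current circle (equal
breakpoints delimit an empty segment: a structural no-op). Interleaving
matters: applying all duplications before any deletion lets consecutive
duplications compound multiplicatively within a single replication and can
blow a large genome up by orders of magnitude before deletions act; under
interleaving the log-length increments of duplications (E ≈ +0.39 per event)
and deletions (E ≈ −1 per event) mix and large genomes contract on average.

Breakpoints "break" the units flanking them: at each breakpoint gap, each of
the six attributes (including the type, as the unit tuple is exchanged
attribute-wise) swaps between the two flanking units with probability 10⁻³.
Deletion and inversion expose 2 such junctions (their two breakpoints),
duplication 3 (two cut points plus the insertion gap), translocation 4 (two
cut points, the closure junction of the excision gap, and the insertion gap).

Replication order is fixed: rearrangements first, then point mutations; each
daughter is an independent replicate of the parent.

## Metabolism and kinetics

Expression gives one protein species per E unit inside a region, each with its
promoter's full β (operon members are not diluted; a config-free design choice
— the alternative of splitting β across members would only rescale evolved
β values). K_M is derived as |k_cat| / (k_cat/K_M) and never stored. Enzymes
transform internal *s* into internal *p*; pumps (s = p) move that metabolite
between the cell and its grid spot, inward when k_cat > 0.

All rates (β, φ, k_cat) are per centi-time-step, with 100 centi-time-steps per
ecological time-step. Integration uses the embedded 4th/5th-order
Runge–Kutta–Cash–Karp pair with error-per-step control at rel_tol = 10⁻⁶,
abs_tol = 10⁻⁹, initial step 0.1 centi-time-step. These tolerances are a
package choice (they keep total metabolite mass conserved to < 10⁻⁶ over a
50-step closed run; Runge–Kutta methods conserve the linear mass invariant
exactly up to round-off, so the observed drift is pure floating-point error).
Tiny negative excursions (< 10⁻⁶ ACU in magnitude) are floored at zero after
each accepted step; larger negativity or step underflow raises an integration
error carrying the organism id.

**Merged-species integration.** Exact gene copies (identical β, reaction and
kinetics — the immediate product of duplications) are merged for integration:
the merged concentration obeys d[S]/dt = kβ − φS and carries the summed flux,
which leaves every metabolite trajectory unchanged (flux additivity, verified
against an unmerged reference integration in the tests). Per-copy
concentrations are recovered exactly afterwards from the closed form
β/φ + (c₀ − β/φ)e^{−φt}, valid because protein dynamics are linear and
independent of the metabolites. Without merging, evolved genomes with heavy
gene amplification make per-organism systems intractably large; with it the
system size tracks the number of *distinct* species. Copies diverge into
distinct species as soon as a point mutation touches any attribute.

Organisms whose reactions can carry no flux from the current state (checked by
a cheap reachability pass) skip the integrator entirely; their proteins relax
in closed form. Per-time-step fluxes (pump inflow, pump outflow, gross
enzymatic production, per tag) are integrated as additional quadrature state
variables, so trophic profiles use exact integrals rather than sampled rates.

The score is the summed internal concentration of prime-tag metabolites
(primality via sympy). Toxicity applies to **internal** concentrations only
(release into the environment is never lethal); the threshold is 1.0 ACU for
every metabolite.

## Ecology

The world is a toroidal grid, one organism per spot, with a dense per-spot
external concentration vector over tags 1..max_tag (the universe grows lazily
as mutation creates new tags). A time-step executes: (1) protocol event;
(2) per-organism integration (spot-local external pools are part of each
organism's system and are written back); (3) score and trophic-profile
update; (4) deaths — lethal toxicity, plus an independent random event of
probability p_death = 0.02 per organism per step ("Poisson law of parameter
p_death" is read as this plain per-step probability; the alternative
1 − e^{−p_death} ≈ 0.0198 is a config switch) — with the dead cell's
metabolites (not its proteins) released into its spot; (5) divisions: empty
spots in randomized order, each won by the highest-scoring Moore neighbour
with score ≥ 10⁻³ that has not divided this step (ties uniform); the parent is
replaced by two daughters (one in situ, one in the empty spot), each daughter
receiving exactly half of each metabolite, half of each protein (matched by
species attribute tuple; a species absent from a mutated daughter's own
expression starts at zero) and an independently mutated genome replicate;
(6) optional migration (Binomial(n_pairs, rate) occupant swaps, or a full
occupancy permutation in the well-mixed mode); (7) simultaneous 8-neighbour
diffusion, each spot keeping 1 − 8D and receiving D of each neighbour
(D = 0.1; exact mass conservation); (8) degradation by the regime's D_g.
This phase order is fixed for reproducibility; a config switch moves diffusion
before divisions for sensitivity checks. Randomness flows from two named PCG64
streams (mutational/death draws vs spot ordering and tie-breaks), and a
(seed, config) pair fully determines a trajectory — checkpoint/resume through
the JSON backup is bit-identical, which the tests assert.

Divisions and deaths are recorded exhaustively in a binary phylogeny; pruning
removes extinct subtrees and contracts unary chains while preserving
along-lineage division counts.

## Protocols and seeding

Periodic: at t ≡ 0 (mod 333) all external pools are zeroed and `m_exo` = #10
set to 10.0 ACU per spot; internal pools untouched; D_g = 0 within cycles.
Continuous: 0.03 ACU of #10 added per spot per step; D_g = 0.003; worlds start
at the steady-state concentration 0.03/0.003 = 10 ACU. Over one 333-step
period the two regimes supply the same resource within 0.1%. Random periodic:
reset intervals drawn as max(1, Poisson(333)) — small coefficient of
variation; an exponential alternative (CV 1) is a config option since the
original description is ambiguous.

Viable seeding fills the grid with independent random genomes, evolves 500
steps under the target regime and accepts when survivors reach
⌈0.49 · n_spots⌉ (500 on the reference 32×32 grid; the threshold scales with
grid area so reduced runs remain meaningful). Survival requires an expressed
importer of #10 plus an enzyme converting #10 to a prime, without running into
the toxicity ceiling — a lottery that typically needs tens of trials on an
8×8 grid (hundreds on 32×32).

## Analysis definitions

Trophic profile: three bit strings over tags 1..max_tag, where max_tag is the
largest tag present in the system (nonzero concentration anywhere, or
referenced by a living organism's expressed proteins). Uptake and release bits
use the **net** pump flux per tag over the time-step; production uses the
**gross** enzymatic creation; the activity threshold is 10⁻¹⁰ ACU per
time-step (both choices are parameters). Group A: net uptake of `m_exo`;
group B: net uptake of anything else but not `m_exo` ("group-A by-products"
is operationalized as any non-`m_exo` uptake, equivalent in-regime since the
environment contains only `m_exo` and organism-released metabolites);
organisms with no uptake are unclassified and are excluded from A/B
proportions and from PS numerators and denominators.

MRCA age: current time minus the birth step of the most recent node ancestral
to all living leaves. PS score: |f₁ − f₂| with fᵢ the group-B frequency among
classified living leaves of each MRCA subtree. Population statistics (over a
group selection): mean genome size; mean units outside all functional
regions; metabolic redundancy = per-organism mean number of expressed copies
per distinct reaction (s, p, direction); uptake/production diversity =
distinct prime tags with realized uptake/production activity (encoded-capacity
variants would differ only for silent genes and are easy to derive from the
species lists). Log-fitness of B over an assay interval is
ln[(B_f/B_i)/(A_f/A_i)] — the log ratio of fold-growths, zero under equal
growth, positive when B outgrows A; an ecotype extinct at the end of the
interval yields a −∞/＋∞ sentinel (the acceptance script applies a 0.5
pseudo-count instead, reported as censored).

Transfer assays re-seed the source world's RNG, reset the clock to a cycle
boundary, tag every organism by its MRCA-subtree side and propagate under the
target regime; the polymorphism is lost at the first step where one side has
no living descendant (equivalent, as tested, to brute-force descendant-set
checks on the recorded tree).

## Engineered fixture strains

The test-suite and assays use constructed (not evolved) strains with
analytically chosen kinetics:

* **steady strain** — weak #10 importer (≈ 0.005 · [ext] ACU/step), fast
  conversion to #7/#3 and fast venting of both: internal pools equilibrate
  near 0.05 ACU, the resource outlasts a full cycle, the score never falls
  below the division threshold and toxicity never triggers. Its demography is
  therefore pure random death, which is what makes it the right probe for
  turnover calibration: on a saturated grid, divisions per organism per
  333-step cycle ≈ p_death · Δt = 6.66.
* **seasonal A/B pair** — A imports #10 fast (≈ 0.05 · [ext] ACU/step),
  converts to #7/#3 (score ≈ 1 ACU while the resource lasts), vents them as
  by-products, and carries a slow #5 side path whose stock decays over ~200
  steps, keeping A above the division threshold through the famine; B ignores
  #10, slowly imports the released #7 and converts part of it to #5. Within a
  cycle A booms in the feast season and collapses in the famine while B does
  the reverse, producing the negative frequency dependence of B's log-fitness
  that the assays measure. Both strains sit well below the toxicity ceiling at
  their design operating points; founders carry a small internal stock of
  their score metabolite so both can compete from the first step of a cycle.

What the engineered pair does **not** emulate: evolved populations are
polymorphic clouds, their ecotype boundaries blur at season transitions
(an A organism whose `m_exo` flux stalls in the famine is classified B at
that step), and their interaction strengths drift under mutation. Passing the
pair's assay shows the ecological machinery (seasons, by-product feedback,
score competition) produces negative frequency dependence — not that any
evolved population will.

## Problem sizes used by the bundled checks

The test-suite and `scripts/acceptance.py` run desk-scale versions of the
experiments: 8×8 grids (16×16 for the frequency-dependence assay, where
drift on 64 spots is too strong), 500-step seeding, six 333-step cycles for
the reduced evolution run, 10⁴ replications for operator-rate recovery, and
two measured cycles (after one burn-in cycle) for turnover. These sizes are
package choices that keep every property measurable with comfortable
statistical margins. The headline campaign design — 12 repetitions × 500,000
time-steps × 32×32 grid per regime, long-term MRCA/PS distributions, Table-
style ecotype statistics and 10-repetition transfer matrices — uses the same
drivers (`run_campaign`, `run_competition`, `run_transfer`) unchanged and is
sized for a cluster; the package does not bundle those outputs.

## Known limitations

* Serial-transfer population subsampling is deliberately absent (as in the
  modeled setup); the periodic regime refreshes resources but never
  bottlenecks the population.
* Genome sizes are bounded only by the mutational load of rearrangements;
  transient gene-amplification waves can still make single runs slow, though
  merged-species integration keeps them tractable.
* Backups are plain JSON: exact and portable, but large worlds (32×32 with a
  rich tag universe) produce files in the tens of megabytes; use the snapshot
  cadence accordingly.
* On 8×8 grids the A/B pair's famine bottleneck (A down to a few organisms)
  makes stochastic extinction within a few cycles likely; multi-cycle
  oscillation studies should use 16×16 or larger.
* Whether external (spot-level) concentrations can also be lethal is left as
  modeled: they are not; only internal pools are checked against the
  threshold.
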