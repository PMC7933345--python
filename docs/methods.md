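# Methods

## Scope and model class

`hdclvr` is an individual-based, stochastic, discrete-time simulator of
CRISPR suppression gene drives. Genetics are tracked per individual at two
loci plus a daisy-element count: a haplosufficient female-fertility gene
hosting the drive cassette (per-gRNA-site cleavability flags and a
gene-function flag per allele), a haploinsufficient essential gene targeted
by the cleave-and-rescue component (intact-site count and function flag per
allele; the recoded rescue copy rides implicitly on each drive allele), the
number of unlinked daisy elements, and an optional driving Y. Because gRNA
sites are exchangeable, the population engine summarises site vectors by
their intact counts; the scalar reference implementation keeps explicit
boolean site vectors and the two are cross-checked distributionally in the
test suite.

## Germline processes

All Cas activity is germline-only (no embryonic activity) and is sampled
independently for every conception. Activity requires a Cas carrier (a
drive allele, or the driving Y) and, in the daisyfield architecture, at
least one daisy element.

* **Homing.** In a drive heterozygote, each intact site on the non-drive
  allele is cut independently with probability `P_c`. Given ≥1 cut, the
  allele converts to a drive copy with probability `1 − P_n` (HDR);
  otherwise all cut sites lose their recognition sequence and the gene
  stays functional only if every repair is in frame (`1 − P_f` each) and
  every one of the `cuts − 1` intervening blocks is retained (`P_b` each).
* **Cleave-and-rescue.** A functional target allele with `i` intact sites
  moves to `j` intact functional sites with probability
  `P_ij = C(i, i−j) (P_c(1−P_f))^(i−j) (1−P_c)^j P_b^max(i−j−1, 0)`;
  the residual mass renders the gene non-functional (absorbing). The block
  exponent is clamped at zero because a block only exists between two
  simultaneous cuts. An independent enumeration oracle over per-site
  cut/repair/block outcomes and a 10⁶-draw Monte-Carlo simulation confirm
  the distribution; at the defaults with four gRNAs a cleaved target gene
  survives functionally with probability 8.0 × 10⁻⁴.
* **Viability.** Offspring need exactly two functional essential-gene
  copies (targets plus one rescue per drive allele) to develop. The
  `at_least_two_copies` mode models a target whose overexpression is
  tolerated; the `both_sex_fertility` mode keeps failing offspring alive
  but permanently sterile. In the driving-Y-cleave-and-rescue variant the
  rescue rides on the Y (a design choice of this package; carriers are
  male, cleave in their germline, and contribute one rescue copy).
* **Inheritance.** One allele per locus per parent uniformly; each
  parental daisy element transmits independently with probability 0.5;
  offspring of driving-Y fathers are male with probability
  `driving_y_skew` and male offspring inherit the Y drive.

`P_f` is the per-site probability that an NHEJ repair destroys gene
function, so an in-frame (functional-resistance) repair has probability
`1 − P_f = 0.333` at the default `P_f = 0.667`.

## Life cycle

Generations are non-overlapping. Every fertile female (≥1 functional
fertility-gene copy; haplosufficiency) is paired with a uniformly random
fertile male — polygynous, so males may sire several litters — litter
sizes are Poisson(`litter_size`), non-viable offspring are removed, and
each survivor is recruited with probability
`p(N) = min(1, exp(r_max (1 − N/K)) · 2/litter_size)` where `N` is the
pre-reproduction census. At `N = K` this gives exactly replacement
(`p · litter/2 = 1`), so the census equilibrates at the carrying capacity;
at low density the cap binds and every offspring is recruited, bounding
per-generation growth at `litter_size/2 ≈ 1.44` for the squirrel preset.
Engineered release animals are drive heterozygotes with one
pre-inactivated target allele (so they satisfy the two-copy rule
themselves), a full daisyfield and an even sex split. Supplementation adds
`floor(percent/100 × census)` such animals at every scheduled generation;
the floor means no animals are added once the census falls below
`100/percent`, so supplementation cannot maintain a remnant population
forever.

## Spatial extension

The arena is a bounded (non-toroidal) square of side
`A = sqrt(K π r²)/sqrt(D)`, sized to hold `K` individuals at `D` per
circular home range of radius `r`. Mate allocation is distance-dependent:
each fertile male approaches a female with probability
`P_a = exp(−(ε s)²)`, with `ε = sqrt(ln(n_obs))/s_max` calibrated so the
largest of `n_obs` observed mating ranges has probability `1/n_obs`
(ε ≈ 0.00307 m⁻¹ for 600 m out of 30); the father is uniform among
approachers and a female with none does not breed. Offspring are born at
the mother's location. Density regulation acts through migration, not
extra mortality: with local density `d` (individuals within `r`, self
included) the migration probability is `0` for `d ≤ D`, else `1 − D/d`.
Residents make one Gamma(5, r/5)-distance move in a uniform direction,
resampling until inside the arena. Migrants search lazily: each step
redraws the direction and adds a Gamma(5, 3r/5) increment to the
cumulative distance from home; the first in-arena candidate with local
density below `D` is accepted, a cumulative distance beyond the maximum
dispersal range resets to zero, and after 50 steps the last in-arena
candidate is kept regardless of density. Candidate densities are evaluated
against a snapshot of pre-movement positions, so movement order is
immaterial. The global recruitment cap of the life cycle still applies.

Supplementation placement strategies: arena middle; population centroid;
mode (centre of the densest cell of a grid with cells of side `r`); one
uniform random point; ten uniform random points with the animals split
evenly; and a moving front — a horizontal line that climbs the arena in
ten steps across successive supplementation events, then stays at the top,
with animals spread evenly across its width. Strategies that need
population locations fall back to the arena centre when the population is
empty. The initial release uses the configured strategy too.

## Parameters

| Parameter | Default | Meaning |
|---|---|---|
| `P_c` | 0.95 | cut probability per intact gRNA site |
| `P_n` | 0.02 | NHEJ (vs HDR) probability during homing |
| `P_f` | 0.667 | per-site loss-of-function probability of an NHEJ repair |
| `P_b` | 0.2 | retention probability of the block between two cuts |
| `n_grnas_homing` / `n_grnas_clvr` | 1 / 4 | multiplexed gRNAs per component |
| `daisyfield_size` | 30 | daisy elements carried by engineered animals |
| `K` | 3000 | carrying capacity (individuals) |
| `r_max` | 1.16 | maximum log growth rate, read per generation |
| `litter_size` | 2.87 | mean offspring per litter |
| `generations_per_year` | 2 | 26-week generation time |
| home range `r` / density `D` | 80 m / 4 | spatial grain of the arena |
| mating range | 600 m / 30 obs. | calibrates the approach kernel |
| max dispersal | 10 000 m | migrant search range |

`driving_y_skew` defaults to 0.95 (driving-Y systems skew all or most
offspring male; the exact value matters only for the driving-Y variants,
which are not part of the headline HD-ClvR scenarios).

## Seeding and determinism

Replicate `k` of a scenario with master seed `s` uses the PCG64 stream
seeded by `SeedSequence([s, k])`: trajectories are bit-reproducible and
independent of the order in which replicates run. Sweeps reuse the base
master seed per cell; the acceptance script assigns each scenario arm its
own derived seed.

## What the simulations show — and what they do not

The generator *is* the study system: there is no external data, and all
conclusions are about this model of a grey-squirrel population. The
following qualitative behaviours are reproduced and tested: a wild
population is stationary at `K`; a standard homing drive at a high NHEJ
rate is defeated by functional resistance alleles that sweep and rescue
the population; a standard cleave-and-rescue drive needs a large
introduction (1000 animals succeed where 100 fail over a 30-year horizon);
homing-cleave-and-rescue purges functional resistance below 10⁻³ among
viable offspring and eliminates the population across NHEJ rates; the
spatial model suppresses strictly later than the randomly mating model;
and supplementation placement matters (ten random groups eliminate where
fixed centre placement stalls).

**Known limitation — timescale compression.** The non-overlapping
generation cycle replaces the whole population every 26 weeks, so a
homing-cleave-and-rescue carrier's near-complete transmission compounds
into ~1.9× carrier-frequency growth per generation when rare. In a real
squirrel population (and in age-structured models of it) a standing pool
of long-lived adults damps per-step frequency growth substantially. Two
consequences follow. First, absolute and differential times are
compressed: elimination takes ~11 generations (5.5 years) here, and the
spatial-versus-random lag measures ~2–2.5 years rather than the several
years an age-structured population would show. Second, the daisyfield
self-limitation race is biased toward the drive: outcrossing needs
~log₂(30) ≈ 5 generations to exhaust a 30-element field, by which time
carriers already exceed the toxin-antidote point of no return, so a single
100-animal HD-ClvR release usually eliminates the modelled population even
with no supplementation (in ~5–10 % of replicates dilution wins and the
population recovers fully — the self-limitation mechanism is present, it
just rarely wins this race). Conclusions about *minimum sufficient*
supplementation rates are therefore optimistic lower bounds, while the
qualitative orderings (more supplementation and larger daisyfields
eliminate faster; placement quality governs spatial success) are the
robust outputs. Other simplifications: no age structure or seasonality, no
fitness cost to carrying Cas, no non-target cleavage, a homogeneous
bounded arena rather than a real landscape, and no Cas-saturation penalty
for multiplexing many homing gRNAs.

## Numerical notes

Cleavage distributions are precomputed per intact-site count and sampled
by inverse CDF; homing cut counts use binomial draws over intact sites.
Mate allocation samples the full female × male Bernoulli approach matrix
in blocks of 256 females, with a uniform random key per approaching male
so the row argmax is a uniform choice among approachers. Local densities
use a k-d tree; pairwise results are independent of spatial indexing.
Degenerate inputs are defined explicitly: an extinct population stays
extinct; a population with no fertile pair collapses to extinction; empty
populations give placement fallbacks at the arena centre; `i = j = 0`
cleavage is the identity.
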