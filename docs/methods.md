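# Methods

## Model

`decoysim` simulates `N` diploid individuals (constant size, equal sex
ratio) carrying two alleles at each of four unlinked loci: a male-expressed
ligand, a female-expressed receptor, a female-expressed decoy, and a
neutral control.  Alleles are integers on `0..allele_max` (default 50);
the phenotype of a genotype is the arithmetic mean of its two alleles,
divided by `allele_max` so that all distances live on `[0, 1]`.

Each generation:

1. every female encounters `n_encounters` males drawn uniformly with
   replacement and mates with each independently with probability equal to
   the pair's mating rate (decoy-modified where the female's own decoy
   phenotype lies strictly between the two mates' phenotypes);
2. mothers of the next generation are sampled with replacement,
   proportional to fecundity `W_f` evaluated at each female's *realized*
   mating rate (matings / encounters), restricted to females with at least
   one mate; each offspring's sire is drawn uniformly from its mother's
   mate multiset;
3. each parent transmits one uniformly chosen allele per locus; each
   transmitted allele mutates independently with probability `mu`.

Assumptions worth stating: one trait dimension; no linkage, no spatial
structure; non-overlapping generations; sex assigned as an exact half
split (offspring are exchangeable, so a random split adds only binomial
noise in the sex ratio without changing any locus dynamics); unmated
females leave no offspring.

## Mating-rate algebra

With male, female and decoy phenotypes `z_m, z_f, z_d`, pair distance
`D = |z_m - z_f|`:

* baseline rate `P_MF = exp(-(D/s_p)^x_p)` — 1 at zero distance, strictly
  decreasing;
* fecundity `W_f = B_max * exp(-(|P - P_opt|/s_w)^x_w)` — peaked at the
  female optimum `P_opt`;
* decoy activity `theta = 1` iff `min(z_m,z_f) < z_d < max(z_m,z_f)`
  (ties inactive: a decoy coincident with either party cannot be
  discriminated from it);
* when active, with `rho = |z_f - z_d| / D` the decoy's relative position
  (0 at the female, 1 at the male) and `dev = |D - D_opt|`:

      Pi = P_opt * min( c0*q + min(1, (dev/sd)^xd),  min(1, (dev/sd)^xd + c0) )
      q  = max(0, 1 - (rho/si)^xi)
      P_modified = clamp( min(P_MF, P_opt) - Pi, 0, 1 )

  The `min(P_MF, P_opt)` term means the decoy never raises a pair's rate
  above the unmodified one.  A decoy exactly at the male (`rho = 1`) at
  the optimal distance (`dev = 0`) yields `P_modified = P_opt` exactly.

The interference has two parts, and the split is load-bearing:

* the **positional part** `c0 * P_opt * q` is what the female pays for an
  imperfect mimic sitting near her true receptor, and its gradient in the
  decoy's position is the selective force that walks the decoy across the
  male-female gap — fast decoy evolution exactly while the chase is
  paused;
* the **deviation penalty** `P_opt * min(1, (dev/sd)^xd)` applies at any
  decoy position.  It holds both male and female at `D_opt` while the
  decoy is active (preventing the three loci from collapsing onto a single
  value) and makes "coverage" of a moving male by a tracking decoy
  costly, which is what keeps decoy-male chases brief.

## Parameter defaults and why

| parameter | default | units / scale | rationale |
|---|---|---|---|
| `P_opt` | 0.1 | probability | female optimum well below the male optimum of 1 creates the conflict; 2 of 20 encounters |
| `B_max` | 10 | offspring | only relative fecundities matter for sampling |
| `s_p, x_p` | 0.1, 2 | normalized distance | Gaussian decay; rate falls below `P_opt` beyond ~7.6 allele units, setting the chase gap |
| `s_w, x_w` | 0.15, 1.5 | rate deviation | sub-Gaussian penalty: a Gaussian (`x_w = 2`) makes fecundity ratios explode far from the optimum and collapses the effective population size whenever the pair is cornered at an allele-space boundary (runs freeze for thousands of generations); a pure exponential (`x_w = 1`) leaves the female too weakly selected to outrun the male (the chase collapses to zero distance).  1.5 sustains the chase and keeps boundary episodes short |
| `D_opt` | 0.1 | normalized distance | inside the band where `P_MF > P_opt`, so decoy effectiveness `Pe = P_MF - P_opt` is positive at the operating point |
| `si, xi` | 1, 1 | relative position | linear interference decline reaching exactly zero at the male |
| `sd, xd` | 0.25, 1 | distance deviation | V-shaped well: a quadratic well has zero restoring force at its center, so the male slides onto the decoy; the linear well holds him.  `Pt` saturates at `P_opt` by deviation 0.25, satisfying the requirement of near-total mating suppression at deviation 0.5 |
| `c0` | 0.2 | fraction of `P_opt` | large enough to give the decoy a measurable selective drive (its substitution rate is proportional to `(c0 * P_opt)^2 / s_w^2`), small enough that the female tolerates an episode instead of fleeing it |
| `mu` | 5e-5 | per locus per transmitted gamete | published rate |
| `jump_prob` | 0.01 | fraction of mutations | see mutation model |
| `N, generations, n_encounters, window, n_replicates` | 10000, 15000, 20, 500, 20 | — | published study conditions |

`validate_params` enforces, beyond range checks: `Pi < Pe` at the
operating distance (the decoy must leave the female better off than the
unmodified rate — checked on a grid of decoy positions, plus a positive
mean fecundity gain over the whole active region) and `Pt >= 0.9 * P_opt`
at deviation 0.5 (otherwise the decoy profitably chases the male).

## Mutation model

A mutation is a stepwise change of ±1 with reflecting boundaries at 0 and
`allele_max`; with probability `jump_prob = 0.01` the step magnitude is
instead uniform on 2..4.  The rare larger steps matter in two stuck
states that pure ±1 dynamics cannot leave on observed timescales:
a population cornered at an allele-space boundary, and a male pinned
under an adjacent decoy (heterozygous ±1 steps move the phenotype only
half a unit and cannot cross it).  The magnitude cap at 4 is deliberate:
crossing an adjacent decoy needs a ~2-unit phenotype move, while a female
escaping a decoy episode outright would need ≥10 units, so episodes
cannot be aborted by a single female mutation.

## Numerical implementation

Two engines share the algebra and are cross-checked statistically in the
tests:

* the **reference engine** composes the vectorized NumPy stage functions
  (`encounter_and_mate`, `reproduce`, `mutate_gametes`) with a
  `numpy.random.Generator`;
* the **fast engine** is a single numba-compiled loop.  Because allelic
  sums are integers on `0..2*allele_max`, mating rates are evaluated once
  per occupied (female, decoy) × (male) phenotype class per generation and
  encounters index the table.  Random numbers come from an inlined PCG32
  generator (the same family as NumPy's default bit generator; numba
  kernels cannot call Generator objects and its Mersenne bindings
  dominated the profile).  The Bernoulli(mu) mutation process over the 8N
  transmitted alleles is sampled exactly by geometric gap-skipping.
  Integer draws use the multiply-shift reduction (bias < n/2^32).

One replicate at the published scale runs in ~20-30 s; the full
20-replicate experiment in ~7-10 min on one CPU.

Determinism: every run is a pure function of (configuration, model
parameters, seed) per engine; replicate k's seed is derived from the base
seed and k alone via `numpy.random.SeedSequence`, so any replicate can be
reproduced in isolation.  The two engines use different random streams
and agree statistically, not bitwise.  With the decoy clamped inactive the
fast engine is bit-identical to its decoy-free two-locus code path (all
paths consume random numbers identically).

Degenerate inputs: a generation in which no female mates aborts the
replicate, returning the partial trajectory flagged `failed`; regressions
require ≥3 points and a non-constant predictor (pairs failing this
classify as "none" in the pipeline rather than raising); a constant
response yields slope 0, r² = 0, p = 1.

## Rate analysis

Substitution rate of a locus in a window = |mean allelic value at the
window end − at the window start| (nonnegative, like a dN/dS proxy;
signed changes are retained for diagnostics).  Per replicate, each locus
pair's rate series are regressed by OLS (statsmodels behind
`fit_rate_regression`; weighted least squares for branch tables, with
weights equal to branch length exactly).  A pair classifies positive /
negative when the two-sided p-value of the slope is `< alpha = 0.05`
(a printed ">" in the source description of the significance rule is
treated as a typo, consistent with the same procedure described for the
empirical analysis).  Fisher's exact test (scipy behind
`fisher_exact_2x2`, checked against full fixed-margin enumeration in the
tests) contrasts negative-significance of the male-decoy pair against the
male-neutral pair by default; the table construction is a parameter, since
the construction behind the originally reported P = 0.0035 is not
recoverable (the natural [[11,9],[0,20]] table gives a one-sided p near
7e-5).

## Synthetic branch-rate generator

`simulate_branch_rates` emulates codon-model output: per-branch omega for
a predictor gene (lognormal), a response gene that is a linear function of
it plus Gaussian noise clipped at zero, and lognormal branch lengths.  It
reproduces the *statistical shape* of such tables — a linear trend across
branches with heteroskedastic-looking scatter — but none of the structure
of real data: no shared phylogenetic covariance between branches, no
estimation error correlated with branch length, no undefined omegas on
short branches.  Passing recovery tests therefore shows the regression
machinery is correct and calibrated, not that branch-model estimates from
real alignments would be.  Note that the zero-clipping attenuates
recovered slopes when the linear predictor goes negative, so recovery
tests use intercepts that keep the response positive.

## Problem sizes used in the tests

Unit tests run populations of 4-500 individuals for ≤2,000 generations.
The acceptance tests run (a) the published scale — 20 replicates,
N = 10,000, 15,000 generations, 500-generation windows — and (b) a desk
scale of 20 replicates at N = 1,000 for 5,000 generations with
250-generation windows, chosen so the whole pipeline (chase, decoy
episodes, classification, Fisher contrast) executes end-to-end in under
two minutes.  Mutational supply scales with N, so desk-scale dynamics are
supply-limited: the same phases occur but with fewer substitutions per
window and weaker correlation signals.

## What the reproduction does and does not recover

Robust across both scales and many seeds:

* the male-female co-evolutionary chase with mating rate between the two
  optima, and significantly **positively correlated male-female windowed
  rates in essentially all replicates**;
* the full decoy phenomenology: activation when the decoy falls between
  the loci, mating rate dropping below `P_opt`, decoy evolution toward the
  male while the chase is frozen, male discrimination ending the episode,
  and resumption of the chase;
* the neutral locus is uncorrelated with other loci at roughly the nominal
  α level at the published scale (each replicate tests three neutral pairs
  at α = 0.05, so a few significant replicates out of 20 are expected by
  chance).

Not recovered under the shipped defaults: a **majority of replicates with
significantly negative male-decoy rate regressions**.  Episodes and chase
phases alternate as described, but the decoy's substitution rate is
bounded by its selective stake — the female's fecundity deficit, which is
at most `P_opt` per encounter — while chase substitutions are driven by
order-one mating-probability differentials.  The decoy therefore moves
5-10× slower than the chase, and the windowed male-decoy regression
usually classifies "none" (with occasional positives when a decoy-male
chase, which the original report also observed in nearly half its runs,
dominates a replicate).  At desk scale the regime alternation itself also
couples rate variances across loci (boundary episodes suppress all
substitution while reducing effective population size), which can push
the neutral control somewhat above its nominal false-positive rate.
Both gaps trace to the exact shapes of the published
response curves, which are not recoverable from their description; the
curve families here are pluggable (`ModelParams`) precisely so that other
shapes can be explored.

## Known limitations

* Empirical branch-model estimation (codeml fitting, likelihood-ratio
  tests, site identification) is out of scope; `branch_corr` ingests its
  output as a table.
* No recombination/linkage model beyond independent loci; no performance
  guarantees beyond N ~ 1e5.
* The fast engine's PCG32 stream is part of the package's reproducibility
  contract but is not guaranteed stable across major versions.
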