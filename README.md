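# decoysim

Population simulator of **sexual conflict over mating rate with a
female-expressed molecular decoy**, plus the substitution-rate correlation
analysis used to compare it with branch-specific dN/dS estimates from real
gamete-recognition genes.

## The scientific problem

In abalone, the sperm protein **lysin** dissolves the egg's vitelline
envelope by binding the giant egg-coat receptor **VERL**; both evolve under
strong positive selection and their per-lineage evolutionary rates are
positively correlated — the signature of antagonistic co-evolution driven by
a conflict over fertilization rate.  A VERL paralog, **VEZP14**, binds lysin
with comparable affinity yet its rates are *anti*-correlated with lysin's
across the same lineages.  One explanation is molecular mimicry: VEZP14 acts
as a **decoy receptor** that soaks up excess lysin, pulling the effective
fertilization rate down toward the female optimum and thereby pausing the
lysin–VERL arms race.

`decoysim` implements a diploid, individual-based model of this hypothesis
and the analysis that turns simulated trajectories into the statistics
reported for real genes.

## The model

Four unlinked diploid loci per individual: male-expressed ligand `m`,
female-expressed receptor `f`, female-expressed decoy `d`, and a neutral
control.  Alleles are integers 0..50; phenotypes are additive (mean of the
two alleles, normalized by 50).  Each generation every female encounters
`n = 20` random males and mates with each with probability

```
P_MF = exp(-(D_MF / s_p)^x_p)            # D_MF = |z_m - z_f|
```

Females produce offspring in proportion to

```
W_f = B_max * exp(-(|P - P_opt| / s_w)^x_w)
```

at their realized mating rate `P`, so males are selected toward females
(`P -> 1`) while females prefer an intermediate rate `P_opt` — a chase.
The decoy modifies the pair's rate only when its phenotype lies strictly
between male and female (`theta = 1`):

```
P_modified = clamp( min(P_MF, P_opt) - Pi )
Pi = P_opt * [ c0 * q(rho)  +  min(1, (|D_MF - D_opt| / sd)^xd) ]
```

with `rho` the decoy's relative position between female (0) and male (1)
and `q = max(0, 1 - rho)`.  A decoy sitting on the male at the optimal
pair distance `D_opt` leaves the female exactly at her optimum; a decoy
near the female interferes (`Pi > 0`), which is what selects the decoy
across the gap toward the male — rapid decoy evolution precisely while the
chase is paused.

Substitution rates are measured as the absolute change of each locus's
mean allelic value per 500-generation window; per-replicate regressions
between locus rate series are classified (positive / negative / none) at
`alpha = 0.05`, counted over 20 replicates, and the decoy-vs-neutral
contrast is tested with Fisher's exact test.  The same regression
machinery (`branch_corr`) applies to empirical tables of per-branch omega
values, optionally weighted by branch length.

## Worked example

One desk-sized replicate and its rate classification:

```python
from decoysim import ModelParams, SimConfig, run_simulation
from decoysim.rate_stats import classify_trajectory, substitution_rates

config = SimConfig(N=1000, generations=5000, window=250, seed=1)
traj = run_simulation(config, ModelParams(), replicate=3)
rates = substitution_rates(traj, config.window)
print(rates["male"].rates[:12])
print(rates["decoy"].rates[:12])
print(classify_trajectory(traj, config.window))
```

prints (first twelve windows of the male and decoy series, then the pair
classes):

```
male rates  :  1.0  2.0  1.9  0.1  1.0  1.0  1.2  2.7  0.0  0.0  0.0  0.0
decoy rates :  0.0  0.1  0.1  0.2  0.1  0.1  0.0  0.0  1.0  0.0  0.0  0.0
male-female: positive
male-decoy: none
male-neutral: none
...
```

The male locus moves during the chase (windows 0–7) and freezes once the
decoy becomes active, which is exactly when the decoy moves (window 8); the
male–female windowed rates are significantly positively correlated, the
neutral control is not.

From the shell, the same pipeline end to end:

```sh
decoysim run --config examples/decoy.ctl --out results/run1
decoysim analyze results/run1/trajectory_*.tsv --window 500
```

and for an empirical-style branch-rate table (here a synthetic fixture
generated with a true slope of −1.3):

```sh
decoysim branchcorr branches.tsv --gene-x gene_x --gene-y gene_y
```

```
unweighted.slope = -1.19526
unweighted.r_squared = 0.81496
unweighted.p_value = 2.3903e-05
unweighted.classification = negative
weighted.slope = -1.1013
weighted.p_value = 3.44037e-05
...
```

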