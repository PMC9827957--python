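# evoflor

Quantitative-genetic evolvability analysis of multivariate floral
morphology, built around the three-dimensional architecture of
*Dalechampia* blossoms: the gland–anther distance (GAD) and gland–stigma
distance (GSD) that govern flower–pollinator fit, and the anther–stigma
distance (ASD, herkogamy) that governs autonomous self-pollination.

The package answers three questions a floral evolutionary biologist asks of
such a system:

1. **How much additive genetic variation is there, and how is it shaped?**
   A multivariate *animal model* is fitted by MCMC to data from a block
   diallel crossing design (all reciprocal crosses within parental blocks,
   including selfs), giving the posterior of the mean-scaled genetic
   covariance matrix **G** along with plant, date, and residual covariance
   components.  The pedigree enters through the additive relationship
   matrix **A** (breeding values distributed N(0, **G** ⊗ **A**)), with
   inbreeding from selfing handled exactly.
2. **How is evolvability distributed over phenotype space?**  The
   Hansen–Houle framework: evolvability e(β) = β'Gβ, conditional
   evolvability c(β) = (β'G⁻¹β)⁻¹, autonomy a = c/e and integration
   i = 1 − a, along trait axes, eigenvectors, and random selection
   gradients drawn uniformly from the unit sphere; plus eigen-summaries
   (ē = trace/k, e_min, e_max, g_min, g_max) and selection doubling times
   t₂ = ln2/e.
3. **Has evolution followed the evolvable directions?**  Among-population
   and among-species divergence matrices **D** of ln trait means are
   estimated from grouped phenotype data and compared with **G** direction
   by direction, together with the deviation of each group from the
   pollen-transfer optimum GSD = GAD.

A synthetic-data module generates datasets with the exact statistical
structure the models assume (diallel pedigree, 160 crosses, plant/date/
blossom noise layers, dropout), so the full pipeline is testable without
any field data.  See `docs/methods.md` for models, priors, sampler design
and limitations.

## Worked example

```python
from evoflor import *

truth = dalechampia_truth()                    # canonical simulation truth
sim   = simulate_breeding_experiment(truth, seed=100)
post  = fit_animal_model(sim.phenotypes, sim.A,
                         ModelSpec(n_iter=8000, burnin=3000, thin=5, seed=1))

tab = post.summary("G")
print(tab[tab.kind == "variance"][["row", "mean", "lower", "upper"]].round(3))
```

prints the posterior of the mean-scaled genetic variances (percent units —
the evolvabilities of the three traits), here recovering the simulation
truth (0.409, 0.801, 6.567) within the credible intervals:

```
row  mean  lower  upper
GAD 0.250  0.092  0.496
GSD 1.120  0.534  1.823
ASD 7.582  2.909 14.535
```

and the evolvability statistics of the posterior-mean **G**:

```python
G = post.component_mean("G")
es = eigen_summary(G)
c, a = conditional_on_subset(G, focal=2, conditioning=[0, 1])
print(es.e_mean, es.e_min, es.e_max)   # 2.984  0.111  7.658
print(c, a)                            # 5.36 % conditional evolvability of
                                       # herkogamy, autonomy 0.707
print(doubling_time(es.e_mean / 100))  # 23.2 generations
```

The same statistics computed on the published **G** matrix for this system
(the fixture's truth) give ē = 2.592%, e_min = 0.286, e_max = 6.640, a
conditional evolvability of herkogamy given the two fit traits of 5.57%
(autonomy 0.848), and a doubling time of ln(2)/0.0259 = 26.8 generations —
herkogamy retains most of its high evolvability even under stabilizing
selection on flower–pollinator fit.

The same pipeline is available from the shell:

```sh
evoflor simulate --seed 3 --out run/
evoflor fit-g --phenotypes run/phenotypes.csv --amatrix run/A.csv \
        --iterations 8000 --burnin 3000 --thin 5 --seed 1 --out run/
evoflor stats --posterior run/posterior.csv --n-gradients 1000 --seed 1 --out run/
evoflor divergence --grouped groups.csv --gmatrix G.csv --out run/
```

Every subcommand writes a `manifest.json` recording its inputs, settings
and seed.

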