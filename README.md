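# mmirtree

Mixture multidimensional IRTree models for 5-point rating data.

Self-report questionnaires are contaminated by *response styles*:
some respondents prefer the extreme categories (extreme response style,
ERS), some the middle category (midpoint response style, MRS),
independently of what the items ask. IRTree models control for this by
decomposing each rating into sequential binary decisions —
*disagreement* (1–2 vs 3–5), *neutrality* (3 vs 4–5) and *extremity*
(1 vs 2 / 5 vs 4) — each governed by a 2PL model in which the
substantive trait θ acts at every node (scaled by a proportionality
constant ω at the extremity node) alongside the style traits η_ers and
η_mrs:

    P(disagree)        = σ(−α_θ θ − α_mrs η_mrs − β₀)
    P(neutral | ¬dis)  = σ(−α_θ θ + α_mrs η_mrs − β₁)
    P(extreme | side)  = σ(±ω α_θ θ + α_ers η_ers − β₂)

Classical IRTrees assume everyone uses the same styles. `mmirtree`
implements a four-class **mixture** of IRTrees in which latent classes
differ only in *which* styles affect responding — ERS only, MRS only,
both ("2RS"), or neither ("0RS") — by fixing the corresponding loadings
to zero per class. α_θ and ω are class-invariant (the same trait is
measured in every class); style loadings and node difficulties β are
class-specific; traits are standard multivariate normal with estimated
correlations; memberships have a Dirichlet-categorical hierarchical
prior. Estimation is by Pólya-Gamma augmented Gibbs sampling, model
comparison by DIC (D̄ + p_V with p_V = var(deviance)/2), and
respondents are classified by modal assignment of their posterior
membership draws. The package is aimed at psychometricians who want
style-corrected trait estimates, and at methodologists studying
response-style heterogeneity.

See `docs/methods.md` for the model, priors, sampler (including the
mixing moves the multimodal mixture posterior requires) and the
synthetic-data design.

## Worked example

```python
import mmirtree as mt

# a mixture population: equal 25% shares of the four style classes
ds = mt.generate_condition(
    mt.get_condition("equal", n_persons=500, n_items=20,
                     n_replications=1, master_seed=3))[0]

model = mt.MMIRTree(ds.ratings)
res = model.fit(n_chains=2, n_iterations=1500, n_burnin=500, seed=11)
print(res.summary())
```

Output (abridged; exact numbers from this command):

```
MM-IRTree results
==============================================
persons: 500   items: 20   chains: 2   kept draws: 2000
DIC: 24,241.9   (Dbar 22,496.0, pV 1,745.8)
max Rhat: 1.102 (NOT converged at threshold 1.05)
omega: 0.477
class proportions (PSD): ERS_ONLY: 0.247 (0.022), MRS_ONLY: 0.254 (0.021),
                         TWO_RS: 0.250 (0.021), ZERO_RS: 0.249 (0.020)
modal class sizes: ERS_ONLY: 119, MRS_ONLY: 129, TWO_RS: 126, ZERO_RS: 126
certainty: ERS_ONLY: 0.93, MRS_ONLY: 0.93, TWO_RS: 0.95, ZERO_RS: 0.95
```

The estimated class proportions recover the generating 25% shares, ω
recovers its generating value 0.50 to within posterior noise, and the
per-class certainty is the average posterior probability of the
assigned class. Against the (known) generating memberships:

```python
mt.hit_rate(res.modal_classes, ds.z_true)
# {1: 0.888, 2: 0.944, 3: 0.952, 4: 0.936}
```

i.e. 89–95% of respondents are assigned to their true class at this
reduced scale (a handful of marginal Rhat values slightly above 1.05
at these short chains is expected; lengthen chains for production use).
Model comparison against the single-class benchmarks:

```python
fits = {"mm": res}
for kind in ("ers", "mrs", "2rs", "0rs"):
    fits[kind] = mt.IRTree(ds.ratings, kind=kind).fit(
        n_chains=2, n_iterations=800, n_burnin=300, seed=17)
best, table = mt.select_model(fits)   # best == "mm" on mixture data
```

## Command line

```sh
mmirtree simulate --condition equal --n 2000 --items 20 --reps 10 --seed 1 --out sim/
mmirtree fit --model mm --data sim/equal_rep0_ratings.csv --chains 10 \
         --iters 3000 --burnin 1000 --seed 2 --out fit_mm/
mmirtree evaluate --truth sim/equal_rep0_truth.json --fit fit_mm/ --out report.json
mmirtree run-study --conditions all --scale 0.25 --seed 3 --out study/
```

`run-study` reproduces the full simulation design (nine class-proportion
conditions × 10 replications; simulate → fit all five models → evaluate)
and is resumable; `--scale` shrinks persons/chains/iterations
proportionally for desk-scale runs.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch at reduced scale (n = 500, 20 items, 2 chains ×
1500 iterations): the per-class classification hit rates of the mixture
model under a dominated mixture condition (the 10% classes and the 70%
class), under the equal-proportions condition, and the percentage of
correct assignments when the mixture model is fitted to single-class
data. Runtime is a few minutes on one CPU.
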