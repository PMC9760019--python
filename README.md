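# isospec

Quantifying **individual dietary specialization** in consumer populations
from two-tissue stable isotope data (δ13C, δ15N).

Ecologists studying generalist predators — for example river fish sampled
for muscle and caudal-fin tissue, which integrate diet over different time
windows — need to know whether a population's wide diet reflects generalist
individuals or a collection of individual specialists. `isospec`
implements the standard quantitative toolkit for that question as a tested,
reproducible pipeline:

- **WIC/TNW niche variance decomposition** — the total niche width (TNW,
  population variance of an isotope value) splits exactly into a
  within-individual component (WIC) and a between-individual component
  (BIC); the ratio WIC/TNW runs from 0 (specialists) to 1 (generalists),
  tested against an all-generalists null by Monte Carlo bootstrap.
- **Hierarchical Bayesian mixing model** — per-individual diet proportions
  over prey functional groups, with individual identity as a Gaussian
  random effect in isometric log-ratio (ILR) space, sampled by adaptive
  Metropolis-within-Gibbs with R̂/ESS convergence gates.
- **Proportional-similarity indices** — PSᵢ = 1 − ½Σⱼ|p_ij − q_j| per
  individual against the population diet q, the population mean IS, and a
  discretized Monte Carlo null.
- **Trophic position** — TP = λ + (δ15N_consumer − δ15N_baseline)/3.04‰
  from a phytoplankton (SPOM) baseline, with between-site ANOVA and
  variance-homogeneity F tests.
- **Beta regression** — maximum-likelihood fit of PSᵢ on trophic position,
  body size and site (logit link, constant precision φ) with Wald
  inference.
- **Synthetic studies** — a generator producing full two-river, two-tissue
  studies with known ground-truth diets, so every stage is testable without
  any external data.

## Worked example

Generate a synthetic study and decompose the δ13C niche per site:

```python
from isospec import SimulationConfig, generate_study
from isospec.niche import decompose_dataset

dataset, sources, baselines, truth = generate_study(SimulationConfig(seed=1))
d = decompose_dataset(dataset, "d13C", "Uatuma", n_reps=1000, seed=42)
print(f"TNW={d.TNW:.2f} WIC={d.WIC:.2f} BIC={d.BIC:.2f} "
      f"ratio={d.ratio:.2f} p={d.p_value:.2f}")
```

prints

```
TNW=6.36 WIC=6.22 BIC=0.14 ratio=0.98 p=1.00
```

TNW (6.36 ‰²) is the population variance of all δ13C observations at the
site; WIC + BIC reproduce it exactly. The ratio 0.98 says nearly all niche
variance is *within* individuals — expected here, because each individual's
muscle and fin differ by a ~5‰ tissue offset while individual diets vary
little — and the bootstrap p of 1.00 (one-tailed toward specialization)
finds no evidence of specialist individuals.

The same study through the full pipeline:

```python
from isospec import RunConfig, run_pipeline

result = run_pipeline(RunConfig(out_dir="out", synthetic={"seed": 1}, seed=1))
```

writes `table1.csv` (per site × tissue isotope summaries), `table2.csv`
(niche decompositions), `table3.csv` (posterior mean diet proportions, IS
and its null p per site), `table4.csv` (beta regression of PSᵢ ~ TP +
standard length + site), `trophic_position.csv`, `tp_anova.json` and a
`manifest.json` recording every seed — identical config and inputs give a
byte-identical bundle.

Or from the shell:

```bash
isospec simulate --out study --seed 1
isospec niche --input study/consumers.csv --isotope d13C --reps 1000 --seed 42
isospec trophic --consumers study/consumers.csv --baseline study/baseline.csv --out tp.csv
isospec anova --input tp.csv
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

runs the entire analysis end-to-end on the default synthetic study —
summaries, both bootstrap null tests, the full MCMC mixing fit for each
site (3 chains × 30 000 iterations), specialization indices, the
trophic-position ANOVA and the beta regression — prints every result table,
and writes the results JSON to `--out` (takes ~1 minute on one CPU).

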