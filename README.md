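# isocline

Stable-isotope trophic ecology for historical marine-mammal bone collagen.

Museum "specimens of opportunity" — whale and seal bones collected between the
1840s and 1960s — carry bulk δ13C and δ15N signatures of where and at what
trophic level the animals fed. Comparing specimens across a century of
collection requires removing two systematic effects before any ecology can be
read off, and then converting the tracer values into quantities that are
comparable across regions. This package implements that pipeline for
ecologists working with historical collections:

1. **Lipid normalization.** Collagen with an elevated C:N ratio carries a
   lipid bias in δ13C. Every specimen is normalized arithmetically:
   δ13C_normalized = δ13C_raw − 3.32 + 0.99 × C:N.
2. **Oceanic Suess correction.** Anthropogenic CO₂ has progressively depleted
   surface-ocean δ13C since ~1850. A specimen from year *y* in a region with
   per-year decline constant *a* (≤ 0 ‰) is corrected by the factor
   *a*·exp((*y* − 1850) × 0.027); the package ships the accumulated Suess
   effects and derived *a*-values for five Southern Ocean / Patagonian regions.
3. **Trophic position.** TP = 2 + (δ15N − δ15N_POM)/TEF, with regional
   particulate-organic-matter baselines (0.6 ‰ in the Ross Sea up to 9.4 ‰
   off Patagonia) and optionally the bone-collagen tissue correction
   TP = 2 + (δ15N − δ15N_POM − TEF_mmt)/TEF with TEF_mmt = 2.03 ‰.
4. **Bayesian mixing model.** Consumer tracers are modelled as a
   proportion-weighted mixture of prey-source distributions:
   x_ij ~ N(Σ_k p_k(μ_jk + λ_j), √(Σ_k p_k²(σ_jk² + τ_j²) + ξ_j²)),
   with a Dirichlet(1,…,1) prior on the diet proportions *p*, fitted by
   adaptive MCMC (3 chains × 100 000 iterations, burn-in 50 000, thin 50)
   with Gelman–Rubin and Geweke convergence diagnostics. Fitting each
   specimen as its own consumer fingerprints its likely foraging region.
5. **Permutation statistics.** One-way PERMANOVA (pseudo-F from a distance
   matrix, significance by label permutation) for pre/post-industrial
   comparisons, and SIMPER (Bray–Curtis similarity percentages) to decompose
   which diet sources drive group differences.

A synthetic-data module generates specimen tables and mixture consumers with
the same statistical structure (including the ±0.188 ‰ / ±0.204 ‰ analytical
uncertainty of δ13C / δ15N), so the whole pipeline is testable end to end.

## Worked example

The package ships a 19-specimen pre-industrial reference dataset (blue
whales, South American fur seals, leopard seals) with published corrected
values. Correcting and summarizing it:

```python
from isocline import corrections, trophic
from isocline.data_model import load_reference_specimens, load_regions

regions = load_regions()
records = corrections.correct_records(load_reference_specimens(), regions)

norm = corrections.normalize_lipid(-23.7, 4.3)        # high-C:N blue whale
se = norm - corrections.suess_factor(regions["SG"].a_value, 1914)
print(round(norm, 2), round(se, 2))                   # -22.76 -22.73

for s in trophic.summarize_groups(records, key=("species",)):
    m, sd = s.stats["d13c_se"]
    print(s.key[0], s.n, round(m, 2), None if sd is None else round(sd, 2))
```

prints

```
-22.76 -22.73
Arctocephalus australis 7 -12.26 0.52
Balaenoptera musculus 3 -15.69 3.8
Hydrurga leptonyx 9 -20.04 1.4
```

i.e. the 1914 South Georgia specimen's raw −23.70 ‰ gains a combined
lipid + Suess correction of 0.97 ‰, and the per-species means of the
Suess-corrected δ13C match the published group statistics. The numbered
scripts under `analysis/` run the full sequence — corrections, trophic
positions with outlier flags, per-specimen mixing models with SIMPER, and
pre/post PERMANOVA — writing tables to `results/`.

There is also a CLI (`isocline correct|tp|mix|permanova|simper|simulate|run`)
for running the stages on any conforming CSV.

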