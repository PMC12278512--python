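# crossgen-gs

Cross-generation genomic prediction for open-pollinated tree-breeding
populations: ABLUP and GBLUP breeding-value models, evaluated by strictly
independent validation across generations and environments, with a
fully tested synthetic-population simulator so every stage runs without
restricted field data.

## Who this is for

Quantitative geneticists and tree breeders who want to study — or teach —
how marker-based (GBLUP) and pedigree-based (ABLUP) selection behave when
models trained in one generation or trial must predict another: forward
selection (parents → progeny), backward selection (progeny → parents), and
across-environment prediction. The package simulates the canonical
conifer setting: plus-tree founders (G0), open-pollinated half-sib
families planted in two randomized incomplete-block trials (G1), and
pith-to-bark radial wood-density profiles measured ring by ring.

## The model

Phenotypes are first adjusted for trial design by the mixed model

    y = Xβ + W b + Z u + e,

with a fixed grand mean, random incomplete-block effects `b`, and a random
additive effect `u`; the adjusted records `y′ = y − β̂ − ŵ` then enter the
animal model

    y′ = X b + Z u + e,   u ~ N(0, K σ²_a),   e ~ N(0, I σ²_e),

where `K` is either the pedigree numerator relationship matrix `A`
(tabular method, optional phantom-parent genetic groups) or the VanRaden
genomic relationship matrix

    G = (M − P)(M − P)ᵀ / (2 Σᵢ pᵢ(1 − pᵢ)),

with `M` the 0/1/2 allele-count matrix and column `i` of `P` equal to
`2 pᵢ` (observed allele frequency over all genotyped individuals).
Variance components are estimated by REML (monotone EM, with
average-information acceleration) and breeding values for *all* kernel
individuals — phenotyped or not — come from Henderson's mixed-model
equations. Narrow-sense heritability is `h² = σ²_a / (σ²_a + σ²_e)`;
predictive ability is `PA = corr(y′, ŷ)` on a validation set that shares
no individuals with the training set, and prediction accuracy is
`ACC = PA / √h²`.

Ring-level density is summarized either cumulatively — the area-weighted
estimate over rings 1..k, `AWE_k = Σ aᵢdᵢ / Σ aᵢ` with circular-ring
areas `aᵢ` — or as the single-annual-ring direct value (SAD), emulating
cheap under-bark measurements; a cambial-age sweep compares GBLUP models
trained on either summary at every ring.

## Worked example

```python
from crossgen_gs.experiments import relatedness_study

study = relatedness_study(seed=1)  # 65 OP families x 6 progeny, 5,000 SNPs
print(round(study["within_family_mean"], 4),
      round(study["among_family_mean"], 4),
      round(study["dam_offspring_mean"], 4))
```

prints

```
0.2449 -0.0041 0.4928
```

— simulated maternal half-sibs average a genomic relationship of ~0.25,
unrelated families ~0.00, and each dam shares ~0.50 with her offspring,
the three classical expectations that make cross-generation GBLUP
prediction possible. With father sharing enabled
(`full_sib_fraction=0.25`) the within-family mean rises to ~0.27,
reproducing the "imperfect half-sib" signature of real open-pollinated
families.

The numbered drivers under `analysis/` run the full studies and write
tidy tables to `results/`:

| script | what it does |
| --- | --- |
| `01_simulate_population.py` | study-scale population → `scratch/population/` |
| `02_relatedness.py` | within/among-family and dam-offspring G distributions |
| `03_heritability_recovery.py` | REML h² recovery, direct and through the ring pipeline |
| `04_cross_generation_validation.py` | ABLUP vs GBLUP, Approaches A/B/C, two h² levels |
| `05_early_training_sweep.py` | AWE- vs SAD-trained GBLUP along cambial age |

A thin command line mirrors the library:
`crossgen-gs {simulate,pheno,qc,relmat,fit,validate,sweep,run}`.

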