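# metadriver

Discovery of **copy-number-driven metabolic driver genes** across cancer
cohorts, with the permutation-null, co-occurrence and prognostic machinery
needed to vet them.

Over-expression of a gene in tumours can come from altered transcriptional
regulation or from somatic DNA copy-number gain. When a gene is recurrently
gained *and* its mRNA abundance tracks its DNA dosage, the gain itself is
the most parsimonious explanation — a putative gain of function under
selection. `metadriver` implements this reasoning as a reusable pipeline
for multi-cohort (pan-cancer style) studies, aimed at computational
biologists working with matched expression, copy-number, mutation and
clinical tables:

1. **SCNA calling** — gene-level log2 ratios *t* are discretised into
   five states: amplification (*t* > 1), gain (0.2 ≤ *t* ≤ 1), neutral,
   loss (−1 ≤ *t* ≤ −0.2), homozygous deletion (*t* < −1).
2. **Candidate drivers per cohort** — a gene is a candidate when it is
   over-expressed in tumours vs normals (Welch *t*, log2 fold change > 0.5,
   BH *q* < 0.05; top decile of the metabolic gene universe), recurrently
   gained or amplified (≥ 20 % of samples), and dosage-correlated
   (Spearman ρ > 0.3 at BH *q* < 10⁻³ over the tested genes). A mirrored
   loss-side screen finds recurrently deleted, silenced genes.
3. **Core signature** — candidates recurring in ≥ 3 cohorts, with
   per-gene inclusion counts.
4. **Hypoxia association** — a per-sample hypoxia score (mean z-scored
   expression of a hypoxia-response signature) is correlated with each
   gene's expression or dosage; the core signature's correlations are
   compared with the remaining metabolic genes by a one-sided rank-sum
   test, and per-sample gained fractions are compared between high- and
   low-hypoxia samples.
5. **Permutation nulls and overlaps** — million-pair mRNA–mRNA correlation
   nulls with 95th/5th percentile cutoffs, size-matched random gene-set
   enrichment (add-one empirical p-values), exact hypergeometric overlap
   tails and their permutation analogues, Fisher-exact amplification
   co-occurrence with cytoband proximity clustering.
6. **Prognosis** — median-dichotomised univariate Cox/log-rank analysis,
   and repeated random-split multivariate modelling: a log-rank screen
   (*P* < 0.1, training half only) followed by LASSO-penalised Cox
   regression with 10-fold cross-validated penalty choice, scored by
   Harrell's concordance index on the held-out half; per-gene inclusion
   frequencies summarise feature stability.

Real cohort data of this kind is access-controlled, so the package ships a
**synthetic multi-cancer cohort generator** with planted ground truth
(drivers with tunable dosage coupling, a latent hypoxia axis that raises
both signature-gene expression and the gain probability of hypoxia-coupled
drivers, prognostic genes with known log-hazard coefficients). Every stage
of the pipeline is validated against these known answers; see
`docs/methods.md` for the generative model and its limitations.

## Worked example

```python
from metadriver import SimulationParams, simulate_pan_cancer, simulate_cohort, run_driver_cascade
from metadriver import hypoxia_score, gene_hypoxia_correlations, signature_vs_other_test, spearman

params = SimulationParams(seed=1)          # 3 cohorts, 200 tumours / 50 normals, 2000 genes
cohorts = [bundle for bundle, _ in simulate_pan_cancer(params)]
_, truth = simulate_cohort(params, 0)

per_cohort, core = run_driver_cascade(cohorts, min_cancers=3)
print(f"core signature: {len(core.genes)} genes "
      f"({len(core.genes & truth.planted_drivers)} of {len(truth.planted_drivers)} planted drivers)")

bundle = cohorts[0]
score = hypoxia_score(bundle.tumour_expr, bundle.hypoxia_signature)
rho, _ = spearman(score, truth.latent_hypoxia)
print(f"hypoxia score vs latent hypoxia: Spearman rho = {rho:.2f}")

metabolic = list(bundle.annotation.loc[bundle.annotation["is_metabolic"], "gene_id"])
other = [g for g in metabolic if g not in core.genes]
sig_rhos = gene_hypoxia_correlations(bundle.tumour_expr, score, sorted(core.genes),
                                     exclude=bundle.hypoxia_signature)
other_rhos = gene_hypoxia_correlations(bundle.tumour_expr, score, other,
                                       exclude=bundle.hypoxia_signature)
print(f"signature-vs-other hypoxia correlation: one-sided P = "
      f"{signature_vs_other_test(sig_rhos, other_rhos):.2g}")
```

prints

```
core signature: 20 genes (20 of 20 planted drivers)
hypoxia score vs latent hypoxia: Spearman rho = 0.87
signature-vs-other hypoxia correlation: one-sided P = 9.8e-05
```

The cascade recovers all 20 planted drivers with no false positives among
the 1980 other genes; the hypoxia score tracks the latent per-sample
hypoxia level it is meant to estimate; and the planted drivers correlate
with that score significantly more strongly than the other metabolic genes
— the association pattern the pipeline is designed to detect.

## Command line

Every stage is exposed as a `metadriver` subcommand operating on plain
tab-separated files (all randomised commands take `--seed` and rerun
byte-identically):

```bash
metadriver simulate  --config sim.yaml --out cohorts/
metadriver call-scna --in cn_log2.tsv --out calls.tsv [--merge-gain-amp]
metadriver diffexpr  --tumour t.tsv --normal n.tsv --out de.tsv [--no-q-filter]
metadriver drivers   --cohort-dir cohorts/ --min-cancers 3 --out drivers.tsv
metadriver hypoxia   --cohort-dir cohorts/cancer_0 --genes core.txt --out hypoxia.tsv
metadriver nulls     --cohort-dir cohorts/cancer_0 --drivers core.txt --seed 7 --out nulls.json
metadriver cooccur   --calls calls.tsv --genes candidates.txt --merged --out cooccur.tsv
metadriver survival  --cohort-dir cohorts/cancer_0 --genes pool.txt --repeats 1000 --seed 7 --out survival.json
```

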