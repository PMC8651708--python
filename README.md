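# polytrainsel

Training-set construction for genomic prediction in autotetraploids.

## The problem

Genomic prediction (GP) regresses phenotypes on genome-wide markers to
predict the genotypic values of individuals that have been genotyped but
not phenotyped. Before any model is fitted, a breeder must decide *which*
individuals to phenotype — the training set — and in polyploid crops such
as potato this choice interacts with dosage-coded marker data (0–4 copies
of the alternate allele at each biallelic SNP in a tetraploid, so the
heterozygous classes AAAB/AABB/ABBB are distinguished).

`polytrainsel` implements, end to end, the machinery needed to study this
question on tetraploid dosage data:

* **Panel I/O and QC** — dosage matrices from TSV or VCF (DS/GT), marker
  filters (monomorphic, unmapped, MAF < 5%, missingness).
* **A synthetic panel generator** — Balding–Nichols subpopulations,
  Binomial(4, p) dosages, traits with exact realized heritability; the
  defaults emulate a 190-line, 3,262-SNP diversity panel in 3 weakly
  separated groups (pairwise Fst ≈ 0.01–0.02).
* **Four genetic distance measures** for polyploid dosages — Nei,
  Euclidean, Jaccard, Kosman–Leonard — with conversion to the [0,1]
  similarity form samplers need, and Mantel tests between matrices.
* **The VanRaden relationship matrix** on recoded dosages
  {0..4} → {−1, −0.5, 0, 0.5, 1}: A = QQ′ / (2Σp_j(1−p_j)).
* **Four training-set samplers** — simple random (SRS), stratified
  proportional allocation n_S = (n/N)·N_S, genetic-distance sampling by
  radial exclusion (core-collection style: each pick discards all
  candidates within radius r, with r tuned to the target size), and
  CDmean, which maximises the mean generalized coefficient of
  determination of contrasts between unphenotyped individuals and the
  candidate average,
  CD(c) = diag[c′(A − λ(Z′MZ + λA⁻¹)⁻¹)c / c′Ac], λ = (1−h²)/h².
* **Three whole-genome prediction models** — GBLUP (REML via spectral
  decomposition), RKHS with a Gaussian kernel K = exp(−D/θ) and a θ grid
  search on (0, 1], and BayesC-π (Gibbs; π = proportion of zero-effect
  markers, estimated from the data).
* **Two evaluation schemes** — training–validation (train on n of 190,
  validate on the complement) and training–test (a common held-out test
  set per realization) — plus a full-factorial ANOVA of Fisher-z
  accuracies over method × size × model.

## Worked example

```python
import polytrainsel as pts

panel = pts.simulate_panel(pts.SimConfig(n_markers=1000, seed=1))
trait = pts.simulate_trait(panel, n_qtl=10, h2=0.85, seed=2)

A   = pts.vanraden_A(panel)
ids = list(panel.genotype_ids)

design = pts.cdmean_select(A, ids, n=150, h2=0.5, seed=3,
                           max_stall=300, n_starts=1)
print(f"mean CD of design: {design.diagnostics['mean_cd']:.3f}")

train = design.training_ids
test  = [g for g in ids if g not in set(train)]
sub   = pts.TraitSet(train, trait.series().loc[train].to_numpy())
fit   = pts.bayesc_fit_predict(panel, sub, test, seed=4)
acc   = pts.accuracy(fit.predictions, trait.series())
print(f"BayesC-pi: accuracy = {acc:.3f}, posterior pi = {fit.pi:.3f}")
```

```
mean CD of design: 0.077
BayesC-pi: accuracy = 0.921, posterior pi = 0.991
```

The mean CD is the optimised precision of the contrasts between each of
the 40 left-out individuals and the candidate average; the accuracy is
the Pearson correlation between their predicted genotypic values and
observed phenotypes, and π ≈ 0.99 says the mixture prior excluded nearly
all of the 1,000 markers, consistent with the sparse 10-QTL architecture.
(At the full 3,262-marker default with independent markers, absolute
accuracies are much lower — see `docs/methods.md` on the no-LD regime.)

The numbered drivers under `analysis/` run the full study on the
synthetic panel: `01_simulate_panel.py` (panel, traits, QC),
`02_distance_measures.py` (Mantel comparison of the four measures),
`03_population_structure.py` (AMOVA, pairwise Fst, PCA),
`04_tv_scheme.py` and `05_tt_scheme.py` (sampler × size × model
comparisons with the accuracy ANOVA). Each writes its tables under
`results/`. A `polytrainsel` command-line interface wraps the same
functions (`polytrainsel simulate|qc|dist|kinship|structure|sample|
predict|evaluate|anova`, see `--help`).

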