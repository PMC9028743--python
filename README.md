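# cochleapharm

Transcriptome-guided drug repurposing for age-related hearing loss
(presbycusis), built around the functional substructures of the cochlea:
the sensorineural organ of Corti + spiral ganglion neurons (**OC/SGN**)
and the endocochlear-potential-generating stria vascularis + spiral
ligament (**SV/SL**).

The package takes bulk RNA-seq count matrices from a 2-substructure x
2-age (young/old) x n-replicate design and carries them through:

1. **QC and normalization** — median-of-ratios size factors, Pearson
   correlation clustering, PCA on top-variable genes, top-k abundance
   overlap between substructures;
2. **Differential expression** — a transparent negative-binomial GLM Wald
   test per gene (log link, size-factor offset, variance
   mu + alpha·mu², mean–dispersion trend alpha(mu) = a0/mu + a1),
   Benjamini–Hochberg FDR, and direction calls (up: log2FC > 0 and
   FDR < 0.05; down: log2FC < 0 and FDR < 0.05);
3. **Enrichment** — hypergeometric over-representation of GMT gene sets
   against the expressed-gene universe, P(X ≥ k) with
   X ~ Hypergeom(N, K, n), run separately for up- and downregulated
   genes, plus curated ageing / senescence / deafness list overlap;
4. **Drug repurposing** — the core selection rule: a (drug, target) pair
   is admitted iff the target is a significant DEG, the drug is
   *approved*, *specific* (exactly one protein target), *safe* (not
   ototoxic) and *mechanism-concordant* — antagonist-class actions
   (antagonist / inhibitor / binder / antibody / degrader) for
   upregulated targets, agonist-class actions (agonist / partial
   agonist / activator) for downregulated targets;
5. **Druggability landscape** — Pharos-style target development levels
   with strict precedence Tclin > Tchem > Tbio > Tdark;
6. **GO-slim networks** — bipartite gene ↔ slim-term graphs under the
   true-path rule (a gene annotated to a term is annotated to every
   ancestor), exported as GraphML.

Because raw sequencing data are not bundled, a first-class synthetic
generator (`cochleapharm.simulate`) plants known ground truth — NB counts
where substructure explains far more variance than age, gene sets
enriched by construction, and drug catalogs with planted candidates and
single-violation decoys — so every stage is testable end to end.  A
curated fixture additionally encodes the published DEG directions and
drug–target pairs for the candidate-selection stage.

## Worked example

```sh
python analysis/01_simulate_cohort.py --seed 42
python analysis/02_qc_clustering.py
python analysis/03_differential_expression.py
python analysis/05_drug_candidates.py
```

prints (abridged):

```
simulated 5000 genes x 12 samples (seed 42); 1500 substructure-DE genes,
461 age-DE genes, 8 planted drug candidates -> results/synthetic
PC1 explains 85.7% of variance, PC2 3.2% (substructure separation dominates the age signal)
OC_SGN: 230 DEGs at FDR<0.05 (117 up, 113 down)
  planted-effect recall 89.4%, realized FDR 4.8%
SV_SL: 240 DEGs at FDR<0.05 (119 up, 121 down)
  planted-effect recall 86.3%, realized FDR 7.9%
shared DEGs: 33 (14.3% of OC/SGN, 13.8% of SV/SL)
fixture: 27 distinct drugs selected (12 OC/SGN, 15 SV/SL)
  rejected decoy-ototoxic -> ITGB3: failed non_ototoxic
  ...
```

PC1 separating the two substructures while age contributes a small
second axis, largely non-overlapping DEG sets, high recall of planted
age effects at controlled FDR, and the 27-drug selection (12 targeting
OC/SGN DEGs, 15 targeting SV/SL DEGs) with every decoy rejected at the
filter it violates are exactly the behaviours the pipeline is designed
to exhibit.  The same stages are available as `cochleapharm` CLI
subcommands (`simulate | qc | de | enrich | repurpose | tdl | network |
report | run-all`).

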