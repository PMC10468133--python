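# cofrac — co-fractionation profiling of CSF lipoprotein subspecies

Lipoproteins in human cerebrospinal fluid (CSF-Lps) are HDL-like
lipid–protein nanoparticles present at roughly 100-fold lower concentration
than their plasma counterparts. Characterizing their subspecies requires
coupling a fluorescent size-exclusion elution profile (which populations of
particle sizes exist?) with per-fraction label-free proteomics (which
proteins ride which particles?). `cofrac` implements that computational
pipeline end to end, for analysts working with fluorescence-detected SEC
traces and MaxQuant-style protein-group tables:

1. **Trace profiling** — read, peak-normalize, replicate-average, and
   integrate elution traces into 1-ml collection fractions; linear
   signal-vs-phospholipid-mass calibration.
2. **Gaussian curve peeling** — deconvolve a trace into k Gaussian particle
   subpopulations, `y(v) = b + Σᵢ Aᵢ·exp(−(v−μᵢ)²/2σᵢ²)`, with k selected by
   BIC and each population quantified by its area share `Aᵢσᵢ√2π / Σⱼ Aⱼσⱼ√2π`.
3. **Proteome filtering** — the identification cascade (≥3 unique peptides;
   detected in the same fraction in all replicates; decoy and contaminant
   removal), replicate averaging, per-protein max-normalization, and overlap
   against a reference proteome list.
4. **Co-elution networks** — for all n(n−1)/2 protein pairs: global Pearson
   r; local Spearman ρ inside sliding ±2-fraction windows (one network per
   window, collapsed by union); and a reference-complex-trained Gaussian
   naive-Bayes classifier over profile features (PrInCE-style). Edges
   require score > 0.85.
5. **Consensus cliques** — edge-set intersection of the three methods,
   Fisher's-exact inter-method agreement (odds ratio > 1, p < 0.05), and
   Bron–Kerbosch maximal-clique enumeration: fully interconnected protein
   groups are the candidate particle subspecies.
6. **Functional-enrichment matrix** — offline hypergeometric GO-BP
   over-representation with Bonferroni < 0.01, a ±1 protein × term matrix,
   independent hierarchical co-clustering of both axes (Jaccard distance,
   average linkage) cut into a 10 × 10 grid, and functional-cluster calls
   for blocks with > 50 % correspondence.

A first-class synthetic-data module (`cofrac.simulate`) generates seeded
traces, co-fractionation tables with planted complexes, and block-structured
annotations, so every stage is testable against known ground truth.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic data
(seed 17) and write their tables under `results/`:

```sh
python analysis/01_simulate_data.py
python analysis/02_deconvolve_trace.py
python analysis/03_filter_proteome.py
python analysis/04_build_networks.py
python analysis/05_consensus_cliques.py
python analysis/06_functional_enrichment.py
```

which prints, stage by stage:

```
planted 10 trace populations, 10 complexes over 120 proteins, 10 annotation modules -> results/data
selected k=10 populations (planted 10); R^2=0.99755; worst mean error 0.068 ml; most intense point at 31.8 ml
136 protein groups -> 102 proteins (peptide rule 18, co-occurrence 0, decoys 8, contaminants 8); 52 shared with the reference, study-unique proteins carry 49.8% of summed intensity
5151 pairs evaluated over 24 local windows; edges: pcc=481, local_spearman=2069, prince=206; all method pairs significantly associated: True
206 consensus edges -> 45 maximal cliques (sizes {2: 15, 3: 10, 4: 8, 5: 3, 6: 5, 7: 4}); 10/10 planted complexes recovered at >=80% membership
80 terms tested on 102 proteome proteins, 38 significant at Bonferroni<0.01; 11 functional clusters called in the 10x10 grid; 8/10 planted modules recovered
```

Reading the output: the BIC-selected deconvolution finds exactly the ten
planted particle populations with sub-0.1-ml mean accuracy; the filter
cascade accounts for every removed row by rule; the local-Spearman method is
the most permissive scorer and the consensus intersection the most
conservative, as expected; every planted complex surfaces as a maximal
clique of the consensus network; and the enrichment matrix recovers the
planted functional modules as high-correspondence blocks.

The same workflow is available as a CLI (`cofrac simulate | profile | peaks |
filter | networks | cliques | enrich | run`); `cofrac run --config cfg.yaml
--outdir run/` executes all stages and writes a manifest whose hashes are
byte-identical across reruns.

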