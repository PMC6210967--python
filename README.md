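# panevo

Comparative pan-genomics of bacterial genome collections, built for the
kind of genus-level studies done on probiotic and gut bacteria
(*Bifidobacterium* and friends): how large is the shared gene repertoire,
is the pan-genome open or closed, what selection pressure acts on the core
genes, which functions track genome size, and which host proteins do the
core proteins plausibly interact with.

It is a library plus a thin `panevo` command-line pipeline for:

* **Gene-family clustering** — greedy centroid clustering of proteomes at
  an identity threshold (default 50%), producing the family-by-genome
  presence matrix and its core / accessory / unique partition.
* **Rarefaction and openness** — pan(n) and core(n) curves over random
  genome orderings (default 30 iterations), a Heaps-law fit
  `pan(n) = κ·n^γ`, an exponential core-decay fit, and an explicit,
  auditable open/closed verdict.
* **Selection pressure** — per-genome codon-usage relative entropy
  (Kullback–Leibler divergence against a positional-nucleotide or
  uniform-synonymous null, with a finite-sample bias correction) compared
  core-vs-chromosome by Welch's t-test; and Nei–Gojobori Ka/Ks (ω) on
  codon alignments of core families, with Jukes–Cantor correction,
  pathway-averaged difference counting, and explicit saturated/undefined
  flags. ω < 1 indicates purifying selection, ω > 1 positive selection.
* **Feature statistics** — COG-class abundance matrices (multi-class
  genes under `MC`; `R`/`S`/`MC` excluded from inference), Spearman
  correlation of features against genome size (exact permutation p below
  n = 10), Kruskal–Wallis group tests, and a conserved-peptide scanner
  (default query: the SecA immunomodulatory peptide `FAIVDEVDSILIDEAR`
  and its single-mismatch variants).
* **Interolog PPI transfer** — host–microbe interaction prediction from
  template interactomes under the standard homology filters (e-value
  ≤ 1e-10, identity ≥ 30%, query coverage ≥ 60%, template coverage
  ≥ 90%, co-complex detection methods excluded), with worst-of-pair joint
  scores and full provenance per predicted edge.
* **Synthetic data** — a generator with known ground truth (tunable Heaps
  exponent, planted ω and Ks, class-specific codon bias, planted feature
  correlations) that every stage is validated against.

See `docs/methods.md` for the models, conventions, and their rationale.

## Worked example

Generate a small closed-pool dataset with planted ω = 0.2 and analyze it
end to end:

```python
import numpy as np
from panevo import (PanGenomeModel, EvolutionModel, generate_pangenome,
                    ProteinRecord, greedy_cluster, build_pan_matrix,
                    partition_pan, rarefy, fit_openness, codon_align,
                    family_omega)

model = PanGenomeModel(n_genomes=8, core_families=60, openness_mode="closed",
                       pool_size=100, mean_length_codons=120, seed=1)
evo = EvolutionModel(omega_target=0.2, ks_target=0.5, seed=1)
ds = generate_pangenome(model, evo)

proteins = [ProteinRecord(g, gm, s) for g, gm, s in ds.protein_records()]
assignment = greedy_cluster(proteins, threshold=0.50)
genome_of = {g: gm for g, gm, _ in ds.protein_records()}
matrix = build_pan_matrix(assignment, genome_of, genome_ids=ds.genome_ids)
core, accessory, unique = partition_pan(matrix)
print(f"{len(assignment)} families: {len(core)} core, "
      f"{len(accessory)} accessory, {len(unique)} unique")

fit = fit_openness(rarefy(matrix, iterations=30, seed=1))
print(f"openness: {fit.verdict} (gamma = {fit.gamma:.3f}, "
      f"95% CI {fit.gamma_ci[0]:.3f}..{fit.gamma_ci[1]:.3f})")

cds = ds.cds_by_gene()
omegas = []
for fam in core[:20]:
    rec = family_omega(codon_align([(g, cds[g]) for g in assignment.families[fam]]))
    if rec.omega_defined:
        omegas.append(rec.omega)
print(f"core-family omega: mean {np.mean(omegas):.3f}, max {max(omegas):.3f} "
      f"({len(omegas)} families, all < 1: {all(w < 1 for w in omegas)})")
```

Output:

```
100 families: 63 core, 33 accessory, 4 unique
openness: closed (gamma = 0.113, 95% CI 0.089..0.136)
core-family omega: mean 0.183, max 0.204 (20 families, all < 1: True)
```

Reading it: the clustering recovers the finite pool (the 3 extra "core"
families beyond the 60 planted are pool families that happened to occur in
all 8 genomes); the saturating pan curve is classified closed even though
its log–log slope is nominally positive — the verdict combines the
exponent's confidence interval with a power-law-versus-saturation model
comparison; and every core family shows ω well below 1, the signature of
purifying selection, close to the planted 0.2.

The same stages are available from the shell:

```bash
panevo simulate --n-genomes 8 --mode closed --core-families 60 \
    --pool-size 100 --seed 1 --outdir sim/
panevo cluster sim/*.faa --outdir clust/
panevo rarefy clust/pan_matrix.tsv --outdir rare/
panevo run-all config.yaml       # full pipeline from a YAML config
```

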