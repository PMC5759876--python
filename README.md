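# pangtm

Comparative pan-genomics and gene-trait matching (GTM) for bacterial strain
collections, built around the kind of analysis used to dissect carbohydrate
utilization in *Bifidobacterium longum* isolates: cluster proteins into gene
families, partition the pan-genome, fit pan/core accumulation curves, build a
core-gene consensus supertree, binarize OD600 growth phenotypes, and match
gene-family occurrence patterns against growth phenotypes to nominate
carbohydrate-utilization gene clusters.

The package is aimed at microbial comparative genomicists who have per-genome
protein FASTA files (plus all-vs-all BLAST tabular output and OD600 growth
measurements) and want a tested, deterministic reimplementation of this
pipeline — together with a synthetic pan-genome generator that plants
trait-linked gene clusters with known ground truth, so every stage can be
validated end to end.

## Methods at a glance

- **Family clustering.** All-vs-all protein similarities are filtered at
  ≥ 50% identity and e-value ≤ 1e-4, symmetrized into a weighted graph
  (edge weight = max bitscore, or percent identity on the internal
  alignment path), and clustered with a from-scratch Markov Cluster
  Algorithm (MCL): alternate expansion (M ← M²) and inflation
  (M ← normalize(M∘ʳ)) with pruning until a fixed point; inflation r = 2.5.
- **Pan-genome.** With presence/absence matrix A (families × genomes),
  core = rows present in all G genomes, unique (TUGs) = rows present in
  exactly one, variable = everything non-core. Accumulation curves over
  random genome orderings are fitted with a Heaps-type power law
  P(N) = κ·N^γ (pan) and an exponential decay C(N) = Ω + A·e^(−N/τ)
  (core), so Ω estimates the asymptotic core size.
- **Phylogeny.** Single-copy core families (exactly one member in every
  genome) give per-family p-distance matrices → Saitou–Nei neighbor
  joining → strict majority-rule consensus (clades in > 50% of family
  trees, support = % of trees) → rooting on a designated outgroup.
- **Phenotyping.** Growth on a carbohydrate is called from the 12-h OD600:
  good (> 0.5), moderate ([0.4, 0.5]), none (< 0.4); the binary call for
  matching is 0 below 0.3 and 1 above 0.4, with readings in [0.3, 0.4]
  surfaced as INDETERMINATE.
- **Gene-trait matching.** After dropping core families and families
  annotated as mobile/defence elements, families with identical occurrence
  patterns collapse into genotype rows; each row is scored against each
  differential phenotype row as the percent of strains with equal calls;
  cells strictly above 95% are reported as candidate gene clusters.

## Worked example

Simulate a 20-strain species with a 400-family core, 600 dispensable
families (four of them planted as trait clusters), recover the clusters by
GTM, and summarize the bundled 20-isolate genome statistics table:

```python
from pangtm import (
    SimulationConfig, simulate_pangenome, simulate_growth_curves,
    presence_absence_from_genomes, build_phenotype_matrix,
    family_annotations, build_genotype_matrix, collapse_patterns,
    match_all, report_hits, genome_summary,
)
from pangtm.datasets import load_genome_stats

cfg = SimulationConfig(seed=1)
genomes, annotations, truth = simulate_pangenome(cfg)
strains = list(cfg.strains)

matrix = presence_absence_from_genomes(genomes, strains)
families = {f: {s: [f"{s}|{f}|0"] for s in m if s in set(strains)}
            for f, m in truth.family_membership.items()}
families = {f: d for f, d in families.items() if d}
fam_ann = family_annotations(families, annotations)
filtered, dropped = build_genotype_matrix(matrix, fam_ann)
patterns = collapse_patterns(filtered, annotations=fam_ann)
pheno = build_phenotype_matrix(simulate_growth_curves(truth, cfg))
hits, _ = report_hits(match_all(patterns, pheno), patterns)
for h in hits:
    print(h.carbohydrate, h.match_pct, len(h.families))

summary = genome_summary(load_genome_stats())
print(summary["orfs"]["mean"], summary["orfs"]["sd"],
      summary["gc_percent"]["mean"])
```

prints

```
arabinan 100.0 8
arabinoxylan 100.0 7
galactan 100.0 6
xylooligosaccharides 100.0 5
1961 107 59.99
```

Each hit is a genotype pattern whose presence/absence across the 20 strains
agrees 100% with growth on one carbohydrate; the member families are exactly
the planted cluster genes. The last line is the ORF-count mean, population
standard deviation, and mean GC% over the bundled isolate table.

The same pipeline runs from the shell:

```bash
pangtm run-all --seed 1 --outdir work/
pangtm simulate --seed 1 --outdir sim/
pangtm cluster --genomes sim/ --min-pid 50 --max-evalue 1e-4 --inflation 2.5 --outdir clust/
pangtm phenotype --curves sim/growth_curves.csv --time 12 --outdir pheno/
```

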