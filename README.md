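# plumhap

Haplotype analysis of the Japanese plum *MYB10* anthocyanin gene cluster from
dominant PCR-band genotypes.

Japanese plum fruit colour (yellow-green through red to purple-black) is
largely controlled by *MYB10* transcription factors in a tandemly duplicated
cluster on linkage group 3.  A single conserved primer pair amplifies alleles
of all cluster copies at once, yielding multi-band dominant genotypes: each
accession shows the union of the band sets of its two chromosomes.  `plumhap`
turns such data into breeding-relevant results:

* **Family phasing** — infer parental haplotypes from band co-segregation in
  F1 progeny (bands in phase agree across progeny; bands in anti-phase
  complement), and merge them across families into a haplotype catalog.
* **Panel calling** — explain unrelated accessions as unions of two catalog
  haplotypes by exhaustive pair search; infer a provably minimal set of new
  haplotypes for the remainder by parsimony.
* **Gene copy number** — count in-phase alleles per homology group: two bands
  segregating in phase cannot be alleles of one single-copy gene, so the
  count is a lower bound on the gene's copy number per haplotype.
* **Colour association & prediction** — Pearson χ² (2×2, no continuity
  correction) of band/haplotype carriers against the binary anthocyanin
  phenotype, and a marker rule predicting skin colour from the a356 band.
* **Sequence statistics** — nucleotide diversity π with explicit gap
  handling, Nei–Gojobori Ka/Ks, TN93 distances, UPGMA trees with bootstrap.
* **Read depth** — normalised coverage, breadth, genic/intergenic ratios over
  the cluster region, the raw material for coverage-based copy-number calls.
* **Simulation** — a generator reproducing the whole study design (six F1
  families, an 81-accession panel with rare haplotypes, penetrance, Poisson
  depth, allele alignments) so every stage is testable end to end offline.

## Worked example

```python
from plumhap import (
    SimulationConfig, simulate_catalog, simulate_families, simulate_panel,
    build_catalog, infer_panel_haplotypes, copy_counts, chisq_2x2,
    reference_gene_map,
)

cfg = SimulationConfig(seed=1)
truth_catalog, gene_map = simulate_catalog(cfg)

# phase six F1 families (50 progeny each) into a haplotype catalog
fams = simulate_families(cfg, truth_catalog, n_progeny=50)
build = build_catalog([fr.family for fr in fams])
print(len(build.catalog.haplotypes))          # 6

# explain an 81-accession panel against the family catalog
panel = simulate_panel(cfg, truth_catalog)
calls = infer_panel_haplotypes(panel.genotypes, build.catalog, gene_map=gene_map)
print(f"{calls.explained_fraction:.2%}")       # 91.36%
print(len(calls.new_haplotypes))               # 5

# copy numbers from in-phase allele counts
report = copy_counts(build.catalog, reference_gene_map())
print(report.min_copy_number)                  # {'G1': 3, 'G2': 1, 'G3': 1}

# colour association from the study's printed carrier counts
chi2, p, _ = chisq_2x2(((52, 1), (0, 28)))
print(f"chi2={chi2:.2f}, p={p:.3g}")           # chi2=76.73, p=1.96e-18
```

The six families recover the six-haplotype catalog exactly; those haplotypes
explain 74 of 81 panel accessions (91.36%), and parsimony infers the five rare
haplotypes carried by the remaining seven.  Three in-phase G1 alleles in H1
and H3 imply at least three copies of the *MYB10.1* gene, and the a356 band
associates with skin colour at p = 1.96 × 10⁻¹⁸.

A CLI mirrors the pipeline for shell use:

```bash
plumhap simulate --seed 1 --out fixtures/
plumhap phase --bands fixtures/band_matrix.csv --pedigree fixtures/pedigree.csv \
              --catalog-out catalog.json
plumhap haplocall --bands fixtures/band_matrix.csv --catalog catalog.json \
                  --gene-map fixtures/gene_map.csv --out calls
plumhap assoc --bands fixtures/band_matrix.csv --phenotypes fixtures/phenotypes.csv \
              --predict-band a356 --out assoc.csv
plumhap diversity --fasta fixtures/alleles.fasta --out div
```

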