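# genopheno

Gene–phenotype–mode-of-inheritance association screening for
HPO-phenotyped, exome-genotyped cohorts.

Given a multi-sample VCF, a per-variant annotation table (gnomAD AC/AN/HOM,
CADD Phred, caller filter status, distance to the nearest coding region), a
patient phenotype table and an HPO ontology in OBO format, the tool:

1. **filters variants** — caller-PASS, gnomAD-covered, ≤ 5 bp from a coding
   region, per-cohort missingness < 20%;
2. **bins each gene's variants** on genotype frequency (GF) × CADD, where GF
   is the gnomAD allele frequency under a dominant model and the estimated
   homozygote frequency `2·HOM/AN` under a recessive model;
3. **finds per-bin carriers** — any het/hom call (dominant) or
   homozygous/compound-heterozygous carriage (recessive; the second variant
   must have an equal-or-higher CADD and an equal-or-lower GF);
4. **Fisher-tests each bin** for case enrichment, cases being the patients
   annotated with the queried HPO term or any of its descendants;
5. **collapses the rare column** (GF < 1/4000) into a goodness-of-fit score
   `HGF = −ln(1 − Φ(Z))` via a weighted, scaled Stouffer combination of the
   per-bin z scores;
6. **predicts the mode of inheritance** from `M = HGF × SR`, where the
   signal ratio SR is the fraction of the heatmap's −ln(p) mass in the rare
   column; the larger branch wins.

A synthetic-cohort simulator (ontology, phenotypes, genotypes, annotations,
truth set) makes the whole pipeline testable with no external data, and a
benchmarking module reproduces the comparator models (Fisher's method,
HGF-only MOI calls, allele-frequency-based recessive GF) and their
error-rate curves against a truth set.

## Run the tests

```sh
python -m pytest -q tests/
```

The suite includes `tests/test_acceptance.py`, which runs the full
simulation-based acceptance criteria (about 2 minutes on one CPU).

## CLI

```sh
# generate a synthetic cohort (VCF, annotations, phenotypes, OBO, truth)
genopheno simulate --params params.yaml --out simdir/

# screen every gene-term pair and export ranked results + heatmaps
genopheno run --vcf simdir/cohort.vcf --annotations simdir/annotations.tsv \
    --phenotypes simdir/phenotypes.tsv --obo simdir/ontology.obo \
    --out rundir/ --np-cutoff 10

# error-rate curves against a truth set, for all comparator models
genopheno benchmark --results rundir/results.tsv --truth simdir/truth.tsv \
    --obo simdir/ontology.obo --out benchdir/
```

`genopheno run` accepts `--gene` / `--term` restrictions; a term of the form
`HP:A&HP:B` runs a conjunction query (cases must carry all listed terms).
Configuration is a flat YAML file mirroring the `GenonConfig` fields
(bin sizes, weights, Stouffer denominator, SR denominator, GF convention,
NP cutoff, …); CLI flags override file values, and the effective
configuration is echoed into `manifest.json` in every output directory.

## Library

```python
from genopheno import (GenonConfig, parse_obo, load_cohort, filter_variants,
                       screen_cohort, build_heatmap)

ontology = parse_obo("hp.obo")
cohort = filter_variants(load_cohort("cohort.vcf", "ann.tsv", "pheno.tsv",
                                     ontology), GenonConfig())
results = screen_cohort(cohort, ontology, GenonConfig(np_cutoff=10))
```

Modules: `ontology` (OBO parsing, descendant closure, case/control split),
`cohort` (VCF/TSV readers, genotype matrix, variant filters), `genon`
(binning, carriers, per-bin Fisher tests, heatmap export), `scoring`
(Stouffer/HGF/SR/M, comparator scorers), `screen` (cohort-wide screening,
positive-term selection, benchmarking), `synthetic` (simulator), `cli`.

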