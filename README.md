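# chprev

Carrier frequency and predicted genetic prevalence of autosomal
recessive congenital hypothyroidism, estimated from population-scale
allele-count data.

Congenital hypothyroidism caused by thyroid dyshormonogenesis (and a
handful of recessive dysgenesis and central forms) is driven by twelve
genes inherited in an autosomal recessive pattern: *SLC5A5*, *TPO*,
*TG*, *IYD*, *DUOXA2*, *DUOX2*, *TSHR*, *SLC26A7*, *GLIS3*, *FOXE1*,
*TSHB*, *TRHR*. Given ancestry-stratified variant summaries in the
gnomAD v2.1.1 style (AC/AN/nhomalt per population, LOFTEE calls,
in-silico scores, ClinVar status), this package

1. classifies every variant with an ACMG/AMP-style evidence engine
   (loss-of-function decision tree with the 50-nt NMD rule, rarity,
   in-trans, co-segregation, in-silico and domain codes, SVI strength
   modulation) into the five-tier scale, keeping the pathogenic /
   likely pathogenic variants (PLPVs);
2. turns the PLPV allele counts into carrier frequencies and
   Hardy–Weinberg birth-prevalence predictions per gene and ancestry
   group.

It is written for laboratory geneticists and genetic epidemiologists
who want to audit or re-run this kind of panel analysis, and ships a
synthetic-cohort generator with known ground truth so the whole
pipeline is testable without any download.

## Model

For a variant *V* with allele count AC, allele number AN and homozygote
count nhom in a population,

```
AF_V = (AC − 2·nhom) / AN          heterozygous-only allele frequency
CF_V = 2·AF_V                      per-variant carrier frequency
```

(homozygotes are stripped: the reference cohort is assumed healthy, so
observed homozygotes are not counted toward carrier risk). Variants of
a gene *G* combine as

```
CF_G  = 1 − Π_k (1 − CF_V,k)                  complement product
pGP_G = (Σ_k CF_V,k / 2)²                     random-mating prevalence q²
```

with q = Σ CF_V / 2 the gene-level pathogenic allele frequency.
Cross-gene population totals are sums of CF_G and pGP_G.

## Worked example

Generate a synthetic gnomAD-like cohort, classify it and compute
prevalence (the numbered drivers under `analysis/` run the same steps
and write their tables under `results/`):

```
$ chprev simulate --seed 1 --out cohort.tsv
wrote 36 records to cohort.tsv; truth in cohort.tsv.truth.json

$ python analysis/02_classify_variants.py
classified 36 variants: 31 PLPVs; points/rule-table agreement 36/36

$ python analysis/03_carrier_frequency.py       # excerpt
 gene population  n_plpv cf_percent pgp_per_100k pgp_ratio
TOTAL        EAS      12       4.02        14.47    1:6909
TOTAL        FIN       8       3.62        13.63    1:7339
TOTAL     GLOBAL      31       2.01         3.72   1:26873
```

Reading the excerpt: in the simulated East Asian group, 4.02% of
individuals carry one pathogenic allele across the panel, predicting
14.47 affected births per 100,000 (one in 6,909) under random mating.
The East Asian excess is driven by *DUOX2*/*DUOXA2* alleles, mirroring
the structure of the real gnomAD panel. `analysis/04_recovery_assessment.py`
checks the estimates against the generator's truth:

```
recovery over 192 gene/population checks: 0 outside the 5-SE allowance
median CF_G relative error: 0.037
```

The same CLI runs on real exports: `chprev report --input variants.tsv
--genes genes.yaml --out dir/ [--pm2-derive | --pm2 0.0003]
[--mode points|rule_table]`.

## Layout

- `src/chprev/` — library: `variant_io` (TSV / gnomAD-dialect VCF),
  `acmg` (evidence engine), `prevalence` (CF/pGP statistics),
  `simulate` (synthetic cohorts), `report` + `cli` (orchestration),
  `reference` + `data/` (bundled panel annotation and published
  estimates).
- `analysis/` — numbered drivers reproducing the study's analyses.
- `docs/methods.md` — model assumptions, parameter choices, numerical
  conventions and limitations.
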