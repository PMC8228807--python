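# Methods

## Scope and model

The package estimates, for an autosomal recessive disease panel, the
carrier frequency (CF) and predicted genetic prevalence (pGP) of each
gene in each ancestry group of a gnomAD-style reference cohort, after
building the pathogenic / likely-pathogenic variant (PLPV) set with an
ACMG/AMP-style evidence engine.

The statistical model is deliberately minimal:

- **Heterozygous-only allele frequency.** AF_V = (AC − 2·nhom)/AN.
  The reference cohort is treated as unaffected, so homozygous
  individuals (who would be patients for a fully penetrant recessive
  disease) are removed from the carrier numerator. The per-variant
  carrier frequency is CF_V = 2·AF_V, i.e. the estimator targets the
  true heterozygote rate 2p(1−p). The naive 2·AC/AN estimator would
  carry a positive bias of ≈2p² (tested; observable at p = 0.05).
- **Per-gene carrier frequency.** CF_G = 1 − Π(1 − CF_V): the
  probability of carrying at least one pathogenic allele in the gene,
  assuming independence across variants (no haplotype structure).
- **Per-gene prevalence.** pGP_G = (Σ CF_V / 2)², the double sum over
  ordered variant pairs CF_i·CF_k/4. This is random-mating q² with the
  gene-level pathogenic allele frequency approximated by q = Σ CF_V/2.
  An explicit O(n²) pairwise loop is kept as an independent oracle and
  the two are required to agree to 1e-12 relative tolerance.
- **Cross-gene totals are sums**, not complement products: a recessive
  disease needs two hits in the *same* gene, so gene-level prevalences
  add, and at panel-level frequencies (total CF ≲ 7%) carrier overlap
  between genes is negligible. The sum rule is also the one validated
  by recombining the published per-gene East Asian carrier frequencies:
  summing gives 7.44% (rounding to the published 7.4%), whereas the
  complement product gives 7.27% and would round to 7.3%.

Not modelled: linkage disequilibrium, consanguinity/inbreeding,
population substructure within an ancestry code, digenic inheritance
(e.g. *DUOX1*/*DUOX2*), reduced penetrance, and confidence intervals on
CF/pGP. pGP is a genetic prevalence under these assumptions, not an
incidence prediction.

## Evidence engine

Pathogenic-side codes only; ClinVar benign/likely-benign rows are
short-circuited out, ClinVar P/LP rows are retained as PLPVs without
re-evaluation (internal evaluation applies only to unknowns, which also
avoids circularity). PP4/PP5 are unrepresentable by construction.

- **LOFTEE filter.** Null variants (nonsense, frameshift, canonical
  splice) that are not already ClinVar P/LP are kept only with a
  high-confidence LOFTEE call and an empty flag list; a null variant
  with no LOFTEE call is filtered (logged).
- **PVS1 decision tree.** Truncation predicted to trigger NMD by the
  50-nt rule → VeryStrong; NMD-escaping truncation that removes a
  critical domain or >10% of the protein → Strong; otherwise Moderate;
  initiation loss → Moderate; only for genes whose configured disease
  mechanism is loss of function. Canonical splice variants run the same
  sub-tree on the CDS position parsed from the HGVS c. string — an
  approximation (the exact skipped-exon product would need an exon
  table the gene config does not carry); for these genes the canonical
  splice sites sit far from the NMD boundary, so the approximation only
  matters within 50 nt of the final junction.
- **PM2 (rarity).** Threshold = max(known pathogenic AFs)/10 rounded to
  one significant figure (so a spectrum topping out at 0.0029 yields
  0.0003). The comparison uses the homozygote-stripped global AF and an
  *inclusive* boundary (AF ≤ threshold) — absence/rarity semantics
  favour inclusion at the bound. Weighted Supporting, per current SVI
  practice. Per-population evaluation is a config switch.
- **PM3 (in trans).** Per-proband points (confirmed in trans with a
  pathogenic partner 1.0, with a likely pathogenic partner 0.5,
  homozygous 0.5, phase unknown 0.25) summed and mapped to a strength:
  ≥4 VeryStrong, ≥2 Strong, ≥1 Moderate, ≥0.5 Supporting. All values
  config-exposed.
- **PP1 (co-segregation).** Informative-meioses thresholds 7/5/3 →
  Strong/Moderate/Supporting. These defaults are this package's
  explicit placeholders for the working-group tables and are
  config-overridable.
- **PP3 (in silico).** Supporting, capped, predictors voting by OR:
  REVEL > 0.75 (strict, missense), splice-impact ≥ 0.2
  (splice-adjacent), PROVEAN ≤ −2.5 (in-frame indels). Only the REVEL
  cut-off is protocol-fixed; the others are package defaults.
- **PM1 (domain).** Moderate when the affected residue of a missense /
  in-frame variant lies in a configured critical-domain interval.
  Restricted to missense/in-frame so the same domain evidence is not
  double-counted with PVS1's domain branch.
- **PS3.** Accepted as a pre-assigned strength column; no evaluator
  exists because no accepted weighting scheme for functional assays
  does.

**Combining.** Two modes, required to agree on all bundled fixtures:
Bayesian points (Supporting 1, Moderate 2, Strong 4, VeryStrong 8;
≥10 Pathogenic, 6–9 LikelyPathogenic, else VUS) and the classic 2015
combining table on strength-modulated counts plus the SVI special case
PVS1 + PM2 → LikelyPathogenic. The two frameworks are known to diverge
on some combinations (e.g. PVS1 alone: 8 points vs. no table row), so
fixtures and the synthetic generator use evidence profiles on which the
published frameworks themselves agree. Both modes are property-tested
for monotonicity: adding evidence or raising a strength never lowers
the tier.

## Gene configuration

`data/genes.yaml` carries, per gene: MANE-convention transcript, coding
length (aa), the last exon–exon junction as a CDS offset (for the 50-nt
rule), curated critical-domain intervals, and the disease mechanism.
Coding lengths are UniProt canonical; junctions and domain intervals
are curated approximations meant as workable defaults and are fully
overridable — no test depends on their exact values. *FOXE1* is single
coding exon (junction 0), so its truncations always escape NMD.

## Synthetic cohorts

The generator emulates the gnomAD v2.1.1 summary structure: seven
ancestry groups at the real cohort sizes (12,487 AFR … 64,603 NFE;
141,456 pooled), per-variant per-population true pathogenic allele
frequencies, and annotation columns chosen so the evidence engine
reproduces a hand-derived intended tier for every variant.

- **Sampling.** Genotypes are drawn per individual (multinomial over
  HWE genotype classes), so nhomalt is realisable and the homozygote
  correction is genuinely exercised; AC = het + 2·hom, AN = 2n. The
  pooled GLOBAL column is the subpopulation sum. A deterministic mode
  assigns rounded expected genotype counts for exact fixtures.
- **Default study.** True AFs for the 12-gene panel come from the
  bundled 27-variant recurrent-PLPV table (span 1e-5–5e-3; the three
  founder-allele entries above 5e-3 are capped there), plus synthetic
  rare variants for the two panel genes absent from that table
  (*SLC5A5*, *GLIS3*; labelled synthetic), plus decoys that must never
  reach the PLPV set: LOFTEE low-confidence and flag-carrying nonsense
  variants, a ClinVar-benign missense, and sub-threshold-evidence
  missense variants. *FOXE1* carries no variants, exercising the
  zero-gene path end to end. The study's engine config uses an explicit
  PM2 threshold of 0.01 so that every rare pathogenic variant earns the
  rarity code and the SVI PVS1+PM2 path is exercised in both combining
  modes. Ground truth per gene/population: CF = 1 − Π(1 − 2p(1−p)),
  pGP = (Σp)².
- **Recovery tolerance.** Each variant's heterozygote count is
  Bin(n, h) with h = 2p(1−p); the per-gene CF allowance accumulates
  5·√(h(1−h)/n) per variant, and the pGP allowance propagates that
  through q². The pipeline's pGP targets (Σ p(1−p))², which sits below
  the truth (Σp)² by a relative ~2Σp²/Σp ≤ 1% at these frequencies —
  well inside the sampling allowance.
- **What passing does not show.** The generator has no linkage, no
  sequencing/annotation error, no missing-call structure, no ancestry
  admixture, and intended tiers are constructed to be reproducible; on
  real data, classification disagreements and coverage artefacts
  dominate, and recovery there is not implied.

Default problem sizes: 36 variants × 7 groups at the cohort sizes above
(~283k simulated individuals per variant); the estimator-bias check
uses 100 replicates of a 20,000-individual cohort at p = 0.05.

## Numerical conventions and degenerate inputs

- One-significant-figure rounding goes through a decimal mantissa to
  avoid float-representation noise (0.00029 → 3e-4 exactly); it is
  scale-equivariant for powers of ten.
- AN = 0 (no coverage) → frequency undefined: PM2 NotMet with a
  rationale, population skipped in CF tables; a missing AC/AN/nhomalt
  triplet skips the population and is never imputed as zero.
- A gene with no PLPVs reports CF 0.00, pGP "0.00 per 100,000 (1:inf)".
- Invalid count rows (AC > AN, 2·nhom > AC, odd AN) are rejected with
  row-level diagnostics; a GLOBAL allele count below a subpopulation
  count is rejected (the pool must be a superset), while a GLOBAL count
  below the subpopulation *sum* only warns, since the real pool includes
  ancestries not in the seven listed groups. A missing GLOBAL column is
  synthesized as the subpopulation sum (documented lower bound).
- Display: CF as percent to 3 significant figures with trailing zeros
  (0.018 → "1.80"); pGP both per-100,000 to 2 dp and as "1:round(1/p)";
  internal computation always at full precision.
- Variants are keyed by (gene, HGVS c.); HGVS strings are opaque (no
  normalisation, no genome-build handling); the only parsing is the
  leading integer for protein/CDS positions.
- Classification output preserves input order and is
  permutation-equivariant; ties in the consequence-class summary break
  by class name.

## Open choices made here

- The pooled GLOBAL column, when present in the input, is used directly
  for global figures (rather than recombining the seven groups).
- PP1 thresholds and PM3 points are explicit defaults, config-exposed.
- One merged critical-domain interval set per gene (no per-source
  Pfam/InterPro/UniProt arbitration).
- Only the direct per-variant CF → pGP route is implemented; no
  alternative gene-level estimator is provided.
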