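# Published panel-level estimates for the 12 autosomal recessive
# congenital hypothyroidism genes in gnomAD v2.1.1, used as reference
# inputs for cross-checks and worked examples. Carrier frequencies (CF)
# are percentages; predicted genetic prevalence (pGP) is per 100,000
# births with the equivalent 1:N ratio.
gene_cf_percent:
  GLOBAL:
    DUOX2: 1.8
    TG: 0.46
    TPO: 0.44
    TSHR: 0.31
    SLC26A7: 0.144
    DUOXA2: 0.141
    IYD: 0.08
    SLC5A5: 0.06
    TRHR: 0.059
    GLIS3: 0.059
    TSHB: 0.04
    FOXE1: 0.0
  EAS:
    DUOX2: 4.25
    DUOXA2: 1.06
    TSHR: 0.67
    TG: 0.57
    TPO: 0.57
    SLC5A5: 0.16
    GLIS3: 0.08
    SLC26A7: 0.04
    TRHR: 0.02
    TSHB: 0.01
    IYD: 0.01
    FOXE1: 0.0
total_cf_percent:
  GLOBAL: 3.6
  EAS: 7.4
  FIN: 5.4
  NFE: 3.6
  AFR: 2.54
  AMR: 2.51
  SAS: 2.1
  ASJ: 1.7
pgp_per_100k:
  GLOBAL: {per_100k: 10.01, ratio: 9992}
  EAS: {per_100k: 52.48, ratio: 1905}
  FIN: {per_100k: 35.96, ratio: 2781}
  NFE: {per_100k: 9.56, ratio: 10457}
  AFR: {per_100k: 4.0, ratio: 24981}
  AMR: {per_100k: 3.89, ratio: 25728}
  SAS: {per_100k: 3.56, ratio: 28103}
  ASJ: {per_100k: 1.81, ratio: 55282}
# Presumed pathogenic / likely pathogenic variant counts per gene and
# population (a variant is counted in a population when observed there).
plpv_counts:
  SLC5A5: {GLOBAL: 18, AFR: 1, AMR: 3, ASJ: 2, EAS: 5, FIN: 8, NFE: 6, SAS: 3}
  TPO: {GLOBAL: 79, AFR: 15, AMR: 13, ASJ: 4, EAS: 9, FIN: 3, NFE: 51, SAS: 9}
  TG: {GLOBAL: 163, AFR: 25, AMR: 29, ASJ: 5, EAS: 25, FIN: 5, NFE: 79, SAS: 32}
  IYD: {GLOBAL: 20, AFR: 5, AMR: 1, ASJ: 0, EAS: 1, FIN: 1, NFE: 14, SAS: 3}
  DUOXA2: {GLOBAL: 34, AFR: 8, AMR: 4, ASJ: 1, EAS: 4, FIN: 1, NFE: 12, SAS: 4}
  DUOX2: {GLOBAL: 143, AFR: 28, AMR: 37, ASJ: 3, EAS: 39, FIN: 6, NFE: 74, SAS: 24}
  TSHR: {GLOBAL: 53, AFR: 14, AMR: 11, ASJ: 1, EAS: 5, FIN: 2, NFE: 33, SAS: 6}
  SLC26A7: {GLOBAL: 46, AFR: 8, AMR: 8, ASJ: 1, EAS: 6, FIN: 1, NFE: 27, SAS: 5}
  GLIS3: {GLOBAL: 28, AFR: 5, AMR: 3, ASJ: 0, EAS: 4, FIN: 3, NFE: 18, SAS: 0}
  FOXE1: {GLOBAL: 0, AFR: 0, AMR: 0, ASJ: 0, EAS: 0, FIN: 0, NFE: 0, SAS: 0}
  TSHB: {GLOBAL: 8, AFR: 1, AMR: 0, ASJ: 0, EAS: 1, FIN: 1, NFE: 6, SAS: 1}
  TRHR: {GLOBAL: 18, AFR: 1, AMR: 0, ASJ: 0, EAS: 1, FIN: 4, NFE: 15, SAS: 1}
consequence_class_counts:
  nonsense: 218
  frameshift: 213
  splice_site: 125
  missense: 51
  inframe_indel: 3
clinvar_registered: {count: 89, total: 610}
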