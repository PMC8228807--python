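# Bundled annotation for the 12-gene autosomal recessive congenital
# hypothyroidism panel (thyroid dyshormonogenesis, recessive dysgenesis,
# isolated central hypothyroidism). Transcripts follow the MANE
# convention; coding lengths are UniProt canonical protein lengths.
# NMD junctions and domain intervals are curated approximations intended
# as workable defaults — override from a project config for locus-exact
# work.
genes:
  SLC5A5:
    transcript: NM_000453.3
    coding_length_aa: 643
    last_junction_cds: 1789
    domains:
      - {start: 40, end: 470, label: sodium/solute symporter core}
  TPO:
    transcript: NM_000547.6
    coding_length_aa: 933
    last_junction_cds: 2683
    domains:
      - {start: 142, end: 738, label: animal haem peroxidase}
  TG:
    transcript: NM_003235.5
    coding_length_aa: 2768
    last_junction_cds: 8188
    domains:
      - {start: 31, end: 1191, label: thyroglobulin type-1 repeats}
      - {start: 2192, end: 2716, label: ChEL domain}
  IYD:
    transcript: NM_203395.2
    coding_length_aa: 293
    last_junction_cds: 700
    domains:
      - {start: 80, end: 275, label: nitroreductase fold}
  DUOXA2:
    transcript: NM_207581.4
    coding_length_aa: 320
    last_junction_cds: 871
    domains: []
  DUOX2:
    transcript: NM_014080.5
    coding_length_aa: 1548
    last_junction_cds: 4501
    domains:
      - {start: 26, end: 593, label: peroxidase-like ectodomain}
      - {start: 1207, end: 1541, label: NADPH oxidase / FAD-binding}
  TSHR:
    transcript: NM_000369.5
    coding_length_aa: 764
    last_junction_cds: 2185
    domains:
      - {start: 36, end: 281, label: leucine-rich repeat ectodomain}
      - {start: 418, end: 683, label: 7TM receptor core}
  SLC26A7:
    transcript: NM_052832.4
    coding_length_aa: 656
    last_junction_cds: 1880
    domains:
      - {start: 41, end: 465, label: sulfate transporter domain}
      - {start: 513, end: 642, label: STAS domain}
  GLIS3:
    transcript: NM_001042413.2
    coding_length_aa: 930
    last_junction_cds: 2650
    domains:
      - {start: 495, end: 642, label: C2H2 zinc-finger cluster}
  FOXE1:
    transcript: NM_004473.4
    coding_length_aa: 373
    last_junction_cds: 0        # single coding exon; truncations escape NMD
    domains:
      - {start: 58, end: 152, label: forkhead DNA-binding domain}
  TSHB:
    transcript: NM_000549.5
    coding_length_aa: 138
    last_junction_cds: 100
    domains:
      - {start: 21, end: 125, label: glycoprotein hormone beta core}
  TRHR:
    transcript: NM_003301.6
    coding_length_aa: 398
    last_junction_cds: 1039
    domains:
      - {start: 37, end: 340, label: 7TM receptor core}
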