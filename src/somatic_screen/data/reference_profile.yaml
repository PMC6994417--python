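# Reference cohort profile: a 71-tumor two-stage lymphoma screen.
#
# 21 discovery tumors (exome + RNA for 18; 4 with matched saliva
# normals) plus 50 extension tumors (8 with matched normals), 20
# unmatched healthy-donor saliva normals (panel of normals), 8
# hyperplastic lymph-node controls. gene_freqs gives, per panel gene
# discovered by the exome screen, the number of tumors that carry a
# filter-surviving nonsynonymous variant; per_sample_burden gives the
# exome-wide nonsynonymous count of each discovery tumor (median 135,
# range 6-204; at exome_mb = 54 the median rate is 2.5/Mb).
name: reference
seed: 42
n_discovery: 21
n_extension: 50
n_matched_pairs: 12
n_matched_discovery: 4
n_pon: 20
n_hyperplastic: 8
n_rna: 18
exome_mb: 54.0
# transitions:transversions = 1676:857
titv_ratio: 1.9556592765460910
gc_bias: 0.65
germline_per_tumor: 50
artifacts_per_tumor: 20
germline_pool: 300
artifact_pool: 100
n_context_duplicated: 5

gene_freqs:
  FAT1: 28
  KMT2C: 23
  TET2: 16
  KMT2D: 16
  NOTCH1: 16
  NOTCH2: 14
  CREBBP: 11
  ATM: 11
  TP63: 9
  KMT2A: 8
  SETD2: 7
  DNMT3A: 6
  ASXL3: 6
  CHD1: 5
  MBD4: 5
  JAK3: 5
  TP53: 5
  STK3: 4
  LATS1: 3
  STAT6: 2
  # additional recurrent genes, two mutated tumors each (52 genes total
  # reach the >=2-sample recurrence threshold)
  PLCG1: 2
  VAV1: 2
  CD28: 2
  RHOA: 2
  IDH2: 2
  JAK1: 2
  STAT3: 2
  STAT5B: 2
  TNFAIP3: 2
  CARD11: 2
  PRDM1: 2
  ARID1A: 2
  ARID2: 2
  SMARCA4: 2
  EP300: 2
  EZH2: 2
  SUZ12: 2
  BCOR: 2
  KDM6A: 2
  FOXO1: 2
  B2M: 2
  CIITA: 2
  PTEN: 2
  PIK3CD: 2
  KRAS: 2
  NRAS: 2
  BRAF: 2
  MGA: 2
  POT1: 2
  FYN: 2
  CCR4: 2
  TRRAP: 2
  # singleton genes completing the 92-gene exome discovery set
  ABCA7: 1
  AKT1: 1
  ALK: 1
  APC: 1
  ARID1B: 1
  ATRX: 1
  BCL11B: 1
  BCL2: 1
  BIRC3: 1
  BRCA2: 1
  BTK: 1
  CDKN2A: 1
  CREB1: 1
  CTNNB1: 1
  DDX3X: 1
  DNM2: 1
  EGFR: 1
  ERBB4: 1
  FBXW7: 1
  GATA3: 1
  GNA13: 1
  HRAS: 1
  IDH1: 1
  IKZF1: 1
  IL7R: 1
  IRF4: 1
  ITPKB: 1
  JAK2: 1
  KDM6B: 1
  KIT: 1
  MED12: 1
  MTOR: 1
  MYC: 1
  NF1: 1
  NFKB2: 1
  PIK3CA: 1
  PTPN11: 1
  RUNX1: 1
  SETBP1: 1
  SF3B1: 1

# 45 literature add-on genes (not recorded in the discovery screen),
# completing the 137-gene targeted panel.
literature_genes:
  - TBX21
  - CCND1
  - CD58
  - CDKN1B
  - CHEK2
  - CSNK1A1
  - DDX50
  - DUSP22
  - EOMES
  - FAS
  - GTF2I
  - HLAA
  - HLAB
  - ICOS
  - IKBKB
  - IL2RG
  - IRF8
  - ITK
  - KMT2B
  - LCK
  - MALT1
  - MAP2K1
  - MAP3K14
  - MSH2
  - MSH6
  - NFATC1
  - NFKBIA
  - NOTCH3
  - PDCD1
  - PIK3R1
  - PLCG2
  - PRKCB
  - PTPRC
  - RELA
  - CARMIL2
  - SETD1B
  - SGK1
  - SOCS1
  - STAT5A
  - TERT
  - TNFRSF14
  - TP53BP1
  - UBR5
  - WHSC1
  - ZEB1

per_sample_burden: [6, 18, 33, 47, 60, 74, 88, 101, 115, 128, 135, 142, 150, 158, 166, 174, 181, 188, 195, 200, 204]

# Missense counts and destabilizing (ddG < -0.5 kcal/mol) counts among
# the planted variants of selected tumor-suppressor genes.
stability_plan:
  FAT1: {missense: 20, destabilizing: 12}
  LATS1: {missense: 3, destabilizing: 2}
  STK3: {missense: 4, destabilizing: 3}
  TP53: {missense: 3, destabilizing: 2}
  TP63: {missense: 5, destabilizing: 3}
  ATM: {missense: 9, destabilizing: 5}

survival:
  gene: FAT1
  n_clinical: 61
  median_mutated: 11.0
  median_wildtype: 26.0
  survival_at_36m: 0.24
  followup_range: [1.0, 78.0]
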