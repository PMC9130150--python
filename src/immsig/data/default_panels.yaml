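# Default immune-subset panel configuration.
#
# CD45 is the single transcript PTPRC; the 13 subset panels use illustrative
# marker-gene lists in the style of published cell-type composites (edit to
# match your code set).  The "ais" entry is a PLACEHOLDER 17-gene adaptive
# immune panel for testing: the validated signature's gene identities are
# supplied by the user or derived with `immsig derive`.
cd45:
  method: log_geometric_mean
  genes: [PTPRC]
b_cells:
  method: log_geometric_mean
  genes: [BLK, CD19, MS4A1, TNFRSF17, FCRL2, PNOC, SPIB, TCL1A]
cd8_t_cells:
  method: log_geometric_mean
  genes: [CD8A, CD8B]
cytotoxic_cells:
  method: log_geometric_mean
  genes: [CTSW, GNLY, GZMA, GZMB, GZMH, KLRB1, KLRD1, KLRK1, PRF1, NKG7]
dc:
  method: log_geometric_mean
  genes: [CCL13, CD209, HSD11B1]
exhausted_cd8:
  method: log_geometric_mean
  genes: [CD244, EOMES, LAG3, PTGER4]
macrophages:
  method: log_geometric_mean
  genes: [CD163, CD68, CD84, MS4A4A]
mast_cells:
  method: log_geometric_mean
  genes: [CPA3, HDC, MS4A2, TPSAB1]
neutrophils:
  method: log_geometric_mean
  genes: [CSF3R, S100A12, CEACAM3, FCAR, FCGR3B, FPR1, SIGLEC5]
nk_cd56dim:
  method: log_geometric_mean
  genes: [IL21R, KIR2DL3, KIR3DL1, KIR3DL2]
nk_cells:
  method: log_geometric_mean
  genes: [NCR1, XCL1, XCL2]
t_cells:
  method: log_geometric_mean
  genes: [CD3D, CD3E, CD3G, CD6, SH2D1A, TRAT1]
treg:
  method: log_geometric_mean
  genes: [FOXP3]
tis:
  method: log_geometric_mean
  genes: [CCL5, CD27, CD274, CD276, CMKLR1, CXCL9, CXCR6, HLA-DQA1,
          HLA-DRB1, HLA-E, IDO1, PSMB10, STAT1, TIGIT]
ais:
  method: ais_standardized_mean
  genes: [CD2, CD3D, CD8A, CD27, CD28, CTLA4, CXCL13, GZMK, ICOS, IL2RB,
          IRF1, LCK, LTB, PRF1, STAT4, TBX21, ZAP70]
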