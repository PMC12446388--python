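# Human TRPA1 domain map (1119 aa reference).
#
# Region boundaries below are ILLUSTRATIVE placeholders laid out to be
# internally consistent (16 tandem ankyrin repeats followed by linkers,
# transmembrane helices S1-S6 and the carboxy terminus, with residue 878
# inside S5).  They are NOT curated structural coordinates: edit this file
# with your own intervals before interpreting real-data results.
reference_taxon: human_TRPA1
reference_length: 1119
regions:
  full_length: [[1, 1119]]
  ARD1_9: [[1, 306]]
  ARD10_16_linker: [[307, 720]]
  S1_S6_COOH: [[721, 1119]]
  S5: [[854, 890]]
ard_annotation:
  ARD1: [1, 34]
  ARD2: [35, 68]
  ARD3: [69, 102]
  ARD4: [103, 136]
  ARD5: [137, 170]
  ARD6: [171, 204]
  ARD7: [205, 238]
  ARD8: [239, 272]
  ARD9: [273, 306]
  ARD10: [307, 340]
  ARD11: [341, 374]
  ARD12: [375, 408]
  ARD13: [409, 442]
  ARD14: [443, 476]
  ARD15: [477, 510]
  ARD16: [511, 544]
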