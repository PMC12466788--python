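# Default label -> canonical class tables for segmentation evaluation.
# "ground_truth" covers pathologist-annotation vocabularies; "prediction"
# covers the segmenter's own class names.  Lookups are case-insensitive and
# anything unlisted maps to "unknown".
ground_truth:
  tumor: cancer
  mitotic figures: cancer
  lymphocytes: immune
  plasma cells: immune
  macrophages: immune
  neutrophils: immune
  fibroblast: fibroblast
  fibroblasts: fibroblast
  ductal: epithelial
  apoptotic bodies: dead
prediction:
  neoplastic: cancer
  inflammatory: immune
  connective: fibroblast
  epithelial: epithelial
  dead: dead
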