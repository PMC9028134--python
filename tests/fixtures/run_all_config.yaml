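# Deterministic end-to-end fixture: a reduced synthetic cohort exercising
# every pipeline stage (expression, orthologs, dN/dS, modules, proteome,
# miRNA integration) at a size that runs in well under a minute.
seed: 11
simulate:
  use_defaults: false
  n_nontoxin_orthologs: 150
  toxin_family_plan:
    - [PLA2, 1]
    - [SVMP, 4]
    - [CTL, 3]
    - [SVSP, 2]
    - [BPP, 2]
  toxin_family_percent:
    PLA2: 5.0
    SVMP: 40.0
    CTL: 35.0
    SVSP: 12.0
    BPP: 8.0
  planted_expression_shifts:
    - [PLA2-1, fonsecai, 6.0]
    - [SVMP-1, fonsecai, 3.0]
  dnds_plan:
    - [PLA2-1, 0.05, 2.41]
  te_offsets:
    - [SVMP-2, -2.0, cotiara]
  te_noise_sd: 0.0
  mirna_plan:
    - id: mir-rep
      counts: {cotiara: 800.0, fonsecai: 100.0}
      targets: [SVMP-2]
      site_type: 8mer
    - id: mir-flat
      counts: {cotiara: 300.0, fonsecai: 300.0}
  max_codons: 200
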