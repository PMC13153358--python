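# Template for cross-complex correlation input.
#
# Fill tau_recdes_ms (and its uncertainty) from the electrophysiology
# literature for each desensitized-state complex, and point `structure`
# at a local coordinate file (mmCIF/PDB) from which the LBD-dimer
# two-fold-deviation angle beta is measured, or supply beta_deg directly.
# No numeric values ship with the package: cite your sources.

complexes:
  - label: GluA1/A2
    structure: null          # e.g. path to the desensitized-state model
    chains: [A, D]
    beta_deg: null
    tau_recdes_ms: null
    tau_uncertainty_ms: null
    source: ""               # citation
  - label: GluA1/A2-g8
    structure: null
    chains: [A, D]
    beta_deg: null
    tau_recdes_ms: null
    tau_uncertainty_ms: null
    source: ""
  - label: GluA2-GSG1L
    structure: null
    chains: [A, D]
    beta_deg: null
    tau_recdes_ms: null
    tau_uncertainty_ms: null
    source: ""
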