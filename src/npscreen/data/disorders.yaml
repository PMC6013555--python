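# GO-term gene pools for the three neuropsychiatric disorders, as identified
# by the Psychiatric Genomics Consortium pathway analysis of BIP/SCZ/MDD
# susceptibility alleles.  Histone H3-K4 methylation (GO:0051568) is listed
# under both BIP and SCZ: 14 slots, 13 distinct terms.
disorders:
  BIP:
    - id: "GO:0051568"
      name: Histone H3-K4 methylation
    - id: "GO:0007129"
      name: (Chromosomal) synapsis
    - id: "GO:0090066"
      name: Regulation of anatomical structure size
    - id: "GO:0070192"
      name: Chromosome organization involved in meiosis
  SCZ:
    - id: "GO:0014069"
      name: Postsynaptic density
    - id: "GO:0045211"
      name: Postsynaptic membrane
    - id: "GO:0043197"
      name: Dendritic spine
    - id: "GO:0051568"
      name: Histone H3-K4 methylation
    - id: "GO:0033267"
      name: Axon part
  MDD:
    - id: "GO:0008601"
      name: Protein phosphatase type 2A regulator activity
    - id: "GO:0034330"
      name: Cell junction organization
    - id: "GO:0043297"
      name: Apical junction assembly
    - id: "GO:0045216"
      name: Cell-cell junction organization
    - id: "GO:0031056"
      name: Regulation of histone modification
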