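# Granular population annotation.  Alternatively activated TAMs carry the
# CD16-high CX3CR1-high CD163+ CD11b+ signature; classically activated TAMs
# the CD16-low CX3CR1-low CD56+ signature.  Proliferative variants add
# Ki-67-high and are listed first so they win ties against their base rule.
# Clusters matching no rule are labelled "other".
rules:
  - population: prolif_alt_act_tam
    hierarchy: proliferative
    expectations: {Ki-67: high, CD16: high, CX3CR1: high, CD163: pos, CD11b: pos}
  - population: prolif_trans_monocyte
    hierarchy: proliferative
    expectations: {Ki-67: high, CD14: high, CD11c: high, CD68: pos}
  - population: prolif_pdl1_schwann
    hierarchy: proliferative
    expectations: {Ki-67: high, PD-L1: high, S100B: high, PanCytokeratin: pos}
  - population: alt_act_tam
    hierarchy: myeloid
    expectations: {CD16: high, CX3CR1: high, CD163: pos, CD11b: pos}
  # classically activated TAMs are CD16-low CX3CR1-low relative to the
  # alternatively activated signature; the rule keys on their positive
  # markers (CD56+, CD74, HLA-DR) because z-based "low" gates sit at the
  # decision boundary when a clustering is finely split.
  - population: class_act_tam
    hierarchy: myeloid
    expectations: {CD68: pos, CD56: pos, CD74: high}
  - population: trans_monocyte
    hierarchy: myeloid
    expectations: {CD14: high, CD11c: high, CD68: pos}
  - population: neutrophil
    hierarchy: myeloid
    expectations: {CD66b: high, CD11b: pos}
  - population: cd8_tem
    hierarchy: lymphoid
    expectations: {CD8a: high, CD3: pos, CD45RO: high}
  - population: cd4_t
    hierarchy: lymphoid
    expectations: {CD4: high, CD3: pos, CD45RA: pos}
  - population: pdl1_schwann
    hierarchy: neoplastic
    expectations: {PD-L1: high, S100B: high, PanCytokeratin: pos}
  - population: perk_schwann
    hierarchy: neoplastic
    expectations: {pERK1/2: high, S100B: high, PanCytokeratin: pos}
  - population: schwann
    hierarchy: neoplastic
    expectations: {S100B: high, PanCytokeratin: pos, Vimentin: pos}
  - population: vasculature
    hierarchy: vascular
    expectations: {SMA: high, CD31: high}
  - population: erythrocyte
    hierarchy: vascular
    expectations: {CD235ab: high}
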