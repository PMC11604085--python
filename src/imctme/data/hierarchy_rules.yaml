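# Coarse hierarchical cell-type annotation applied to Leiden cluster mean
# profiles (z-scored across clusters).  Rule order breaks ties: Ki-67-high
# clusters are typed proliferative before any lineage rule can claim them.
rules:
  - population: proliferative_cells
    hierarchy: proliferative
    expectations: {Ki-67: high}
  - population: t_cells
    hierarchy: lymphoid
    expectations: {CD3: high}
  - population: vasculature
    hierarchy: vascular
    expectations: {SMA: high}
  - population: erythrocytes
    hierarchy: vascular
    expectations: {CD235ab: high}
  - population: schwann_like
    hierarchy: neoplastic
    expectations: {S100B: high}
  - population: neutrophils
    hierarchy: myeloid
    expectations: {CD66b: high}
  - population: myeloid_cells
    hierarchy: myeloid
    expectations: {CD68: pos}
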