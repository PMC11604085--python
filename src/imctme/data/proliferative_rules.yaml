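# Annotation of Leiden sub-clusters within the proliferative (Ki-67+) cells:
# proliferative alternatively activated TAMs, proliferative transitioning
# monocytes and proliferative PD-L1+ Schwann cells.
rules:
  - population: prolif_alt_act_tam
    hierarchy: proliferative
    expectations: {CD16: high, CX3CR1: high}
  - population: prolif_trans_monocyte
    hierarchy: proliferative
    expectations: {CD14: high, CD11c: high}
  - population: prolif_pdl1_schwann
    hierarchy: proliferative
    expectations: {PD-L1: high, S100B: high}
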