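name,compartment,metal_tag
PanCytokeratin,neoplastic,La139
S100B,neoplastic,Pr141
CD56,neoplastic,Nd150
MHC1,immune,Nd142
CD14,immune,Nd144
CD16,immune,Nd146
CD163,immune,Sm147
CD66b,immune,Nd148
CD11b,immune,Sm149
GranzymeB,immune,Eu151
CD45,immune,Sm152
CD11c,immune,Sm154
CD4,immune,Gd156
CD45RA,immune,Gd158
Iba1,immune,Dy161
CD8a,immune,Dy162
CD74,immune,Er166
CD3,immune,Er170
CX3CR1,immune,Yb172
CD45RO,immune,Yb173
HLA-DR,immune,Yb174
CD206,immune,Lu175
CD68,immune,Pt198
SMA,vascular,Y89
CD235ab,vascular,In115
vWF,vascular,Tb159
CD31,vascular,Tm169
Ki-67,proliferative,Er168
Vimentin,other,Nd143
HIF-1a,other,Gd155
VEGF,other,Dy163
Fibrinogen,other,Ho165
PD-L1,other,Er167
pERK1/2,other,Yb171
MCT4,other,Yb176
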