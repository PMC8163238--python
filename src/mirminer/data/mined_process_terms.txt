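# candidate process terms harvested from list patterns in text
endothelial permeability
invasion
tumor growth
colony formation
cell death
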