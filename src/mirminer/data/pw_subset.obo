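format-version: 1.2
ontology: pw (pathway subset for desk-scale matching)

[Term]
id: PW:0000008
name: Wnt signaling pathway

[Term]
id: PW:0000718
name: p53 signaling pathway

[Term]
id: PW:0000605
name: PI3K-Akt signaling pathway
synonym: "PI3K/Akt signaling pathway" EXACT []

[Term]
id: PW:0000007
name: MAPK signaling pathway

[Term]
id: PW:0000201
name: NF-kappaB signaling pathway
synonym: "NF-κB signaling pathway" EXACT []
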