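format-version: 1.2
ontology: bto (biofluid subset for desk-scale matching)

[Term]
id: BTO:0001239
name: blood serum
synonym: "serum" RELATED []

[Term]
id: BTO:0000131
name: blood plasma
synonym: "plasma" RELATED []

[Term]
id: BTO:0001229
name: seminal plasma

[Term]
id: BTO:0001419
name: urine

[Term]
id: BTO:0001202
name: saliva

[Term]
id: BTO:0000089
name: blood

[Term]
id: BTO:0000237
name: cerebrospinal fluid
synonym: "CSF" EXACT []

[Term]
id: BTO:0001374
name: tear
synonym: "tears" RELATED []

[Term]
id: BTO:0000849
name: milk
synonym: "breast milk" RELATED []

[Term]
id: BTO:0001285
name: sputum

[Term]
id: BTO:0000061
name: amniotic fluid

[Term]
id: BTO:0001228
name: semen
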