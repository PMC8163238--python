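format-version: 1.2
ontology: go (cellular-process subset for desk-scale matching)

[Term]
id: GO:0006915
name: apoptotic process
namespace: biological_process
synonym: "apoptosis" EXACT []
synonym: "apoptotic cell death" EXACT []

[Term]
id: GO:0008219
name: cell death
namespace: biological_process

[Term]
id: GO:0008283
name: cell population proliferation
namespace: biological_process
synonym: "cell proliferation" EXACT []
synonym: "proliferation" RELATED []

[Term]
id: GO:0016477
name: cell migration
namespace: biological_process
synonym: "migration" RELATED []

[Term]
id: GO:0001525
name: angiogenesis
namespace: biological_process

[Term]
id: GO:0007049
name: cell cycle
namespace: biological_process

[Term]
id: GO:0006914
name: autophagy
namespace: biological_process

[Term]
id: GO:0001837
name: epithelial to mesenchymal transition
namespace: biological_process
synonym: "EMT" EXACT []
synonym: "epithelial-mesenchymal transition" EXACT []

[Term]
id: GO:0006954
name: inflammatory response
namespace: biological_process

[Term]
id: GO:0006955
name: immune response
namespace: biological_process

[Term]
id: GO:0007155
name: cell adhesion
namespace: biological_process

[Term]
id: GO:0030154
name: cell differentiation
namespace: biological_process
synonym: "differentiation" RELATED []
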