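format-version: 1.2
ontology: doid (cancer subset for desk-scale matching)

[Term]
id: DOID:684
name: hepatocellular carcinoma
synonym: "HCC" EXACT []
synonym: "liver cell carcinoma" EXACT []
xref: MESH:D006528

[Term]
id: DOID:3068
name: glioblastoma
synonym: "GBM" EXACT []
synonym: "glioblastoma multiforme" EXACT []
xref: MESH:D005909

[Term]
id: DOID:9256
name: colorectal cancer
synonym: "colorectal carcinoma" EXACT []
xref: MESH:D015179

[Term]
id: DOID:10534
name: stomach cancer
synonym: "gastric cancer" EXACT []
synonym: "stomach neoplasm" EXACT []
xref: MESH:D013274

[Term]
id: DOID:1612
name: breast cancer
synonym: "breast carcinoma" EXACT []
xref: MESH:D001943

[Term]
id: DOID:10283
name: prostate cancer
synonym: "prostate carcinoma" EXACT []
xref: MESH:D011471

[Term]
id: DOID:1324
name: lung cancer
synonym: "lung neoplasm" EXACT []
xref: MESH:D008175

[Term]
id: DOID:1909
name: melanoma
xref: MESH:D008545

[Term]
id: DOID:2394
name: ovarian cancer
synonym: "ovarian carcinoma" EXACT []
xref: MESH:D010051

[Term]
id: DOID:1793
name: pancreatic cancer
synonym: "pancreatic carcinoma" EXACT []
xref: MESH:D010190

[Term]
id: DOID:5520
name: head and neck squamous cell carcinoma
synonym: "HNSCC" EXACT []
xref: MESH:D000077195

[Term]
id: DOID:9119
name: acute myeloid leukemia
synonym: "AML" EXACT []
xref: MESH:D015470
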