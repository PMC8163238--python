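# mirminer

Rule-based mining of microRNA information from biomedical abstracts:
entity recognition and normalization, relation extraction, a local
document store with query modes and aspect views, and a seeded synthetic
corpus for end-to-end evaluation — all runnable offline at desk scale.

## What it does

- **Corpus I/O** (`mirminer.corpus_io`) — reads Medline XML
  (`PubmedArticleSet`) or 3-column TSV (`pmid`, `title`, `abstract`),
  splits sentences with stable character offsets, and round-trips the
  document-centric schema (one title, many sentences/entities/relations)
  as JSON lines.
- **miRNA NER** (`mirminer.ner_mirna`) — regex detection over the common
  surface dialects (`miR-21`, `microRNA 21`, `hsa-miR-17-5p`,
  `let-7b-5p`, `miR-19a/b`, OCR-split `miR-30 c`, clusters) and
  normalization to family identifiers (`mir-17`, `let-7b`); paralog
  letters are preserved, arm and genomic-copy suffixes stripped.
- **Lexicons** (`mirminer.lexicons`) — OBO-backed dictionaries for
  processes (GO BP + Pathway Ontology + list-pattern mined terms),
  diseases (DOID, plus a MESH→DOID xref mapping), biofluids (BTO) and
  transporter forms; genes from a symbol→NCBI-Gene-ID table.  Matching is
  case-insensitive, token-boundary-respecting, longest-match-wins.
- **Relation extraction** — miRNA–gene (target / regulation /
  gene-regulates-miRNA with polarity; `mirminer.rel_gene`),
  miRNA–process (regulation / involvement / association;
  `mirminer.rel_roles`), miRNA–disease roles (BIOMARKER,
  THERAPEUTIC_TARGET, OUTCOME, TREATMENT, OTHER with disease-argument
  provenance), differential-expression frames (direction, sample and
  comparison descriptors), and extracellular locations (same-sentence
  proximity pairs plus patient-context sentence linking;
  `mirminer.rel_extracellular`).  All extractors run on a shared
  token-window parse layer (`mirminer.parse_layer`) that degrades
  gracefully when no dependency parser is configured.
- **Store and queries** (`mirminer.corpus_store`) — inverted indices with
  miRNA-centric, context-centric (AND/OR boolean keyword) and
  disease-centric (DOID synonym expansion) search, aspect views with
  substring filtering and stable sorting, CSV/JSON export, and summary
  counts.
- **Synthetic corpus** (`mirminer.synth_corpus`) — a seeded generator
  producing templated abstracts with gold relations for every family,
  plus distractor sentences, and a precision/recall/F1 scorer.

## CLI

```bash
mirminer ingest abstracts.tsv corpus.jsonl          # or Medline XML
mirminer extract corpus.jsonl extracted.jsonl       # annotate + extract
mirminer query extracted.jsonl --mirna mir-21
mirminer query extracted.jsonl --context "glioma AND PTEN"
mirminer query extracted.jsonl --doid DOID:3068
mirminer view extracted.jsonl --aspect gene_regulation --filter PTEN
mirminer export extracted.jsonl --format csv -o relations.csv
mirminer stats extracted.jsonl
mirminer synth --seed 42 --n-documents 200 -o synthetic.jsonl --gold gold.csv
```

## Library example

```python
from mirminer import default_resources, annotate, extract
from mirminer.corpus_io import document_from_text

res = default_resources()
doc = document_from_text("1", "", "miR-21 directly targets PTEN in glioma cells.")
extract(annotate(doc, res))
for rel in doc.relations:
    print(rel.family, rel.tag, rel.partner_canonical)
```

Bundled desk-scale lexicons live in `src/mirminer/data/` (plain text and
OBO subsets); swap in full ontology files through the builder functions
in `mirminer.lexicons` for larger runs.
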