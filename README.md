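# belkit

Compile, summarize, query and analyze causal knowledge networks encoded
in the Biological Expression Language (BEL).

BEL expresses biological knowledge as subject–predicate–object triplets
— `p(HGNC:RB1) increases act(p(HGNC:E2F4))` — qualified by citations,
evidence sentences and contextual annotations (cell line, tissue,
curated subgraph membership). Corpora of such statements compile into
directed multigraphs whose nodes are typed biological entities (genes,
RNAs, proteins, abundances, complexes, biological processes,
pathologies) and whose edges carry a causal sign: +1 for
`increases`/`directlyIncreases`, −1 for `decreases`/`directlyDecreases`,
0 for correlative relations, which are symmetric and traversable both
ways.

belkit is aimed at curators and systems biologists who need to validate
BEL at scale, audit curation quality, extract relevant subnetworks
reproducibly, and overlay differential-expression data to rank
dysregulated biological processes.

## What it does

- **Parse & validate** (`belkit.bel_io`) — a total parser: every input
  line either becomes metadata, a definition or a statement, or is
  reported as a syntactic/semantic issue with its verbatim line, 1-based
  line number and column. Recurring issues group by (code, offending
  token) for triage; validated documents serialize back to canonical
  BEL.
- **Compile & merge** (`belkit.graph_model`) — one edge per statement,
  nodes deduplicated by identity `(function, namespace, name,
  variants)`; networks merge by node-set union and edge-multiset
  concatenation with exact-duplicate removal. Node-link JSON and
  GraphML export.
- **Summarize** (`belkit.summary`) — counts by function/relation/
  namespace/annotation, density, average degree, betweenness, and the
  Szymkiewicz–Simpson node overlap |A∩B| / min(|A|,|B|); plus
  "biogrammar" motifs: contradictory pairs (A increases B *and*
  A decreases B) and inconsistent negative-correlation triangles.
- **Query** (`belkit.query`, `belkit.transforms`) — replayable
  transactions: select networks, seed by neighborhood, upstream/
  downstream causal layers, shortest/all paths, provenance, authors or
  annotations, then apply a named transformation pipeline
  (causal extraction, pathology removal, family-member enrichment,
  central-dogma origin enrichment, variant/gene collapsing, ...).
  Queries serialize to JSON and hash to stable SHA-256 identifiers;
  `undo` unwinds them stepwise.
- **Analyze** (`belkit.diffusion`) — map omics scores (signed log2 fold
  changes) onto gene nodes and run sign-aware heat diffusion: each
  synchronous step, non-sink nodes forward their heat split equally over
  net-signed causal out-edges, flipping sign across decreasing edges;
  sinks (e.g. biological processes) absorb. Per-stage process heats are
  clustered with K-means (K = 5 by default) to find shared progression
  patterns.
- **Fixtures** (`belkit.fixtures`, `belkit.scenario`) — seeded
  generators of BEL corpora with ground-truth ledgers (planted
  contradictions and triangles), family resources, and staged omics
  tables with planted trajectory archetypes, plus an end-to-end
  progression-study driver.

## Worked example

```python
from belkit import (parse_bel_document, compile, network_statistics,
                    find_contradictory_pairs)

text = '''SET DOCUMENT Name = "demo"
DEFINE NAMESPACE HGNC AS LIST {"RB1", "E2F4"}
SET Citation = {"PubMed", "Li 1997", "9001"}
SET Evidence = "RB1 stimulates E2F4 transcriptional activity."
p(HGNC:RB1) increases act(p(HGNC:E2F4))
SET Citation = {"PubMed", "Other 2000", "9002"}
SET Evidence = "RB1 represses E2F4 transcriptional activity."
p(HGNC:RB1) decreases act(p(HGNC:E2F4))
'''
doc = parse_bel_document(text)
net = compile(doc)
stats = network_statistics(net)
print(f"{len(doc.statements)} statements -> {len(net)} nodes, "
      f"{net.number_of_edges()} edges")
print(f"density={stats.density}, average_degree={stats.average_degree}")
for u, v, support in find_contradictory_pairs(net):
    print(f"contradiction: {u.as_bel()} -> {v.as_bel()} "
          f"({', '.join(e.relation for e in support)})")
```

prints

```
2 statements -> 2 nodes, 2 edges
density=0.5, average_degree=2.0
contradiction: p(HGNC:RB1) -> p(HGNC:E2F4) (decreases, increases)
```

The two statements compile to two parallel edges on one ordered node
pair (the activity modifier is an edge qualifier, not a separate node),
so the opposing signs surface as a contradictory pair — the kind of
curation conflict the biogrammar summary is built to catch. Density is
0.5 because one of the two ordered pairs is connected; average degree is
2·|edges|/n = 2.

The same flows are available from the shell:

```bash
belkit fixtures corpus --seed 7 --out corpus.bel --ledger ledger.json
belkit compile corpus.bel --json-out net.json --report issues.tsv
belkit summarize net.json --motifs
belkit fixtures omics --seed 7 --genes 30 --out-dir omics/
belkit diffuse net.json --omics omics/early.tsv --omics omics/moderate.tsv \
    --omics omics/severe.tsv --k 5 --seed 42 --out heats.tsv
```

`belkit compile` prints, for the seed-7 corpus:
`60 statements, 30 nodes, 60 edges, 0 errors, 0 warnings`.

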