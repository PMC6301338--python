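# Methods

This note documents the models, conventions and numerical choices
behind belkit, the assumptions they rest on, and what the synthetic
test fixtures do and do not demonstrate about real curated corpora.

## The knowledge-network model

A statement `subject relation object` compiles to one directed edge.
Node identity is the canonical tuple *(function, namespace, name,
variants)*; variant descriptors (`pmod(...)`, `var(...)`) are ordered
and part of identity, annotation maps are not. Activity modifiers
(`act(...)`, `kin`, `tscript`, `cat`) do **not** create nodes: they are
recorded as edge-side qualifiers (`subject_activity`,
`object_activity`) on the underlying entity node. This keeps all
statements about a node pair on that pair, which is what makes
opposing activity-qualified statements detectable as a contradiction.

Correlative relations (`association`, `positiveCorrelation`,
`negativeCorrelation`) are stored once with a `symmetric` flag rather
than as two directed edges; every traversal (neighborhoods, paths,
density, betweenness) expands them to both directions on the fly. The
single-storage choice avoids double-counting symmetric knowledge in
edge statistics and motif support.

Merging unions node sets and concatenates edge multisets, deduplicating
only *exact* duplicates (same endpoints, relation, citation, evidence,
annotations, qualifiers). Near-duplicates — the same assertion curated
from different articles — are deliberately kept as parallel edges,
matching multigraph semantics of curated corpora. A single-network
merge returns a metadata-preserving copy so the identity query
reproduces its input byte-for-byte in canonical node-link JSON.

## Parser conventions

The parser supports a bounded BEL 1.0-style dialect: the nine entity
functions with short and long names, one level of modifier nesting
(`act(p(...))` is accepted, `act(act(...))` is not), `pmod`/`var`
variants on sequence entities, long-form relations plus `->`, `=>`,
`-|`, `=|`, `--`, and `SET`/`UNSET`/`DEFINE` control lines. Names with
spaces must be quoted; quotes are stripped in the model. Line and
column numbers are 1-based, matching editor conventions for curator
feedback, and every issue carries the verbatim input line.

Issue severity decides statement fate: errors (malformed syntax, names
without a namespace, undefined namespaces, names absent from a resolved
namespace, missing citations) reject the statement; warnings
(unresolved namespace definitions, undefined annotation keys, values
outside a defined annotation) keep it. Exactly one error is reported
per rejected relational line — validation stops at the first fatal
problem — so the count identity *relational lines = statements +
rejected lines* holds exactly. Namespace URLs are resolved only from a
caller-supplied resource map or local file paths; anything else is
"unresolved" and its names pass with a warning, keeping the toolkit
fully usable offline.

Serialization is canonical (sorted metadata, namespace terms,
annotation keys and values; one `SET`-block per statement followed by
`UNSET ALL`), which makes parse ∘ serialize ∘ parse a fixed point on
the statement multiset.

## Summary statistics and biogrammar

Density treats the multigraph as a simple directed graph: the fraction
of *connected ordered node pairs* out of n(n−1), with a symmetric edge
connecting both orders. This keeps density in [0, 1] regardless of
parallel edges. Average degree is 2·|edges|/n over the edge multiset.
Betweenness is computed on the symmetric-expanded simple directed graph
(networkx, unnormalized).

The contradictory-pair finder pools direct and indirect causal forms by
sign and ignores activity qualifiers, reporting every ordered pair
supported by at least one +1 and one −1 edge. Direction matters:
`A increases B` with `B decreases A` is not a contradiction. The
triangle finder reports each unordered all-negative-correlation triple
once. Only these two motifs ship; `MotifRegistry` accepts user
predicates for extension. Mixed-sign correlation cycles (e.g. one
negative edge in a triangle) are *not* flagged — only the all-negative
triple is claimed to be inconsistent.

## Query semantics

Seeding unions across multiple seed specifications (no intersection
semantics are offered). Distance in `neighbors` ignores edge direction
— the visual-neighborhood use case — while `shortest_paths` and
`all_paths` respect direction, with symmetric edges usable both ways;
this split is an explicit design choice and is documented on each
function. `upstream`/`downstream` apply exactly two expansion layers
over causal edges and then induce all causal edges among the result.
`all_paths` bounds simple paths at six edges by default. Filter seeds
(provenance, authors, annotations) return exactly the matching edges
plus endpoints; annotation filters OR within a key and AND across keys;
author matching is exact, case-insensitive full-string — no fuzzy
matching, for determinism.

A query (selection + seeds + pipeline) serializes to versioned JSON;
its identifier is the SHA-256 of the canonical serialization (sorted
keys, sorted value lists), so equal queries hash equally under any
construction order and no database is needed. `undo` removes the last
pipeline entry, then the last seed.

Transformations are pure functions in a name registry; network-valued
arguments (e.g. the family resource for `enrich_members`) may be given
as catalog ids in query JSON. `enrich_members` adds only direct
members of subjects already present (one hop, not transitive).
Collapsing (`collapse_variants`, `collapse_to_genes`) quotients the
graph, re-targets edges, removes central-dogma edges that become
internal to a collapsed group, and deduplicates exact duplicates; both
collapses and the origin enrichment are idempotent.

## Heat diffusion

The diffusion operates on the causal subgraph. Parallel causal edges
on an ordered pair collapse to the sign of their sum; pairs summing to
zero are dropped and reported as contradictory. The update is
synchronous: each step, every node with surviving out-edges forwards
its entire working heat, split equally (1/outdegree) over its
out-neighbors and multiplied by each edge's sign. Nodes without
outgoing causal edges are sinks and absorb; their initial heat counts
as absorbed. Iteration stops when total circulating |heat| drops below
`tolerance` (default 1e−8) or after `max_iterations` (default 100),
which bounds behavior on cycles, where heat can circulate indefinitely.

These semantics make the map linear in the initial heats, conservative
on all-positive DAGs (Σ absorbed = Σ h0), and exactly equal on DAGs to
the path-sum Σ_paths h0(source)·Π(sign/outdegree) — the independent
oracle the tests enumerate exhaustively on graphs of ≤ 15 nodes.

Omics scores are taken as pre-processed signed log2 fold changes;
significance filtering is the caller's responsibility. Mapping matches
variant-free gene nodes on (namespace, name) with case-insensitive
namespace keywords and case-sensitive names, so networks should be
collapsed to genes first (not enforced).

Trajectory clustering uses scikit-learn K-means (10 restarts, best
inertia) on per-process heat vectors across experiments, with the
random state derived from the caller's seed. Rows are sorted by
canonical node identity before fitting and labels renumbered by first
occurrence, making the output deterministic and invariant to input
order. Heats are clustered raw by default — on synthetic data the
scales are comparable across stages — with a `standardize` opt-in that
z-scores each experiment column. If fewer distinct vectors than K
exist, fewer clusters are returned without error.

## Synthetic fixtures and what passing tests show

The corpus generator emits valid BEL with configurable relation
mixtures, citations with author lists, and annotation assignments, and
plants contradictory pairs and negative triangles at per-slot
probabilities. It *refuses* accidental motifs (a random causal edge
never opposes an existing sign; a random negative correlation never
closes a triangle), so the ledger it returns is exact ground truth —
the independent comparison target for the motif finders.

The staged omics generator draws per-gene trajectories from five
archetype profiles — rising (0, 1, 2), falling (0, −1, −2), late fall
(0, 0, −1.5), flat, elevated (1.5 constant) — in log2-fold-change units
scaled by an effect size (default 2.0) plus Gaussian noise (default
sd 0.25). Three ordered stages (early/moderate/severe) model a
progression study. The end-to-end scenario plants one archetype per
biological process by routing three dedicated genes into each process,
and includes family, mouse/rat, pathology, correlative, variant and
unannotated distractor statements so every pipeline stage has real
work; the scenario sizes (5 archetypes × 4 processes × 3 genes) keep a
20-seed replication fast while leaving clusters statistically
unambiguous (between-archetype separation ≥ ~7 heat units against
per-coordinate noise ≈ 0.43).

Passing these tests shows the machinery is correct under its own
model: clean separable effects, exact name matching, complete mapping,
noise far below effect size. Real corpora bring parser dialect
variation, namespace drift, heavy-tailed and correlated expression
noise, incomplete gene coverage and contradictions that are not
planted; recovery rates on such data will be lower, and no agreement
with any external diffusion implementation is claimed — only with the
stated update rule.

## Known limitations

- BEL 2.x surface syntax, nested complex/composite member terms, and
  network fetching of namespace definitions are out of scope.
- Diffusion on cyclic causal graphs terminates by iteration cap, not
  convergence; residual heat is reported rather than resolved.
- Contradiction detection does not weight by biological context,
  reference type or publication date; all statements count equally.
- The generators model none of: heteroskedastic noise, batch effects,
  missing measurements, or realistic degree distributions.
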