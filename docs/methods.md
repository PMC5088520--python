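# Methods

## From pathway charts to protein networks

A KGML document describes one pathway as *entries* and *relations*. An
entry of type `gene` may carry several KEGG gene identifiers in one
space-separated `name` attribute — a multi-protein box; the placeholder
`undefined` denotes no identifiers. Group entries bundle other entries and
are resolved before any network is built: a relation whose endpoint is a
group fans out to one relation per member (a relation between groups of
sizes m and n becomes m·n relations), recursively if groups nest, and the
group entries are then dropped. `reaction` elements and all graphics are
ignored: only relation links carry the connectivity this package models.
Entries of type `compound` and `map` are parsed and validated but excluded
from protein networks.

Identifier space is UniProtKB. KEGG or Ensembl gene ids translate through
two-column mapping tables; the mapping is treated as authoritative and
many-to-many — a gene mapping to k accessions contributes k protein nodes.
Isoform accessions (`P46531-2`) collapse to their canonical stem, an
interpretation this package makes explicitly: its networks are
protein-level, not isoform-level. Unmapped ids are reported, never
silently dropped, and entries with no mapped accession contribute no
relations.

The relational store holds two tables. A *relation row* is the unordered
accession pair (stored lexicographically; self-pairs dropped) plus a
collapsed category, with the raw subtype names and the pathway ids of every
occurrence unioned on. The collapse maps `activation` → activation,
`inhibition` and `repression` → inhibition, `expression` → expression, and
everything else — phosphorylation, binding/association, indirect effect,
or no subtype at all — to *other*; when several recognized subtypes
co-occur on one relation the precedence activation > inhibition >
expression decides. A relation between entries with m and n mapped
accessions expands to m·n candidate pairs. Relation types that do not join
two protein entries directly (`PCrel` through compounds, `maplink`)
contribute no rows. The store deduplicates on (pair, category): building
from a corpus and from the same corpus duplicated yields identical stores,
and the canonical SQL dump (sorted `INSERT` statements over an embedded
SQLite schema) is byte-deterministic.

Networks are undirected simple graphs. The *local* network of a pathway is
exactly its proteins (isolated ones included) and relations. The *global*
network adds every store relation incident to a local protein together
with the external partner nodes — one hop only, a deliberate cut: closing
transitively would reconstruct the whole corpus interactome rather than a
pathway-centred view. Parallel categories on one pair merge into a single
edge carrying a category set; the single `display_category` used for SIF
output and edge colouring follows the same fixed precedence (activation >
inhibition > expression > other), a convention documented rather than
derived. Physical-interaction pairs decorate matching edges
(`ppi_supported`) and by default never add edges; a union mode adds pairs
between existing nodes as category-*other* edges with empty pathway
provenance.

## Expression states

Per context, every node gets exactly one state:

- **ON** — score strictly greater than the threshold,
- **OFF** — score less than or equal to the threshold,
- **NA** — the accession (and every gene id mapping to it) is absent from
  the expression table.

The threshold default is 0.4 on barcode-style fractional scores. The
strict/non-strict split matters at the boundary (0.40 → OFF, 0.41 → ON)
and is exercised by boundary-value fixtures. Filtering keeps ON *and* NA
nodes — an unmeasurable gene is not evidence of absence — and removes OFF
nodes with incident edges; the counts ON + OFF-removed + NA always equal
the node count, and the ON set shrinks monotonically as the threshold
rises.

The barcode-style scorer is a deliberately simple presence/absence caller:
given each gene's unexpressed reference distribution (mu, sigma > 0), a
gene is expressed in a sample iff (x − mu)/sigma exceeds the z-cutoff
(default 5.0, configurable — there is no universally correct value), and
the context score is the fraction of that context's samples called
expressed, hence always in [0, 1]. Full microarray preprocessing
(normalization, probe summarization) is out of scope; inputs are
gene-level. Raw FPKM or EST resources are judged against an absolute,
user-supplied cutoff on the tabulated per-context value; no default is
claimed because none transfers across platforms.

When a resource is keyed by gene id rather than accession, an accession
scoring several rows takes the maximum by default ("any evidence of
expression"); mean aggregation is available.

## Topology

Metrics on the undirected simple graph: degree; betweenness by exact
shortest-path counting, unnormalized by default, with equal split across
equal-length paths; the local clustering coefficient (degree < 2 scores
0); and eigenvector centrality. Eigenvector centrality is the leading
eigenvector of each connected component's adjacency matrix, computed by a
dense symmetric eigendecomposition — robust for components of any size,
including pairs — taken with non-negative sign and scaled to a maximum of
1 within the component; isolated nodes score 0. The max-1 normalization
is this package's chosen convention. Hub selection is deterministic:
degree descending, accession ascending on ties, by top-k (clamped) or by
a degree quantile.

The test suite checks betweenness and clustering against an independent
brute-force oracle (explicit enumeration of all simple paths / direct
triangle counting) on hundreds of random graphs of up to 8 nodes, plus
closed forms on triangle, path and star graphs.

## The synthetic-data generator

The fixtures module emulates the *structure* of real pathway corpora, not
their content: pathways of 8–14 genes by default, a quarter of entries
multi-protein, occasional group/compound/map entries, relation subtypes
drawn from a distribution dominated by activation/inhibition/expression,
and a 25 % cross-pathway protein-sharing rate that makes global networks
strictly larger than local ones. Expression contexts plant ON/OFF states
with scores drawn clear of the 0.4 threshold (ON in [0.45, 1], OFF in
[0, 0.35]); a boundary flag plants exact-0.4 scores, which must come out
OFF. NA is modelled as a platform property — a protein absent from the
expression table in every context. All randomness flows from one integer
seed through a single generator; a seed reproduces the corpus
byte-for-byte. Every corpus ships a ground-truth manifest (entry, relation
and store-row counts; per-context states; filtered node/edge counts)
derived from the generative choices themselves, which the pipeline must
reproduce exactly.

The packaged case-study corpus is a deterministic 48-protein pathway (a
ring scaffold plus seeded chords, 90 edges) with three contexts whose ON
sets are nested — 32 ON in the B-cell-like context, 24 and 22 in the two
T-cell-like contexts, with the same 2 NA proteins everywhere, five
ligand-like proteins OFF in every context, and one differential protein
scoring 1.00 / 0.41 / 0.17. The nesting guarantees the filtered B-like
network strictly contains each T-like network in nodes and edges, the
qualitative shape of a B-versus-T lymphocyte comparison. What these
fixtures do *not* emulate: real pathway size distributions, realistic
microarray intensity structure beyond the two-component model, correlated
expression between interacting proteins, and release-dependent database
content — so passing tests demonstrate the machinery's correctness, not
agreement with any particular database snapshot.

## Numerical and design choices

- Canonical order everywhere (lexicographic pairs, sorted exports, sorted
  file iteration) makes builds and dumps byte-deterministic.
- KGML is read as UTF-8; XML namespaces are stripped before matching;
  external DTDs are never fetched.
- GraphML export encodes sets as sorted `;`-joined strings and a missing
  score as −1; import reverses both, making the round trip lossless.
- Problem sizes in tests and the acceptance script (corpora of 3–5
  pathways, 100–200 random graphs of ≤ 8–20 nodes) are chosen so the whole
  suite completes in seconds while still covering every rule; all scale
  linearly if enlarged.

## Known limitations

- One organism per store; cross-organism corpora are not merged.
- Directionality of relations is deliberately discarded; signed/directed
  analyses need a different edge model.
- The global expansion is one-hop; no shortest-path or diffusion-based
  neighbourhood definitions.
- No community detection: "clusters" beyond hub identification are out of
  scope.
- Live retrieval from KEGG, UniProt or expression repositories is not
  implemented; all inputs are files.
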