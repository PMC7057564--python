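# Methods

## The model

A concept hierarchy is a rooted directed acyclic graph of CUIs linked by
is_a edges, stored as one child–parent row per link in a CSV file. Two
modes exist because the field uses both: `mono` (every non-root concept
has exactly one parent — the convention for small curated examination
ontologies, where each row of the file *is* the hierarchy) and `dag`
(poly-hierarchies such as SNOMED CT, where a concept may have several
parents and the same CUI appears once per parent row).

Semantic distance between concepts *a* and *b* is the normalized
Wu–Palmer distance

    Dist(a, b) = 1 − 2·depth(LCS) / (depth(a) + depth(b))

with depth counting levels from the root. Conventions, in order of how
much they matter:

- **Root depth is 0.** This is what makes a pair of concepts whose only
  common subsumer is the root come out at exactly 1.0, the "maximally
  distant" boundary the normalization promises.
- **`Dist(root, root) := 0.`** The raw ratio is 0/0 there; identity must
  hold universally, so the degenerate case is pinned to 0.
- **DAG depth is the shortest root-path length.** Deterministic and the
  common choice for Wu–Palmer on poly-hierarchies. On a mono-hierarchy
  there is only one root path, so no convention is needed.
- **LCS selection and DAG evaluation.** The LCS is the
  subsumption-*minimal* common ancestor: candidates with another common
  ancestor below them are discarded, then the deepest survivor wins, with
  ties broken by lexicographically smallest CUI. The distance is then
  evaluated with the depths of *a* and *b* measured *through* the LCS
  (depth(LCS) plus the shortest descent from the LCS to each concept) —
  Wu and Palmer's original path formulation. On a tree this is
  algebraically identical to plugging plain node depths into the equation
  above. On a DAG it is not optional: with shortest-path depths a concept
  can have an ancestor deeper than itself (a short edge to the root plus
  a long chain from elsewhere), and the naive max-depth-common-ancestor
  reading then yields distances outside [0, 1] and a nonzero
  self-distance. Property testing on random DAGs surfaced exactly this,
  and the path form restores the guarantees: Dist ∈ [0, 1], Dist(a, a) = 0,
  symmetry, and Dist = 1 iff the LCS is the root.

Subsumption is the inclusive ancestor relation; the subsumption table is
the irreflexive transitive closure, emitted in (depth, CUI) order so
outputs diff cleanly. Structural defects (duplicate rows, dangling
parents, cycles, multiple roots) are hard load errors with the offending
line or cycle named; content defects (a CUI not matching `C` + seven
digits, an empty name, a non-numeric SCTID) are collected by `validate`
into a report instead, so imperfect files can still be loaded and
inspected.

## Coverage and corpus statistics

Coverage is exact CUI membership of a test set in an inventory — only
pre-coordinated concepts count; no attempt is made to compose missing
concepts from parts. Contribution accounting reads an optional `source`
column on each concept (this column is this package's extension to the
hierarchy CSV; concepts without one aggregate under "Miscellaneous").
Per-case statistics use the sample (n−1) standard deviation, the
convention for summarizing a case series. Display rounding follows the
field's table conventions — whole percents for coverage and contribution,
one decimal for frequencies, two decimals for distances in CLI output —
via round-half-even, while every stored value keeps full precision.

## Phrase mapping

Normalization is lowercase → punctuation to spaces → whitespace collapse,
and is idempotent. A lexicon stores synonym terms under their normalized
form and is rejected at build time if one normalized term maps to two
CUIs, so lookup never faces ties. Mapping tries, in order: the raw phrase
as a key, the normalized phrase, the laterality-stripped phrase
(whole-word removal of *right, left, bilateral, bilaterally, both*), else
unmapped; the recorded match kind is the first stage that succeeded.
Ordering matters: a concept whose own name contains a laterality word
("bilateral extensor plantar response", C0422917) is matched at the
normalized stage before stripping could mangle it. There is deliberately
no fuzzy or edit-distance matching — phrase-to-concept curation in this
domain is human-audited, and a miss should be visible as a miss.

## What the generators emulate

`reflex_grouping_fixtures()` encodes the two defensible subsumption
strategies for a brisk biceps reflex (group by quality vs by muscle) with
shared leaf CUIs, so the discordance comparison can show that the
hierarchy choice flips which pairs look similar. `neo_skeleton()` is a
42-concept miniature of a full examination ontology: a root, the nine
top-level branches of a neurological examination (mental status, cranial
nerve, motor, sensory, reflex, head, neck, skin, symptoms), and a few
illustrative descendants each, using published CUIs where the concept has
one and reserved `C9xxxxxx` identifiers otherwise. It preserves the
structural facts that matter for testing — nine branches, depth within
the seven-level bound, cross-branch pairs meeting only at the root — but
not the published ontology's size (~1100 concepts) or its per-branch
concept counts.

`random_hierarchy(seed, n, dag)` grows concepts in insertion order, each
drawing parents from roughly the first *i*/branching earlier concepts
(half the draws fill parents in order, half are uniform), which is
acyclic by construction and keeps the mean children per non-leaf near the
branching target (default 3, a realistic fan-out for curated clinical
ontologies). DAG mode draws one to three parents. `synthetic_corpus`
draws lexicon terms, decorates them with case, punctuation, and
laterality noise that normalization provably undoes (the generator
verifies each decorated phrase still maps to its planted CUI, and only
adds laterality to terms that carry none), and plants exactly
round(n·unknown_fraction) out-of-lexicon phrases — so the mapping yield
on such a corpus is known by construction, not estimated.

What passing on these fixtures does *not* show: real examination text is
noisier than the decorations here (abbreviations, negation, compound
sentences), real lexicons are far larger and genuinely ambiguous before
curation, and the absolute distances printed for any particular published
hierarchy depend on its local depths, which a skeleton cannot reproduce.
The fixtures validate the machinery and the invariants, not the coverage
or yield one would obtain on clinical records.

## Numerical and design choices

- Deterministic ordering everywhere: concept listings and subsumption
  tables sort by (depth, CUI); discordance results sort by |Δ| descending
  with stable ties; all generators are seeded (numpy `default_rng`).
- Distance matrices are dense pandas DataFrames — inventories in this
  domain are hundreds to a few thousand concepts, so O(n²) pairs are
  cheap and a labelled table is the useful container.
- Laterality, severity grading (e.g. 4/5 muscle strength), and
  quantitative values (visual acuity) are not modeled on concepts:
  findings are encoded at the granularity of the non-lateralized,
  ungraded concept.
- Test problem sizes: the invariant suite runs sixty seeded random
  hierarchies of 40–200 concepts with twenty sampled pairs each, cross-
  checked against a brute-force oracle that walks raw parent links; the
  round-trip checks include a 1000-concept mono and 200-concept DAG
  fixture. These sizes exercise every code path while keeping the suite
  fast.

## Known limitations

- No OWL/RDF emission and no UMLS RRF parsing; the child-parent CSV is
  the canonical format.
- Coverage cannot score post-coordinated equivalents; an inventory that
  could compose a missing concept still counts it as uncovered.
- The phrase mapper is a lexicon lookup, not an NLP pipeline: it does no
  segmentation, negation handling, or approximate matching.
- Published absolute distance values for licensed hierarchies are not
  reproducible here; the package reproduces the equation, its boundary
  behavior, and qualitative orderings on fixtures.
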