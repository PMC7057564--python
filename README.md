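# neoexam

Tools for encoding neurological-examination findings as concepts in a
curated hierarchy. The neurological examination has no standard
terminology: the same abnormality may be recorded as "sixth nerve palsy",
"abducens palsy", or "abducens nerve weakness", which frustrates any
attempt to aggregate examination data from electronic health records.
The standard remedy is to map each free-text finding to a concept unique
identifier (CUI, the `C#######` codes of the UMLS Metathesaurus) and to
organize the concepts of interest into a small, curated mono-hierarchy
rooted at a single examination-finding concept.

`neoexam` implements the machinery around such an ontology, testable
end-to-end on generated fixtures with no licensed terminology download:

- **Hierarchies** (`neoexam.hierarchy`) — load, validate, and write
  child–parent CSV files (`name,cui,sctid,parent_cui[,source]`, one row
  per link, root row with empty parent); depth, ancestor, and subsumption
  queries; transitive-closure subsumption tables. Both mono-hierarchies
  (trees) and poly-hierarchies (DAGs, as in SNOMED CT) are supported.
- **Inter-concept distance** (`neoexam.distance`) — the normalized
  Wu–Palmer distance

  Dist(a, b) = 1 − 2·depth(LCS) / (depth(a) + depth(b))

  where the LCS is the lowest common subsumer and depth counts levels
  from the root (root depth 0). Dist is 0 for identical concepts and
  exactly 1 when a pair meets only at the root. Pairwise matrices and a
  cross-hierarchy discordance comparison (the same pair under two
  subsumption strategies) are included.
- **Coverage statistics** (`neoexam.coverage`) — how much of a test
  concept set an ontology inventory covers (exact pre-coordinated CUI
  match), per-source-vocabulary contribution counts, concept frequency
  tables over a mapped corpus, and per-case summary statistics.
- **Phrase mapping** (`neoexam.mapping`) — normalize free-text phrases
  (lowercase, strip punctuation, collapse whitespace) and resolve them
  through a synonym lexicon, with a final fallback that ignores
  laterality ("right ataxia", "left ataxia", and "bilateral ataxia" all
  map to plain ataxia, C0004134). Matching is exact on normalized keys;
  there is no fuzzy matching, so every mapping is auditable.
- **Fixtures** (`neoexam.fixtures`) — deterministic generators: the two
  alternative reflex-grouping hierarchies (by quality vs by muscle), a
  nine-branch examination skeleton, seeded random hierarchies, and
  synthetic phrase corpora with planted ground truth.

A thin `neo` command wraps everything for shell use
(`validate stats depth lcs dist matrix compare subsumption coverage freq
contrib map fixture`).

## Worked example

```python
import neoexam as neo
from neoexam import fixtures as fx

by_quality, by_muscle = fx.reflex_grouping_fixtures()
pair = (fx.BRISK_BICEPS, fx.ABSENT_BICEPS)
print(neo.wu_palmer_distance(by_quality, *pair))  # 0.6666666666666667
print(neo.wu_palmer_distance(by_muscle, *pair))   # 0.33333333333333337
```

A brisk biceps reflex can be subsumed under *brisk reflex* (grouping by
quality) or under *biceps reflex finding* (grouping by muscle); both are
semantically correct. Under the quality grouping the pair's lowest
common subsumer is *reflex finding* at depth 1 and both concepts sit at
depth 3, so Dist = 1 − 2·1/(3+3) ≈ 0.67; under the muscle grouping the
LCS is *biceps reflex finding* at depth 2, so Dist ≈ 0.33. The choice of
hierarchy — not the metric — decides whether a brisk biceps reflex looks
more like a brisk knee reflex or like an absent biceps reflex.

The same from the shell:

```console
$ neo fixture --kind skeleton --out skeleton.csv
wrote 42 concepts to skeleton.csv
$ neo dist skeleton.csv C0018681 C9100005   # headache vs absent ankle reflex
1.00
$ neo stats skeleton.csv
concepts        42
max_depth       3
mean_children   3.42
```

Concepts in different top-level branches of the examination skeleton
(here a head finding and a reflex finding) share only the root, so their
distance is exactly 1.00. The `examples/` directory has three short
narrative scripts covering distances, coverage statistics, and phrase
mapping; each prints its numbers with a line on what they mean.

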