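"""Deterministic toy hierarchies, lexicons, and phrase corpora.

Everything here is generated in memory, so the rest of the package is
testable end-to-end without downloading any licensed terminology.  Concepts
with published UMLS identifiers use their real CUIs (e.g. ataxia C0004134,
bilateral extensor plantar response C0422917); all other fixture concepts
get synthetic CUIs in the reserved C9xxxxxx range to avoid colliding with
real codes.

The two ``reflex_grouping_fixtures`` hierarchies encode the classic
subsumption dilemma for a brisk biceps reflex: group it with other brisk
reflexes (by quality, as a curated examination ontology does) or with
other biceps reflexes (by muscle, as SNOMED CT does).  Both are
semantically correct but yield opposite inter-concept distance orderings,
which is exactly what the discordance comparison is for.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import EmptyInputError
from .hierarchy import Concept, ConceptHierarchy
from .mapping import Lexicon, build_lexicon, map_phrase, normalize_phrase, strip_laterality

ROOT_CUI = "C9000000"

# Shared leaf CUIs so the two reflex hierarchies can be compared pairwise.
BRISK_BICEPS = "C9100001"
ABSENT_BICEPS = "C9100002"
BRISK_KNEE = "C9100003"
BRISK_ANKLE = "C9100004"
ABSENT_ANKLE = "C9100005"

#: Published CUI for "bilateral extensor plantar response".
EXTENSOR_PLANTAR_CUI = "C0422917"
#: Published CUI for "ataxia" (laterality deliberately not modeled).
ATAXIA_CUI = "C0004134"

#: The thirteen ways the teaching cases phrased a bilateral extensor
#: plantar response; all of them normalize to one concept.
EXTENSOR_PLANTAR_VARIANTS = (
    "Babinski response elicited bilaterally",
    "bilateral Babinski responses",
    "bilateral Babinski signs",
    "bilateral extensor toes signs",
    "bilateral upgoing plantars",
    "bilateral upgoing toes",
    "both plantar responses were extensor",
    "both plantars were upgoing",
    "both toes upgoing",
    "plantar responses were extensor",
    "plantars extensor",
    "upgoing plantar responses bilaterally",
    "upgoing plantars",
)


def extensor_plantar_lexicon() -> Lexicon:
    """Lexicon mapping all thirteen phrase variants to C0422917."""
    return build_lexicon(
        (term, EXTENSOR_PLANTAR_CUI) for term in EXTENSOR_PLANTAR_VARIANTS
    )


def demo_lexicon() -> Lexicon:
    """A small mixed lexicon: plantar-response variants plus common findings."""
    entries = [(term, EXTENSOR_PLANTAR_CUI) for term in EXTENSOR_PLANTAR_VARIANTS]
    entries += [
        ("ataxia", ATAXIA_CUI),
        ("hyperreflexia", "C0151889"),
        ("brisk reflexes", "C0151889"),
        ("quadriceps weakness", "C0577655"),
        ("weak quadriceps", "C0577655"),
        ("reduced visual acuity", "C0234632"),
        ("decreased visual acuity", "C0234632"),
        ("aphasia", "C0003537"),
        ("loss of words", "C0003537"),
        ("headache", "C0018681"),
        ("unstable gait", "C0231686"),
        ("dysarthria", "C0013362"),
        ("hemiparesis", "C0018989"),
        ("neck stiffness", "C0151315"),
    ]
    return build_lexicon(entries)


# -- reflex grouping fixtures --------------------------------------------


def reflex_grouping_fixtures() -> tuple[ConceptHierarchy, ConceptHierarchy]:
    """The two alternative 7-concept reflex hierarchies.

    Returns ``(by_quality, by_muscle)``.  The first groups leaves under
    brisk/absent reflex (quality); the second groups the same leaves under
    biceps/knee reflex findings (muscle).  Leaf CUIs are shared so
    cross-hierarchy distance comparison can pair them.
    """
    by_quality = ConceptHierarchy(
        [
            Concept(ROOT_CUI, "neurological finding"),
            Concept("C9100010", "reflex finding", parents=(ROOT_CUI,)),
            Concept("C9100011", "brisk reflex", parents=("C9100010",)),
            Concept("C9100012", "absent reflex", parents=("C9100010",)),
            Concept(BRISK_BICEPS, "brisk biceps reflex", parents=("C9100011",)),
            Concept(BRISK_KNEE, "brisk knee reflex", parents=("C9100011",)),
            Concept(ABSENT_BICEPS, "absent biceps reflex", parents=("C9100012",)),
        ],
        mode="mono",
    )
    by_muscle = ConceptHierarchy(
        [
            Concept(ROOT_CUI, "neurological finding"),
            Concept("C9100010", "reflex finding", parents=(ROOT_CUI,)),
            Concept("C9100021", "biceps reflex finding", parents=("C9100010",)),
            Concept("C9100022", "knee reflex finding", parents=("C9100010",)),
            Concept(BRISK_BICEPS, "brisk biceps reflex", parents=("C9100021",)),
            Concept(ABSENT_BICEPS, "absent biceps reflex", parents=("C9100021",)),
            Concept(BRISK_KNEE, "brisk knee reflex", parents=("C9100022",)),
        ],
        mode="mono",
    )
    return by_quality, by_muscle


# Backwards-compatible aliases matching the figure's panel labels.
fig2_fixtures = reflex_grouping_fixtures


# -- examination skeleton ------------------------------------------------

_SKELETON_BRANCHES: dict[tuple[str, str], list[tuple[str, str, str | None]]] = {
    ("C9000001", "mental status finding"): [
        ("C0009676", "confused", "SNOMED CT"),
        ("C0233794", "impaired memory", "SNOMED CT"),
        ("C0233407", "disorientation", "SNOMED CT"),
        ("C0003537", "aphasia", "SNOMED CT"),
    ],
    ("C9000002", "cranial nerve finding"): [
        ("C0012569", "diplopia", "SNOMED CT"),
        ("C0030353", "papilledema", "SNOMED CT"),
        ("C0234632", "reduced visual acuity", "SNOMED CT"),
        ("C1384666", "hearing impaired", "MEDCIN"),
        ("C0013362", "dysarthria", "SNOMED CT"),
    ],
    ("C9000003", "motor finding"): [
        ("C0018989", "hemiparesis", "SNOMED CT"),
        ("C0577655", "quadriceps weakness", "SNOMED CT"),
        ("C0004134", "ataxia", "SNOMED CT"),
    ],
    ("C9000004", "sensory finding"): [
        ("C9200001", "decreased tactile sensation of hand", "MEDCIN"),
        ("C9200002", "sensory level at T2 dermatome", "MEDCIN"),
    ],
    # The reflex branch nests the quality-grouped subtree two levels deep.
    ("C9100010", "reflex finding"): [],
    ("C9000005", "head finding"): [
        ("C0018681", "headache", "MeSH"),
        ("C9200003", "head tilt", "OMIM"),
    ],
    ("C9000006", "neck finding"): [
        ("C0151315", "neck stiffness", "SNOMED CT"),
        ("C9200004", "limited neck rotation", "MEDCIN"),
    ],
    ("C9000007", "skin finding"): [
        ("C9200005", "neurocutaneous lesion", "HPO"),
        ("C9200006", "facial port wine stain", "HPO"),
    ],
    ("C9000008", "neurological symptoms"): [
        ("C9200007", "numbness", None),
        ("C9200008", "tingling", None),
        ("C0231686", "unstable gait", "SNOMED CT"),
    ],
}


def neo_skeleton() -> ConceptHierarchy:
    """A miniature examination ontology: root plus nine top-level branches.

    The branches mirror the sections of a neurological examination (mental
    status, cranial nerve, motor, sensory, reflex) plus head, neck, skin,
    and symptoms, each with a few illustrative descendants; the reflex
    branch contains the quality-grouped reflex subtree.  Maximum depth 3.
    Any two leaves in different top-level branches meet only at the root,
    so their normalized distance is exactly 1.0.
    """
    concepts = [Concept(ROOT_CUI, "neurological examination finding")]
    for (branch_cui, branch_name), members in _SKELETON_BRANCHES.items():
        concepts.append(
            Concept(branch_cui, branch_name, parents=(ROOT_CUI,), source="SNOMED CT")
        )
        for cui, name, source in members:
            concepts.append(
                Concept(cui, name, parents=(branch_cui,), source=source)
            )
    # Reflex subtree: grouped by quality, as the curated ontology does.
    concepts += [
        Concept("C9100011", "brisk reflex", parents=("C9100010",), source="SNOMED CT"),
        Concept("C9100012", "absent reflex", parents=("C9100010",), source="SNOMED CT"),
        Concept("C0151889", "hyperreflexia", parents=("C9100010",), source="SNOMED CT"),
        Concept(EXTENSOR_PLANTAR_CUI, "bilateral extensor plantar response",
                parents=("C9100010",), source="SNOMED CT"),
        Concept(BRISK_BICEPS, "brisk biceps reflex", parents=("C9100011",), source="MEDCIN"),
        Concept(BRISK_KNEE, "brisk knee reflex", parents=("C9100011",), source="MEDCIN"),
        Concept(BRISK_ANKLE, "brisk ankle reflex", parents=("C9100011",), source="MEDCIN"),
        Concept(ABSENT_BICEPS, "absent biceps reflex", parents=("C9100012",), source="MEDCIN"),
        Concept(ABSENT_ANKLE, "absent ankle reflex", parents=("C9100012",), source="MEDCIN"),
    ]
    return ConceptHierarchy(concepts, mode="mono")


def skeleton_branch_cuis() -> list[str]:
    """CUIs of the nine top-level branches, in canonical order."""
    return sorted(cui for cui, _ in _SKELETON_BRANCHES)


# -- random hierarchies --------------------------------------------------


def random_hierarchy(
    seed: int, n: int, dag: bool = False, branching: float = 3.0
) -> ConceptHierarchy:
    """A seeded random hierarchy of *n* concepts with synthetic CUIs.

    Concepts are added in order; each non-root concept draws its parent(s)
    from the earlier concepts, so the graph is acyclic by construction.
    Restricting candidate parents to roughly the first ``i / branching``
    concepts keeps the mean number of children per non-leaf near
    *branching*.  In DAG mode a concept gets one to three parents.
    """
    if n < 1:
        raise EmptyInputError("n must be >= 1")
    rng = np.random.default_rng(seed)
    ids = [f"C9{i:06d}" for i in range(n)]
    concepts = [Concept(ids[0], "synthetic root")]
    for i in range(1, n):
        pool = max(1, math.ceil(i / branching))
        # Half the draws fill parents in order, half are uniform over the
        # pool; this keeps the realized mean children per non-leaf close
        # to the branching target instead of drifting above it.
        if rng.random() < 0.5:
            primary = (i - 1) // max(1, round(branching))
        else:
            primary = int(rng.integers(0, pool))
        if dag:
            k = min(int(rng.integers(1, 4)), pool)
            extra = rng.choice(pool, size=k, replace=False)
            parents = tuple(ids[j] for j in sorted({primary, *map(int, extra)})[:3])
        else:
            parents = (ids[primary],)
        concepts.append(
            Concept(ids[i], f"synthetic concept {i}", parents=parents)
        )
    return ConceptHierarchy(concepts, mode="dag" if dag else "mono")


# -- synthetic phrase corpora --------------------------------------------


@dataclass
class SyntheticCorpus:
    """Phrases with planted ground truth (CUI, or None for unknowns)."""

    phrases: list[str]
    true_cuis: list[str | None]

    @property
    def n_mappable(self) -> int:
        return sum(1 for c in self.true_cuis if c is not None)


_CASE_NOISE = ("keep", "title", "upper", "capitalize")
_PUNCT_SUFFIX = ("", "!", ".", "!!")


def synthetic_corpus(
    lex: Lexicon, seed: int, n: int, unknown_fraction: float
) -> SyntheticCorpus:
    """Draw *n* phrases from a lexicon with planted unmappable phrases.

    Exactly ``round(n * unknown_fraction)`` phrases are out-of-lexicon; the
    rest are lexicon terms decorated with case, punctuation, and laterality
    noise that the normalization pipeline is guaranteed to undo (the
    generator verifies each decorated phrase still maps to its planted
    CUI).  Output order is a seeded shuffle.
    """
    if not lex.entries:
        raise EmptyInputError("lexicon is empty")
    if not 0.0 <= unknown_fraction <= 1.0:
        raise ValueError("unknown_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    terms = sorted(lex.entries)
    laterality = sorted({"right", "left", "bilateral", "both"})

    n_unknown = round(n * unknown_fraction)
    items: list[tuple[str, str | None]] = []
    for i in range(n - n_unknown):
        term = terms[int(rng.integers(len(terms)))]
        phrase = term
        # Laterality decoration only when the term itself carries none,
        # otherwise stripping would also delete part of the key.
        if strip_laterality(term) == term and rng.random() < 0.4:
            phrase = f"{laterality[int(rng.integers(len(laterality)))]} {phrase}"
        noise = _CASE_NOISE[int(rng.integers(len(_CASE_NOISE)))]
        if noise == "title":
            phrase = phrase.title()
        elif noise == "upper":
            phrase = phrase.upper()
        elif noise == "capitalize":
            phrase = phrase.capitalize()
        if rng.random() < 0.3:
            phrase = phrase.replace(" ", " - ", 1)
        phrase = phrase + _PUNCT_SUFFIX[int(rng.integers(len(_PUNCT_SUFFIX)))]
        if rng.random() < 0.2:
            phrase = f"  {phrase} "
        cui = lex.entries[normalize_phrase(term)]
        assert map_phrase(lex, phrase).cui == cui, phrase
        items.append((phrase, cui))
    for i in range(n_unknown):
        phrase = f"untranslatable synthetic finding {i:04d}"
        assert map_phrase(lex, phrase).match_kind == "unmapped"
        items.append((phrase, None))

    order = rng.permutation(len(items))
    phrases = [items[j][0] for j in order]
    true_cuis = [items[j][1] for j in order]
    return SyntheticCorpus(phrases=phrases, true_cuis=true_cuis)


# -- dispatch ------------------------------------------------------------

FIXTURE_KINDS = ("fig2_neo", "fig2_snomed", "skeleton", "random")


def make_fixture(
    kind: str, seed: int = 0, size: int = 50, dag: bool = False
) -> ConceptHierarchy:
    """Build a named hierarchy fixture (used by the CLI)."""
    if kind == "fig2_neo":
        return reflex_grouping_fixtures()[0]
    if kind == "fig2_snomed":
        return reflex_grouping_fixtures()[1]
    if kind == "skeleton":
        return neo_skeleton()
    if kind == "random":
        return random_hierarchy(seed, size, dag=dag)
    raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
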