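"""Lowest common subsumer and normalized Wu-Palmer inter-concept distance.

The distance between concepts *a* and *b* in a rooted hierarchy is

    Dist(a, b) = 1 - 2 * depth(LCS) / (depth(a) + depth(b))

where the LCS is the lowest common subsumer and depth counts levels from
the root (root depth 0).  The result is normalized: 0.0 for identical
concepts, 1.0 when the only common subsumer is the root.

On a mono-hierarchy every ancestor of a concept lies on its single root
path, so the equation can be evaluated with plain node depths.  On a
poly-hierarchy that shortcut breaks down -- a concept can reach the root
by a short route while also sitting under a deep ancestor, which would
push the ratio above one.  The distance therefore follows Wu and Palmer's
original path formulation: the LCS is a subsumption-minimal common
ancestor (no other common ancestor below it), and the depths of *a* and
*b* are measured through the LCS, i.e. depth(LCS) plus the shortest
descent from the LCS.  On a tree the two readings coincide exactly;
on a DAG the path form keeps the distance in [0, 1] with Dist(a, a) = 0.
LCS ties at equal depth break to the lexicographically smallest CUI, so
results are deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .errors import SkippedPairWarning
from .hierarchy import ConceptHierarchy


def lcs(h: ConceptHierarchy, a: str, b: str) -> str:
    """The lowest common subsumer of *a* and *b*.

    Ancestor sets are inclusive, so ``lcs(h, a, a) == a`` and the LCS of a
    concept with its own ancestor is that ancestor.  "Lowest" is meant in
    the subsumption order: no other common ancestor lies below the result.
    Among several lowest candidates (possible in DAG mode) the deepest
    wins; remaining ties break to the smallest CUI.
    """
    common = h.ancestors(a) & h.ancestors(b)
    lowest = [
        c
        for c in common
        if not any(c != d and c in h.ancestors(d) for d in common)
    ]
    return min(lowest, key=lambda c: (-h.depth(c), c))


def wu_palmer_distance(h: ConceptHierarchy, a: str, b: str) -> float:
    """Normalized Wu-Palmer distance between two concepts in [0, 1].

    Evaluates ``1 - 2*depth(LCS) / (depth(a) + depth(b))`` with the depths
    of *a* and *b* measured through the LCS (identical to plain depths on
    a mono-hierarchy).  ``Dist(root, root)`` is defined as 0, where the
    raw ratio would be 0/0, so identity holds universally.
    """
    anc = lcs(h, a, b)
    d_lcs = h.depth(anc)
    denom = 2 * d_lcs + h.descent_length(anc, a) + h.descent_length(anc, b)
    if denom == 0:
        return 0.0
    return 1.0 - 2.0 * d_lcs / denom


def distance_matrix(h: ConceptHierarchy, ids: list[str]) -> pd.DataFrame:
    """Symmetric pairwise distance matrix over *ids*, zero on the diagonal."""
    for cui in ids:
        h.depth(cui)  # raises MissingConceptError on unknown ids
    mat = pd.DataFrame(0.0, index=ids, columns=ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            d = wu_palmer_distance(h, a, b)
            mat.loc[a, b] = d
            mat.loc[b, a] = d
    return mat


@dataclass(frozen=True)
class DiscordancePair:
    """One concept pair with its distance under two hierarchies."""

    a: str
    b: str
    dist_h1: float
    dist_h2: float

    @property
    def delta(self) -> float:
        return self.dist_h2 - self.dist_h1


def compare_distances(
    h1: ConceptHierarchy,
    h2: ConceptHierarchy,
    pairs: list[tuple[str, str]],
) -> list[DiscordancePair]:
    """Distances for each pair under both hierarchies, most discordant first.

    Pairs whose CUIs do not resolve in both hierarchies are skipped with a
    :class:`SkippedPairWarning` rather than raising.  Results are sorted by
    absolute delta, descending; ties keep input order.
    """
    out: list[DiscordancePair] = []
    for a, b in pairs:
        missing = [c for c in (a, b) if c not in h1 or c not in h2]
        if missing:
            warnings.warn(
                f"pair ({a}, {b}) skipped: {', '.join(missing)} not present "
                "in both hierarchies",
                SkippedPairWarning,
                stacklevel=2,
            )
            continue
        out.append(
            DiscordancePair(
                a=a,
                b=b,
                dist_h1=wu_palmer_distance(h1, a, b),
                dist_h2=wu_palmer_distance(h2, a, b),
            )
        )
    out.sort(key=lambda p: -abs(p.delta))
    return out
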