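"""Brute-force reference implementations used to cross-check the library.

These walk the raw parent links stored on the concepts and deliberately
share no code (and no graph library) with the optimized routines.
"""

from __future__ import annotations

from neoexam.hierarchy import ConceptHierarchy


def bf_ancestors(h: ConceptHierarchy, a: str) -> set[str]:
    """Inclusive ancestor set by naive recursive reachability."""
    seen: set[str] = set()
    stack = [a]
    while stack:
        node = stack.pop()
        if node in seen:
            continue
        seen.add(node)
        stack.extend(h.concepts[node].parents)
    return seen


def bf_depth(h: ConceptHierarchy, a: str) -> int:
    """Shortest root-path length by exhaustive recursion over parents."""
    memo: dict[str, int] = {}

    def go(node: str) -> int:
        if node in memo:
            return memo[node]
        parents = h.concepts[node].parents
        memo[node] = 0 if not parents else 1 + min(go(p) for p in parents)
        return memo[node]

    return go(a)


def bf_lcs(h: ConceptHierarchy, a: str, b: str) -> str:
    """Subsumption-lowest common (inclusive) ancestor.

    Candidates with another common ancestor below them are discarded;
    the deepest survivor wins, ties broken by smallest CUI.
    """
    common = bf_ancestors(h, a) & bf_ancestors(h, b)
    lowest = [
        c for c in common
        if not any(c != d and c in bf_ancestors(h, d) for d in common)
    ]
    best_depth = max(bf_depth(h, c) for c in lowest)
    return min(c for c in lowest if bf_depth(h, c) == best_depth)


def bf_up_length(h: ConceptHierarchy, desc: str, anc: str) -> int:
    """Fewest parent steps from *desc* up to *anc* (breadth-first)."""
    frontier, steps, seen = {desc}, 0, set()
    while frontier:
        if anc in frontier:
            return steps
        seen |= frontier
        frontier = {
            p for node in frontier for p in h.concepts[node].parents
        } - seen
        steps += 1
    raise ValueError(f"{anc} is not an ancestor of {desc}")


def bf_wu_palmer(h: ConceptHierarchy, a: str, b: str) -> float:
    anc = bf_lcs(h, a, b)
    d_lcs = bf_depth(h, anc)
    denom = 2 * d_lcs + bf_up_length(h, a, anc) + bf_up_length(h, b, anc)
    if denom == 0:
        return 0.0
    return 1.0 - 2.0 * d_lcs / denom
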