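"""Hierarchy loading, validation, queries, and CSV round-trips."""

import pytest

import neoexam as neo
from neoexam import fixtures as fx
from oracles import bf_ancestors, bf_depth

FIG2_CSV = """\
name,cui,sctid,parent_cui
neurological finding,C9000000,,
reflex finding,C9100010,,C9000000
brisk reflex,C9100011,,C9100010
absent reflex,C9100012,,C9100010
brisk biceps reflex,C9100001,,C9100011
brisk knee reflex,C9100003,,C9100011
absent biceps reflex,C9100002,,C9100012
"""


def test_load_reflex_csv_builds_expected_structure():
    h = neo.loads_hierarchy(FIG2_CSV)
    assert len(h) == 7
    assert h.root == "C9000000"
    assert h.concepts["C9100001"].name == "brisk biceps reflex"
    assert h == fx.reflex_grouping_fixtures()[0]


def test_load_single_row_gives_root_only_hierarchy():
    h = neo.loads_hierarchy("name,cui,sctid,parent_cui\nroot,C0000001,,\n")
    assert len(h) == 1 and h.depth(h.root) == 0


@pytest.mark.parametrize(
    "body,exc",
    [
        # two concepts that are each other's parents
        ("x,C0000001,,C0000002\ny,C0000002,,C0000001\n", neo.CycleError),
        # duplicate CUI in mono mode
        ("r,C0000001,,\nx,C0000002,,C0000001\nx,C0000002,,C0000001\n",
         neo.DuplicateConceptError),
        # parent that resolves to nothing
        ("r,C0000001,,\nx,C0000002,,C0000009\n", neo.DanglingParentError),
        # two parentless rows in mono mode
        ("r,C0000001,,\ns,C0000002,,\n", neo.MultiRootError),
    ],
)
def test_structural_errors_are_specific(body, exc):
    with pytest.raises(exc):
        neo.loads_hierarchy("name,cui,sctid,parent_cui\n" + body)


@pytest.mark.parametrize(
    "text",
    [
        "",  # no header at all
        "concept,identifier\nroot,C0000001\n",  # wrong header
        "name,cui,sctid,parent_cui\nroot,C0000001\n",  # short row
    ],
)
def test_malformed_csv_raises_parse_error(text):
    with pytest.raises(neo.HierarchyParseError):
        neo.loads_hierarchy(text)


def test_self_parent_row_is_an_error():
    with pytest.raises(neo.CycleError):
        neo.ConceptHierarchy(
            [neo.Concept("C0000001", "r"),
             neo.Concept("C0000002", "x", parents=("C0000002",))]
        )


def test_validate_reports_ok_and_stats(by_quality, skeleton):
    rep = neo.validate(by_quality)
    assert rep.ok and rep.stats.max_depth == 3
    rep = neo.validate(skeleton)
    assert rep.ok
    assert len(skeleton.children(skeleton.root)) == 9


def test_validate_flags_bad_cui_without_refusing_to_load():
    h = neo.loads_hierarchy(
        "name,cui,sctid,parent_cui\nroot,C123,,\nx,C0000002,,C123\n"
    )
    rep = neo.validate(h)
    assert not rep.ok
    assert any(code == "cui-format" and cui == "C123"
               for code, cui, _ in rep.errors)


def test_validate_flags_empty_name():
    rep = neo.validate(
        neo.ConceptHierarchy(
            [neo.Concept("C0000001", "r"),
             neo.Concept("C0000002", "", parents=("C0000001",))]
        )
    )
    assert ("empty-name", "C0000002") in [(c, i) for c, i, _ in rep.errors]


def test_depth_counts_levels_from_root(by_quality):
    assert by_quality.depth(by_quality.root) == 0
    assert by_quality.depth(fx.BRISK_BICEPS) == 3
    with pytest.raises(neo.MissingConceptError):
        by_quality.depth("C9999999")


def test_depth_is_shortest_root_path_in_dag_mode():
    # "a" has parents at depths 1 and 3; the shortest route wins.
    h = neo.ConceptHierarchy(
        [
            neo.Concept("C0000001", "root"),
            neo.Concept("C0000002", "d1", parents=("C0000001",)),
            neo.Concept("C0000003", "d2", parents=("C0000002",)),
            neo.Concept("C0000004", "d3", parents=("C0000003",)),
            neo.Concept("C0000005", "a", parents=("C0000002", "C0000004")),
        ],
        mode="dag",
    )
    assert h.depth("C0000005") == 2 == bf_depth(h, "C0000005")


def test_ancestors_is_inclusive_and_contains_root(by_quality):
    root = by_quality.root
    assert by_quality.ancestors(root) == {root}
    assert by_quality.ancestors(fx.BRISK_BICEPS) == {
        fx.BRISK_BICEPS, "C9100011", "C9100010", root
    }


@pytest.mark.parametrize("seed", range(10))
@pytest.mark.parametrize("dag", [False, True])
def test_depth_and_ancestors_match_brute_force(seed, dag):
    h = fx.random_hierarchy(seed, 120, dag=dag)
    for cui in h.concepts:
        assert h.depth(cui) == bf_depth(h, cui)
        assert h.ancestors(cui) == bf_ancestors(h, cui)
        parents = h.concepts[cui].parents
        if parents:
            assert h.depth(cui) == 1 + min(h.depth(p) for p in parents)
        else:
            assert h.depth(cui) == 0


def test_subsumes_follows_is_a_direction(by_quality):
    root = by_quality.root
    for cui in by_quality.concepts:
        assert by_quality.subsumes(root, cui)
    assert by_quality.subsumes("C9100011", fx.BRISK_BICEPS)  # brisk reflex
    assert not by_quality.subsumes(fx.BRISK_BICEPS, "C9100011")


def test_subsumption_table_is_the_irreflexive_transitive_closure(by_quality):
    root_only = neo.ConceptHierarchy([neo.Concept("C0000001", "r")])
    assert root_only.subsumption_table() == []

    chain = neo.ConceptHierarchy(
        [
            neo.Concept("C0000001", "root"),
            neo.Concept("C0000002", "a", parents=("C0000001",)),
            neo.Concept("C0000003", "b", parents=("C0000002",)),
        ]
    )
    assert set(chain.subsumption_table()) == {
        ("C0000001", "C0000002"),
        ("C0000001", "C0000003"),
        ("C0000002", "C0000003"),
    }

    table = by_quality.subsumption_table()
    # Frozen from the enumeration oracle: sum over nodes of |descendants|.
    expected = {
        (anc, desc)
        for anc in by_quality.concepts
        for desc in by_quality.concepts
        if anc != desc and anc in bf_ancestors(by_quality, desc)
    }
    assert set(table) == expected
    assert len(table) == 14
    # Antisymmetry: no pair appears in both directions.
    assert not {(d, a) for a, d in table} & set(table)


@pytest.mark.parametrize(
    "make",
    [
        lambda: fx.reflex_grouping_fixtures()[0],
        lambda: fx.reflex_grouping_fixtures()[1],
        fx.neo_skeleton,
        lambda: fx.random_hierarchy(17, 1000, dag=False),
        lambda: fx.random_hierarchy(17, 300, dag=True),
    ],
)
def test_csv_round_trip_is_identity(tmp_path, make):
    h = make()
    path = tmp_path / "h.csv"
    neo.write_hierarchy(h, path)
    assert neo.load_hierarchy(path, mode=h.mode) == h


def test_empty_sctid_written_as_empty_cell(tmp_path):
    h = neo.ConceptHierarchy(
        [neo.Concept("C0000001", "root", sctid=None)]
    )
    path = tmp_path / "h.csv"
    neo.write_hierarchy(h, path)
    text = path.read_text()
    assert "None" not in text
    assert "root,C0000001,,\r\n" in text or "root,C0000001,,\n" in text
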