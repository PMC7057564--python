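"""Coverage, contribution, and frequency accounting on synthetic inputs.

A test list of 601 concept identifiers is checked against inventories of
varying completeness; the skeleton ontology's per-source contributions and
a small frequency table round out the report shapes.
"""

import neoexam as neo
from neoexam import fixtures as fx

test_concepts = [f"C{i:07d}" for i in range(1, 602)]

print("coverage of a 601-concept test list:")
for n_hit in (601, 412, 317, 118):
    report = neo.coverage(test_concepts, test_concepts[:n_hit])
    print(f"  inventory holding {n_hit:>3} of them -> {report.percent:>4}"
          f"  ({report.n_covered}/{report.n_test})")

print("\nper-source contribution in the skeleton ontology:")
contrib = neo.source_contribution(fx.neo_skeleton())
for source, count, proportion in contrib.rows:
    print(f"  {source:<14}{count:>3}  {neo.percent_display(proportion):>4}")

print("\nfrequency of mapped findings (47 of 2386 are hyperreflexia):")
corpus = ["C0151889"] * 47 + [f"C{1000 + i:07d}" for i in range(2339)]
table = neo.concept_frequency(corpus, names={"C0151889": "hyperreflexia"})
cui, name, count, proportion = table.rows[0]
print(f"  {name} ({cui}): {count} occurrences,"
      f" {neo.percent_display(proportion, 1)} of findings")

stats = neo.case_statistics([6] * 291 + [5] * 128)
print(f"\nfindings per case over {stats.n_cases} cases: {stats.display}")
print("(mean ± sample standard deviation)")
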