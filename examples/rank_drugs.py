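"""Rank drugs and drug combinations over prioritized network nodes.

Uses the bundled reference table of drugs per indispensable node: drugs are
ranked by how many prioritized nodes they cover, and combinations around an
anchor drug are assembled from pairwise non-interacting partners.
"""

from tepcontrol.drugs import map_targets, rank_combinations, rank_drugs
from tepcontrol.synthetic import load_reference_fixtures

table3 = load_reference_fixtures()["table3"]
drugs = list(table3.values())
nodes = frozenset().union(*(d.targets for d in drugs))

ranked = rank_drugs(map_targets(nodes, drugs))
print("single agents by indispensable-target coverage:")
for drug, count in ranked[:5]:
    print(f"  {drug:25s} {count}")

combos = rank_combinations(drugs, anchor="Fostamatinib", interactions=set(),
                           nodes=nodes, max_size=3)
best = combos[0]
print(f"\nbest combination around Fostamatinib: {' + '.join(best.members)}")
print(f"  union coverage: {best.coverage} targets")
print("coverage counts distinct targets (a union, never a sum), so partners")
print("that duplicate the anchor's targets add nothing")
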