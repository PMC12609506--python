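"""Classify every node of a directed network by its controllability role.

A maximum matching of the bipartite representation yields the minimum number
of driver nodes N_D; nodes are then classed as critical / intermittent /
redundant (in every / some / no minimum driver set) and indispensable /
neutral / dispensable (their deletion raises / keeps / lowers N_D).
"""

from tepcontrol.controllability import (
    driver_count_and_set,
    maximum_matching,
    node_control_profiles,
)
from tepcontrol.synthetic import load_reference_fixtures

star = load_reference_fixtures()["toy_graphs"]["star4"]
n_d, drivers = driver_count_and_set(star, maximum_matching(star))
print(f"star h->(a,b,c): N_D = {n_d}, drivers = {sorted(drivers)}")
print("the hub can feed only one leaf at a time, so the other two leaves and")
print("the hub itself (nothing feeds it) need external inputs\n")

profiles = node_control_profiles(star, seed=1, n_samples=200)
cols = ["mds_class", "removal_class", "control_capacity", "control_centrality"]
print(profiles[cols].to_string())
print("\ncontrol capacity is the fraction of minimum driver sets containing")
print("the node; control centrality the dimension a single input there steers")
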