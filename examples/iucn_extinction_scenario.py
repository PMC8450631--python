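"""IUCN-ordered extinction over a synthetic host-parasite community.

Removes all CR hosts, then EN, VU, NT (domesticated and DD hosts are
treated as LC and never removed), recomputing every parasite's host
richness and MPD at each step, and contrasts one batch scenario with the
fan of randomized single-host extinction orders for one generalist.
"""

import numpy as np

import coextinct as cx

cfg = cx.SynthConfig(n_tips=200, n_parasites=100, phi=2.0, beta=1.5, seed=11)
tree = cx.simulate_tree(cfg)
net = cx.simulate_network(tree, cfg)

scenario = cx.iucn_scenario(net)
print("hosts removed per step (CR, EN, VU, NT):",
      [len(e) for e in scenario.events])

traj = cx.run(scenario, net, tree, cx.CoextinctionRule("all_hosts_lost"))
for st in traj.steps:
    alive = [p for p in net.parasites if p not in st.coextinct]
    deltas = [st.delta_mpd[p] for p in alive if abs(st.delta_mpd[p]) > 1e-9]
    print(
        f"  step {st.step}: {len(st.surviving_hosts)} hosts, "
        f"{len(st.coextinct)} parasites coextinct, "
        f"{len(deltas)} with changed MPD "
        f"(mean shift {np.mean(deltas) if deltas else 0:+.2f} Myr)"
    )
# Most parasites shift little, but MPD moves in both directions and a few
# parasites lose every documented host.

# --- randomized extinction orders for the most generalist parasite
focal = max(net.parasites, key=lambda p: len(net.hosts_of(p)))
print(f"\nrandomized extinction orders for {focal} "
      f"({len(net.hosts_of(focal))} hosts): final-step MPD trajectories")
ups = downs = 0
for seed in range(50):
    sc = cx.random_order_scenario(net, focal, seed=seed)
    t = cx.run(sc, net, tree)
    mid = t.steps[len(t.steps) // 2]
    if mid.delta_mpd[focal] > 0:
        ups += 1
    elif mid.delta_mpd[focal] < 0:
        downs += 1
print(f"  at the half-way step, MPD is up in {ups} orders "
      f"and down in {downs} of 50")
# The order of host loss alone decides whether the parasite looks like an
# emerging generalist or an emerging specialist along the way.
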