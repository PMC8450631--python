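"""Which way does optimal virulence evolve when a host goes extinct?

A parasite shared across host classes and constrained to one virulence
level settles at a force-of-infection-weighted compromise between the
hosts' individual optima v* = s*mu/(1-s).  Removing a host re-normalizes
the weights and shifts the compromise towards the survivors' optima.
"""

import coextinct as cx

system = cx.MultiHostSystem(
    [
        cx.HostClass("rodent", rho=0.6, mu=1.0, s=0.5),   # v* = 1.0
        cx.HostClass("carnivore", rho=0.3, mu=3.0, s=0.5),  # v* = 3.0
        cx.HostClass("primate", rho=0.1, mu=5.0, s=0.5),   # v* = 5.0
    ]
)
for h in system.hosts:
    print(f"  {h.id:9s} rho={h.rho:.2f} single-host optimum "
          f"v*={cx.single_host_optimum(h):.2f}")
v0 = cx.joint_optimum(system)
print(f"joint optimum across all three hosts: v = {v0:.3f}")
# Intermediate virulence, optimal in none of the hosts, pulled towards the
# rodent's optimum because rodents contribute most new infections.

for lost in ("rodent", "primate"):
    res = cx.extinction_response(system, {lost})
    print(f"  lose {lost:9s}: v {res['v_before']:.3f} -> "
          f"{res['v_after']:.3f} ({res['direction']})")
# Losing the low-optimum rodent host selects for higher virulence in the
# survivors; losing the rare high-optimum primate host barely matters.
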