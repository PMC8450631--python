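"""Host specificity (MPD) and the four outcomes of losing a single host.

A parasite's phylogenetic host specificity is the mean pairwise patristic
distance (MPD, Myr) among its documented hosts.  Losing one host can kill
the parasite outright, reduce it to a single host, or push MPD either way.
"""

import coextinct as cx

tree, net, expected = cx.fixture_fig1()
print("tree:", tree.to_newick())
for panel, (parasite, lost, outcome) in sorted(expected.items()):
    before = net.mpd(parasite, tree)
    labels = cx.classify_outcome(net, tree, lost)
    try:
        after = net.mpd(parasite, tree, net.hosts - {lost})
        after_s = f"{after:.2f}"
    except cx.CoextinctError:
        after_s = "--"
    print(
        f"  {parasite:9s} loses {lost}: MPD {before:.2f} -> {after_s} Myr "
        f"=> {labels[parasite]}"
    )
# P_spec loses its distant host C and looks more specialized (14/3 -> 2);
# P_gen loses a close host B and looks more generalist (14/3 -> 6), though
# neither parasite gained or lost any ability to infect.
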