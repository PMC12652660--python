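"""Topology of the packaged Arabidopsis floral regulatory network.

Loads the curated activation edges among the floral MADS-box and timing
genes and reports per-node degrees (self-loops counted toward out-degree),
clustering coefficients and autoregulation flags.
"""

import promotif as pm

net = pm.load_floral_network()
print(f"{len(net.nodes)} genes, {len(net.edges)} directed edges, "
      f"self-loops: {sorted(net.self_loops())}")

metrics = pm.degree_metrics(net, selfloop_policy="out_only")
print("\nper-gene topology (sorted by out-degree):")
print(metrics.sort_values("out_degree", ascending=False).round(3).to_string())

# SEP3 is the top hub: it feeds SEP1/SEP2/SEP4/AG plus itself (out-degree 5)
# and is fed back by the four partners (in-degree 4).  Clustering reflects
# how interconnected each gene's neighbourhood is in the undirected view.
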