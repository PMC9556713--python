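"""Detect symptom clusters with Walktrap and rank symptoms by centrality.

The chosen partition maximizes modularity over the merge dendrogram; the
centrality table orders symptoms by strength (total absolute edge weight),
the index that tracks how much a symptom co-varies with the rest.
"""

import symptomnet as sn

model = sn.make_planted_model(10, 3, 1.5, 0.0, (-3.0, -1.0), seed=1)
X = sn.gibbs_sample(model, 1000, seed=2)
net = sn.estimate_network(X)

part = sn.walktrap(net, t=4)
q = part.modularity_per_cut[part.chosen_cut]
print(f"{part.n_communities} communities at modularity Q={q:.3f}")
for cid, members in sorted(part.members().items()):
    true = {model.true_communities[m] for m in members}
    print(f"  community {cid}: {members} (planted cluster(s) {sorted(true)})")

table = sn.centrality_table(net)
print("\ncentrality indices (ordered by strength):")
print(table.round(3))
print("\nNaN closeness marks symptoms that cannot reach every other symptom "
      "(the network is disconnected).")
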