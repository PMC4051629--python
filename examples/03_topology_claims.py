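"""Check verbal topology claims against the optimal cladogram.

The published discussion of this dataset makes four machine-checkable
claims about the tree; each is evaluated as a clade query on the
outgroup-rooted optimum.
"""

import parsclad as pc

matrix = pc.load_bundled_matrix()
result = pc.branch_and_bound(matrix)
(tree,) = result.best_trees_collapsed

descriptions = [
    "cordata subgroup (neocordata) is the most basal ingroup lineage",
    "dacunhai and milleri are sister taxa",
    "parasaltans is sister to the saltans subgroup clade",
    "prosaltans+austrosaltans are closer to each other than to saltans",
]
verdicts = pc.check_topology_statements(tree, pc.SALTANS_CLAIMS,
                                        outgroup="willistoni")
for text, ok in zip(descriptions, verdicts):
    print(f"  [{'ok' if ok else 'VIOLATED'}] {text}")

# A deliberately false claim for contrast:
claim = pc.TopologyStatement("sister-taxa", ("sturtevanti", "emarginata"))
(ok,) = pc.check_topology_statements(tree, [claim], outgroup="willistoni")
print(f"  [{'ok' if ok else 'false, as expected'}] "
      "sturtevanti and emarginata are sister taxa")
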