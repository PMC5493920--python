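"""From a raw weighted edge list to ordinal categories.

Contact counts are binned into M=3 equal-frequency intensity categories
(low / medium / high), pooled over all time steps so a category means the
same thing at every step; zeros (no edge) stay zero.
"""

import tempfile

import numpy as np

from dynsbm import bin_weights, read_edge_list

edge_lines = """\
1\tant_a\tant_b\t12
1\tant_a\tant_c\t3
1\tant_b\tant_c\t55
2\tant_a\tant_b\t7
2\tant_b\tant_c\t30
2\tant_a\tant_d\t1
"""

with tempfile.NamedTemporaryFile("w", suffix=".tsv", delete=False) as fh:
    fh.write(edge_lines)
    path = fh.name

raw = read_edge_list(path, n_steps=2)
net = bin_weights(raw, m=3)
print("raw weights (pooled):", sorted(raw.values[raw.values > 0].tolist()))
for t in range(2):
    for i in range(net.n_nodes):
        for j in range(i + 1, net.n_nodes):
            if net.values[t, i, j]:
                print(f"t={t + 1} {raw.node_labels[i]}-{raw.node_labels[j]}: "
                      f"weight {raw.values[t, i, j]:.0f} -> "
                      f"category {net.values[t, i, j]}")
# Each third of the pooled positive weights lands in one category; ties at a
# quantile threshold fall into the lower bin.
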