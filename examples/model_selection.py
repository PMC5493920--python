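"""Choose the number of groups with ICL and the elbow heuristic.

Networks are simulated with Q=3 planted groups (dense within, sparse
between); a scan over Q=1..5 should point back at 3 by both criteria.
"""

import numpy as np

from dynsbm import FitSettings, community_params, scan_q, simulate

params = community_params(q=3, n_steps=10, beta_within=0.4,
                          beta_between=0.05, pi_stay=0.9)
net, _ = simulate(params, np.ones((100, 10), dtype=bool), seed=21)

scan = scan_q(net, q_min=1, q_max=5, settings=FitSettings(n_init=3,
                                                          max_iter=50),
              seed=0)
print(scan.to_frame().to_string(index=False))
print(f"ICL selects Q={scan.best_q_icl}; elbow selects Q={scan.best_q_elbow}")
# The ELBO keeps creeping up with Q (more parameters always fit better);
# ICL's penalty and the elbow's curvature rule both stop at the planted 3.
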