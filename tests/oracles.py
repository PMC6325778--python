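"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results from first principles — exhaustive
enumeration and closed-form combinatorics — without calling the package's
own search or scipy's tests, so each check has two independent routes.
"""

from itertools import combinations
from math import comb


# ---------------------------------------------------------------------------
# parsimony: enumerate every rooted leaf-labeled binary topology and score
# each character by exhaustive minimization over internal state assignments
# ---------------------------------------------------------------------------

def all_rooted_topologies(leaves):
    """Every rooted binary leaf-labeled topology over the given leaf names."""
    leaves = list(leaves)
    if len(leaves) == 1:
        return [leaves[0]]
    first, rest = leaves[0], leaves[1:]
    out = []
    # the clade containing `first` at the root's left; enumerate bipartitions
    for k in range(0, len(rest) + 1):
        for left_rest in combinations(rest, k):
            right = [x for x in rest if x not in left_rest]
            if not right:
                continue
            for lt in all_rooted_topologies([first, *left_rest]):
                for rt in all_rooted_topologies(right):
                    out.append((lt, rt))
    return out


def min_changes(topology, states, root_state=0):
    """Minimum state changes for one binary character on a rooted topology,
    with the root (germline) fixed; plain recursion over both child states."""

    def cost(node, state):
        if not isinstance(node, tuple):
            return 0 if states[node] == state else float("inf")
        best = float("inf")
        for s_left in (0, 1):
            for s_right in (0, 1):
                c = (cost(node[0], s_left) + (s_left != state)
                     + cost(node[1], s_right) + (s_right != state))
                best = min(best, c)
        return best

    # the topology hangs below the germline root by the trunk edge
    return min(cost(topology, s) + (s != root_state) for s in (0, 1))


def brute_force_parsimony(presence_rows, region_names):
    """Best parsimony score over all rooted topologies for a binary matrix."""
    states_list = [dict(zip(region_names, row)) for row in presence_rows]
    best = None
    for topology in all_rooted_topologies(region_names):
        score = sum(min_changes(topology, states) for states in states_list)
        if best is None or score < best:
            best = score
    return best


# ---------------------------------------------------------------------------
# exact tests by direct enumeration
# ---------------------------------------------------------------------------

def binomial_two_sided(k, n, p0=0.5):
    """Sum of point probabilities not exceeding the observed one."""
    probs = [comb(n, i) * p0 ** i * (1 - p0) ** (n - i) for i in range(n + 1)]
    obs = probs[k]
    return min(1.0, sum(p for p in probs if p <= obs * (1 + 1e-12)))


def fisher_two_sided(a, b, c, d):
    """Fisher's exact test on [[a, b], [c, d]] by hypergeometric enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def table_prob(x):
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    lo, hi = max(0, c1 - r2), min(r1, c1)
    obs = table_prob(a)
    return min(1.0, sum(table_prob(x) for x in range(lo, hi + 1)
                        if table_prob(x) <= obs * (1 + 1e-12)))


def mannwhitney_two_sided(x, y):
    """Exact two-sided Mann-Whitney p by enumerating all label assignments
    (no ties): symmetric tail count of |U - n1*n2/2|."""
    pooled = list(x) + list(y)
    n1 = len(x)
    mid = n1 * (len(pooled) - n1) / 2.0

    def u_of(group):
        rest = [v for i, v in enumerate(pooled) if i not in group]
        return sum(1 for i in group for v in rest if pooled[i] > v)

    u_obs = sum(1 for a in x for b in y if a > b)
    total = extreme = 0
    for group in combinations(range(len(pooled)), n1):
        total += 1
        if abs(u_of(group) - mid) >= abs(u_obs - mid) - 1e-12:
            extreme += 1
    return extreme / total
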