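"""Independent brute-force reference implementations used by oracle tests.

Deliberately plain-Python and structurally unrelated to the package's
vectorized scoring path.
"""


def oracle_edge_score(c1, c2, w1, w2):
    """Two-branch edge score, written out longhand."""
    if c1 < 0 or c2 < 0:
        total = 0
        if c1 < 0:
            total += c1 * w1
        if c2 < 0:
            total += c2 * w2
        return total
    return c1 * w1 + c2 * w2


def oracle_module_score(edges, gds, calls):
    """Explicit re-summation over an enumerated edge list."""
    total = 0
    for a, b in edges:
        total += oracle_edge_score(calls.get(a, 0), calls.get(b, 0), gds[a], gds[b])
    return total


def oracle_min_score(edges, gds):
    """Module score when every node is monoallelically lost."""
    return oracle_module_score(edges, gds, {g: -1 for e in edges for g in e})
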