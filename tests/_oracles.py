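"""Independent brute-force oracles used to cross-check the implementation.

These deliberately share no code with the package: the hypergeometric
tail is accumulated from the *lower* side in exact rational arithmetic,
and the running-sum recomputation walks the ranking one gene at a time
in plain Python.
"""

from fractions import Fraction
from math import comb


def hypergeom_upper_tail_exact(k: int, n: int, K: int, N: int) -> Fraction:
    """P(X >= k) as an exact rational, via the complement of the lower tail."""
    lower = sum(comb(K, i) * comb(N - K, n - i) for i in range(0, k))
    return 1 - Fraction(lower, comb(N, n))


def hypergeom_upper_tails_sweep(n: int, K: int, N: int) -> list[Fraction]:
    """P(X >= k) for every k in 0..min(n, K), lower-side accumulation."""
    hi = min(n, K)
    denom = comb(N, n)
    tails = []
    lower = 0
    for k in range(hi + 1):
        tails.append(1 - Fraction(lower, denom))
        lower += comb(K, k) * comb(N - K, n - k)
    return tails


def running_sum_es(genes, scores, members, w=1.0):
    """Straight-line recomputation of the weighted running-sum ES.

    ``genes``/``scores`` must already be in ranking order.  Returns the
    signed maximum deviation, preferring the positive extremum on an
    exact magnitude tie.
    """
    n = len(genes)
    hits = [g in members for g in genes]
    n_hit = sum(hits)
    assert 0 < n_hit < n
    nr = 0.0
    for s, h in zip(scores, hits):
        if h:
            nr += abs(s) ** w
    cur = 0.0
    best = 0.0
    for s, h in zip(scores, hits):
        if h:
            cur += abs(s) ** w / nr
        else:
            cur -= 1.0 / (n - n_hit)
        if abs(cur) > abs(best) or (abs(cur) == abs(best) and cur > best):
            best = cur
    return best


def membership_signatures(named_sets):
    """Per-gene membership vectors by direct enumeration."""
    union = set()
    for _, genes in named_sets:
        union |= set(genes)
    out = {}
    for gene in union:
        sig = "".join("1" if gene in genes else "0" for _, genes in named_sets)
        out.setdefault(sig, set()).add(gene)
    return out


def connected_components_bruteforce(edges):
    """Components by repeated set merging (no graph library)."""
    comps: list[set] = []
    nodes = set()
    for a, b in edges:
        nodes |= {a, b}
        hit = [c for c in comps if a in c or b in c]
        merged = {a, b}
        for c in hit:
            merged |= c
            comps.remove(c)
        comps.append(merged)
    return sorted(frozenset(c) for c in comps)
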