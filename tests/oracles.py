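"""Independent reference implementations used as test oracles.

These deliberately share no code with the package: a plain-Python affine-gap
Smith-Waterman scorer, an exact-string tandem copy counter, and a linear-scan
restriction-site finder.
"""

from __future__ import annotations


def sw_affine_score(a: str, b: str, match: float = 1.0, mismatch: float = -1.0,
                    gap_open: float = -2.0, gap_extend: float = -1.0) -> float:
    """Best local alignment score; a gap of length L costs open + L*extend."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    prev_h = [0.0] * (m + 1)
    prev_e = [NEG] * (m + 1)
    best = 0.0
    for i in range(1, n + 1):
        cur_h = [0.0] * (m + 1)
        cur_e = [NEG] * (m + 1)
        f = NEG
        for j in range(1, m + 1):
            e = max(prev_h[j] + gap_open + gap_extend, prev_e[j] + gap_extend)
            f = max(cur_h[j - 1] + gap_open + gap_extend, f + gap_extend)
            s = match if a[i - 1] == b[j - 1] else mismatch
            h = max(0.0, prev_h[j - 1] + s, e, f)
            cur_h[j] = h
            cur_e[j] = e
            if h > best:
                best = h
        prev_h, prev_e = cur_h, cur_e
    return best


def exact_copy_count(seq: str, unit: str) -> int:
    """Non-overlapping verbatim occurrences of the unit."""
    count = start = 0
    while True:
        i = seq.find(unit, start)
        if i < 0:
            return count
        count += 1
        start = i + len(unit)


def site_positions(seq: str, site: str) -> list[int]:
    """All (possibly overlapping) occurrences of a restriction site."""
    out, i = [], seq.find(site)
    while i >= 0:
        out.append(i)
        i = seq.find(site, i + 1)
    return out


def best_chain_score(candidates, switch_penalty: float) -> float:
    """Exhaustive maximum chained score over <= ~15 candidate alignments.

    Candidates are (query_start, query_end, ref_id, score) tuples; chains
    must be query-disjoint and ascending, each reference switch costs
    switch_penalty.
    """
    from itertools import combinations, permutations
    n = len(candidates)
    best = 0.0
    for k in range(1, n + 1):
        for combo in combinations(range(n), k):
            cs = sorted((candidates[i] for i in combo), key=lambda c: c[0])
            if any(cs[i][1] > cs[i + 1][0] for i in range(len(cs) - 1)):
                continue
            total = sum(c[3] for c in cs)
            total -= switch_penalty * sum(
                1 for i in range(len(cs) - 1) if cs[i][2] != cs[i + 1][2])
            best = max(best, total)
    return best
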