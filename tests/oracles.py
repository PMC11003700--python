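"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately naive: per-base accumulation, all-pairs
graph construction, exhaustive scans. These functions never share code
with the package paths they check.
"""

from __future__ import annotations

import numpy as np


def naive_matrix(steps_by_chrom, anchors, flank, bin_size):
    """Per-base accumulation oracle for the binned signal matrix.

    ``steps_by_chrom``: chrom -> list of (start, end, value);
    ``anchors``: list of (chrom, anchor position).
    """
    n_bins = 2 * flank // bin_size
    out = np.zeros((len(anchors), n_bins))
    for row, (chrom, anchor) in enumerate(anchors):
        base_values = {}
        for start, end, value in steps_by_chrom.get(chrom, []):
            for pos in range(int(start), int(end)):
                base_values[pos] = base_values.get(pos, 0.0) + value
        for b in range(n_bins):
            lo = anchor - flank + b * bin_size
            total = sum(base_values.get(pos, 0.0) for pos in range(lo, lo + bin_size))
            out[row, b] = total / bin_size
    return out


def naive_center_score(matrix_values, bin_size, flank, window):
    """Direct summation over bins within +-window of the anchor."""
    n_bins = matrix_values.shape[1]
    mid = n_bins // 2
    half = window // bin_size
    return np.array([row[mid - half: mid + half].sum() for row in matrix_values])


def brute_overlap_components(intervals_a, intervals_b, min_bp=1):
    """All-pairs bipartite graph + breadth-first components.

    Intervals are (chrom, start, end). Returns a list of
    (set of A indices, set of B indices) for every component holding at
    least one edge, plus the min-count.
    """
    n_a, n_b = len(intervals_a), len(intervals_b)
    adj = {("A", i): set() for i in range(n_a)}
    adj.update({("B", j): set() for j in range(n_b)})
    for i, (ca, sa, ea) in enumerate(intervals_a):
        for j, (cb, sb, eb) in enumerate(intervals_b):
            if ca == cb and min(ea, eb) - max(sa, sb) >= min_bp:
                adj[("A", i)].add(("B", j))
                adj[("B", j)].add(("A", i))
    seen = set()
    components = []
    for node in list(adj):
        if node in seen or not adj[node]:
            continue
        queue, comp = [node], set()
        while queue:
            cur = queue.pop()
            if cur in comp:
                continue
            comp.add(cur)
            queue.extend(adj[cur] - comp)
        seen |= comp
        side_a = {i for (s, i) in comp if s == "A"}
        side_b = {j for (s, j) in comp if s == "B"}
        components.append((side_a, side_b))
    n_min = sum(min(len(a), len(b)) for a, b in components)
    return components, n_min


def brute_distal_filter(anchors, tss_positions, exclusion):
    """Min-distance scan: keep anchors farther than exclusion from all TSSs."""
    kept = []
    for idx, (chrom, anchor) in enumerate(anchors):
        tss_here = [t for (c, t) in tss_positions if c == chrom]
        if not tss_here or min(abs(anchor - t) for t in tss_here) > exclusion:
            kept.append(idx)
    return kept


def brute_stitch(intervals, stitch_distance):
    """Chain sorted intervals per chromosome; returns lists of index groups."""
    by_chrom = {}
    for idx, (chrom, start, end) in enumerate(intervals):
        by_chrom.setdefault(chrom, []).append((start, end, idx))
    groups = []
    for chrom in sorted(by_chrom):
        items = sorted(by_chrom[chrom])
        current, span_end = [], None
        for start, end, idx in items:
            if current and start - span_end <= stitch_distance:
                current.append(idx)
                span_end = max(span_end, end)
            else:
                if current:
                    groups.append(current)
                current, span_end = [idx], end
        if current:
            groups.append(current)
    return groups


def brute_call_supers(signals):
    """Exhaustive scaled finite-difference scan for the super cutoff.

    Returns (is_super boolean list aligned to signal-ascending order,
    cutoff or nan).
    """
    order = sorted(range(len(signals)), key=lambda i: signals[i])
    s = [signals[i] for i in order]
    n = len(s)
    if n < 2 or s[-1] == s[0]:
        return [False] * n, float("nan")
    x = [i / (n - 1) for i in range(n)]
    y = [(v - s[0]) / (s[-1] - s[0]) for v in s]
    slopes = []
    for i in range(n):
        if i == 0:
            slopes.append((y[1] - y[0]) / (x[1] - x[0]))
        elif i == n - 1:
            slopes.append((y[-1] - y[-2]) / (x[-1] - x[-2]))
        else:
            slopes.append((y[i + 1] - y[i - 1]) / (x[i + 1] - x[i - 1]))
    cutoff = float("nan")
    for i in range(n - 1, -1, -1):  # scan from the top rank downward
        if slopes[i] > 1.0:
            cutoff = s[i]
            break
    if cutoff != cutoff:  # nan
        return [False] * n, cutoff
    return [v >= cutoff for v in s], cutoff
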