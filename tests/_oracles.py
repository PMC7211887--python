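"""Independent brute-force oracles used by the test suite.

Everything here is written in plain Python loops, independent of the
package's vectorised implementations, so tests compare two genuinely
different routes to the same quantity.
"""

from __future__ import annotations


def brute_wss(
    calls_a: dict[int, str],
    calls_b: dict[int, str],
    depth_a,
    depth_b,
    window_size: int = 1000,
    min_breadth: float = 0.30,
    min_mean_depth: float = 3.5,
    window_min_depth: int = 5,
    max_low_fraction: float = 0.5,
):
    """Position-by-position WSS re-implementation (no vector shortcuts).

    Returns the 0-100 score, or None when sample QC fails or no window
    survives.
    """
    L = len(depth_a)
    assert len(depth_b) == L

    def breadth(d):
        return sum(1 for x in d if x >= 1) / L

    def mean_depth(d):
        return sum(int(x) for x in d) / L

    if breadth(depth_a) < min_breadth or breadth(depth_b) < min_breadth:
        return None
    if mean_depth(depth_a) < min_mean_depth or mean_depth(depth_b) < min_mean_depth:
        return None

    sims = []
    start = 0
    while start < L:
        end = min(start + window_size, L)
        wlen = end - start
        low_a = sum(1 for p in range(start, end) if depth_a[p] < window_min_depth)
        low_b = sum(1 for p in range(start, end) if depth_b[p] < window_min_depth)
        if low_a > max_low_fraction * wlen or low_b > max_low_fraction * wlen:
            start = end
            continue
        union = 0
        concordant = 0
        for pos in range(start + 1, end + 1):  # 1-based
            ca = calls_a.get(pos)
            cb = calls_b.get(pos)
            if ca is None and cb is None:
                continue
            union += 1
            if ca is not None and ca == cb:
                concordant += 1
        sims.append(concordant / union if union else 1.0)
        start = end
    if not sims:
        return None
    return 100.0 * sum(sims) / len(sims)


def naive_bray_curtis(x, y):
    num = sum(abs(a - b) for a, b in zip(x, y))
    den = sum(a + b for a, b in zip(x, y))
    return num / den


def naive_upgma_heights(d):
    """Merge heights (distance/2) of average-linkage clustering.

    ``d`` is a full square matrix (list of lists).  Cluster pairs are
    chosen by minimum average distance; returns the sorted list of
    ultrametric merge heights.
    """
    clusters = [[i] for i in range(len(d))]
    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                dist = sum(d[a][b] for a in clusters[i] for b in clusters[j]) / (
                    len(clusters[i]) * len(clusters[j])
                )
                if best is None or dist < best[0]:
                    best = (dist, i, j)
        dist, i, j = best
        heights.append(dist / 2.0)
        merged = clusters[i] + clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return sorted(heights)


def mother_infant_pattern_oracle(vec):
    """Count-based re-derivation of the time-point pattern table."""
    informative = [c for c in vec if c != "no_call"]
    n_rel = sum(1 for c in informative if c == "related")
    n_unrel = sum(1 for c in informative if c == "unrelated")
    if n_rel + n_unrel == 0:
        return "insufficient_data"
    if n_unrel == 0:
        return "shared_all_timepoints"
    if n_rel == 0:
        return "never_shared"
    return "mixed_timepoints"


# Explicit 27-entry decision table for (donor_f1, dam_f1, donor_dam),
# states R(elated)/U(nrelated)/N(o call), derived by hand from the four
# engraftment patterns plus the all-unrelated / insufficient rules.
_R, _U, _N = "related", "unrelated", "no_call"
FMT_TABLE = {}
for _df in (_R, _U, _N):
    for _mf in (_R, _U, _N):
        for _dm in (_R, _U, _N):
            if _df == _R and _mf == _R:
                pat = "donor_and_dam_related"
            elif _mf == _R:
                pat = "dam_only_related"
            elif _df == _R:
                pat = "donor_only_related"
            else:
                avail = [c for c in (_df, _mf, _dm) if c != _N]
                pat = (
                    "all_unrelated"
                    if avail and all(c == _U for c in avail)
                    else "insufficient_data"
                )
            FMT_TABLE[(_df, _mf, _dm)] = pat

# spot-checked entries of the hand table
assert FMT_TABLE[("related", "related", "related")] == "donor_and_dam_related"
assert FMT_TABLE[("no_call", "related", "no_call")] == "dam_only_related"
assert FMT_TABLE[("related", "no_call", "no_call")] == "donor_only_related"
assert FMT_TABLE[("unrelated", "unrelated", "unrelated")] == "all_unrelated"
assert FMT_TABLE[("unrelated", "unrelated", "related")] == "insufficient_data"
assert FMT_TABLE[("no_call", "no_call", "no_call")] == "insufficient_data"
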