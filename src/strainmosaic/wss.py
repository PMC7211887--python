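"""Window-based SNV similarity (WSS) scoring.

The WSS score compares the consensus SNV profiles of two samples
against one species' reference genome.  The reference is tiled into
non-overlapping windows (1000 bp by default; the terminal window may
be partial).  Within each window, the variant sites called in either
sample form the union; sites where both samples carry the identical
call are concordant; window similarity is concordant/union, with
windows containing no variant site in either sample counting as fully
similar (two samples that both match the reference are
indistinguishable there).  The score is 100 times the unweighted mean
similarity over retained windows.

Two QC gates precede scoring.  A sample pair is only scored when both
samples have breadth of coverage >= 30% and mean depth >= 3.5 over the
whole reference.  A window is ignored when, in either sample, more
than 50% of its bases have depth below 5 (exactly 50% retains the
window).

A scored pair is called related when its score strictly exceeds the
species' calibrated cut-off and unrelated when it falls below; a score
exactly at the cut-off is called unrelated (the calls are defined by
strict inequalities on both sides).  Species without a cut-off yield
no call.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import DepthTrack, SNVProfile

DEFAULT_WINDOW_SIZE = 1000
DEFAULT_MIN_BREADTH = 0.30
DEFAULT_MIN_MEAN_DEPTH = 3.5
DEFAULT_WINDOW_MIN_DEPTH = 5
DEFAULT_WINDOW_MAX_LOW_FRACTION = 0.5


@dataclass(frozen=True)
class Window:
    species_id: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    index: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class WindowSimilarity:
    window: Window
    n_union_sites: int
    n_concordant_sites: int
    similarity: float
    retained: bool
    low_depth_bases_a: int
    low_depth_bases_b: int


@dataclass
class PairQC:
    breadth_a: float
    breadth_b: float
    mean_depth_a: float
    mean_depth_b: float
    passed: bool
    reason: str = ""


@dataclass
class WSSResult:
    species_id: str
    sample_a: str
    sample_b: str
    score: float | None
    n_windows_total: int
    n_windows_retained: int
    qc: PairQC
    call: str = "no_call"
    cutoff_used: float | None = None
    window_similarities: list[WindowSimilarity] | None = None


@dataclass(frozen=True)
class WSSParams:
    """Tunable parameters of the WSS computation.

    ``empty_union_policy`` controls windows whose retained depth is
    fine but where neither sample calls a variant: "one" scores them
    1.0 (default), "drop" excludes them from the mean.  The similarity
    normalisation is the one genuinely open choice in the method and
    is isolated here so both variants stay testable.
    """

    window_size: int = DEFAULT_WINDOW_SIZE
    min_breadth: float = DEFAULT_MIN_BREADTH
    min_mean_depth: float = DEFAULT_MIN_MEAN_DEPTH
    window_min_depth: int = DEFAULT_WINDOW_MIN_DEPTH
    window_max_low_fraction: float = DEFAULT_WINDOW_MAX_LOW_FRACTION
    empty_union_policy: str = "one"  # "one" | "drop"

    def __post_init__(self) -> None:
        if self.window_size < 1:
            raise ValueError("window_size must be positive")
        if self.empty_union_policy not in {"one", "drop"}:
            raise ValueError("empty_union_policy must be 'one' or 'drop'")


def make_windows(
    reference_length: int, window_size: int = DEFAULT_WINDOW_SIZE, species_id: str = ""
) -> list[Window]:
    """Tile the reference into non-overlapping windows.

    Produces ceil(length/window_size) windows covering every position
    exactly once; the last window may be shorter than window_size.
    """
    if reference_length < 1:
        raise ValueError("reference_length must be positive")
    if window_size < 1:
        raise ValueError("window_size must be positive")
    windows = []
    for i, start in enumerate(range(0, reference_length, window_size)):
        windows.append(
            Window(species_id, start, min(start + window_size, reference_length), i)
        )
    return windows


def pair_qc(
    depth_a: DepthTrack,
    depth_b: DepthTrack,
    min_breadth: float = DEFAULT_MIN_BREADTH,
    min_mean_depth: float = DEFAULT_MIN_MEAN_DEPTH,
) -> PairQC:
    """Sample-pair QC on breadth of coverage and mean depth.

    Both samples must reach breadth >= min_breadth (fraction of
    reference positions with depth >= 1) and mean depth >=
    min_mean_depth computed over the whole reference.  The thresholds
    themselves pass; a pair failing either bound in either sample is
    excluded.
    """
    if depth_a.length != depth_b.length:
        raise ValueError("depth tracks have different lengths")
    ba, bb = depth_a.breadth, depth_b.breadth
    ma, mb = depth_a.mean_depth, depth_b.mean_depth
    reasons = []
    if ba < min_breadth or bb < min_breadth:
        reasons.append("coverage")
    if ma < min_mean_depth or mb < min_mean_depth:
        reasons.append("depth")
    return PairQC(ba, bb, ma, mb, passed=not reasons, reason=",".join(reasons))


def window_retained(
    window: Window,
    depth_a: DepthTrack,
    depth_b: DepthTrack,
    min_depth: int = DEFAULT_WINDOW_MIN_DEPTH,
    max_low_fraction: float = DEFAULT_WINDOW_MAX_LOW_FRACTION,
) -> tuple[bool, int, int]:
    """Window depth QC; returns (retained, low_bases_a, low_bases_b).

    The window is dropped when, in either sample, strictly more than
    ``max_low_fraction`` of its bases have depth below ``min_depth``.
    A window unusable in one sample cannot support a pairwise
    comparison, hence the either-sample rule.
    """
    sl = slice(window.start, window.end)
    low_a = int((depth_a.depth[sl] < min_depth).sum())
    low_b = int((depth_b.depth[sl] < min_depth).sum())
    limit = max_low_fraction * window.length
    retained = not (low_a > limit or low_b > limit)
    return retained, low_a, low_b


def window_similarity(
    profile_a: SNVProfile, profile_b: SNVProfile, window: Window
) -> tuple[int, int, float]:
    """Concordant/union SNV similarity inside one window.

    Returns (n_union, n_concordant, similarity); an empty union gives
    similarity 1.0 (both samples are reference-identical there).
    """
    union = 0
    concordant = 0
    lo, hi = window.start + 1, window.end  # 1-based inclusive bounds
    a_calls, b_calls = profile_a.calls, profile_b.calls
    positions = {p for p in a_calls if lo <= p <= hi}
    positions |= {p for p in b_calls if lo <= p <= hi}
    for p in positions:
        union += 1
        if a_calls.get(p) is not None and a_calls.get(p) == b_calls.get(p):
            concordant += 1
    sim = concordant / union if union else 1.0
    return union, concordant, sim


def wss_score(
    profile_a: SNVProfile,
    profile_b: SNVProfile,
    depth_a: DepthTrack,
    depth_b: DepthTrack,
    windows: list[Window] | None = None,
    params: WSSParams = WSSParams(),
    keep_window_detail: bool = False,
) -> WSSResult:
    """Compute the WSS score of a sample pair for one species.

    The score is 100 times the unweighted mean of per-window
    similarities over retained windows, giving a 0-100 scale
    comparable across species.  Pairs failing sample QC, or retaining
    zero windows, get no score (call stays ``no_call``).  The score is
    exactly symmetric in the two samples.
    """
    if profile_a.species_id != profile_b.species_id:
        raise ValueError("profiles are for different species")
    if depth_a.length != depth_b.length:
        raise ValueError("depth tracks have different lengths")
    if windows is None:
        windows = make_windows(depth_a.length, params.window_size, profile_a.species_id)
    qc = pair_qc(depth_a, depth_b, params.min_breadth, params.min_mean_depth)
    if not qc.passed:
        return WSSResult(
            profile_a.species_id,
            profile_a.sample_id,
            profile_b.sample_id,
            None,
            len(windows),
            0,
            qc,
        )
    sims: list[float] = []
    detail: list[WindowSimilarity] = []
    n_retained = 0
    for w in windows:
        retained, low_a, low_b = window_retained(
            w, depth_a, depth_b, params.window_min_depth, params.window_max_low_fraction
        )
        union = concordant = 0
        sim = float("nan")
        if retained:
            n_retained += 1
            union, concordant, sim = window_similarity(profile_a, profile_b, w)
            if union > 0 or params.empty_union_policy == "one":
                sims.append(sim)
        if keep_window_detail:
            detail.append(
                WindowSimilarity(w, union, concordant, sim, retained, low_a, low_b)
            )
    score = 100.0 * float(np.mean(sims)) if sims else None
    return WSSResult(
        profile_a.species_id,
        profile_a.sample_id,
        profile_b.sample_id,
        score,
        len(windows),
        n_retained,
        qc,
        window_similarities=detail if keep_window_detail else None,
    )


def classify_pair(result: WSSResult, cutoff: float | None) -> WSSResult:
    """Attach a related/unrelated call by comparing score to cut-off.

    ``related`` iff score > cutoff (strictly); a score exactly at the
    cut-off is ``unrelated``.  Without a score or a cut-off the call
    stays ``no_call``.
    """
    if result.score is None or cutoff is None:
        return replace(result, call="no_call", cutoff_used=cutoff)
    call = "related" if result.score > cutoff else "unrelated"
    return replace(result, call=call, cutoff_used=cutoff)
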