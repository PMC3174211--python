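"""Sliding-window peak calling for tiling-array ChIP-chip log-ratio tracks.

The detector scores one candidate window per probe with a robust
T-statistic, estimates an empirical null by mirroring the negative tail of
the score distribution, merges significant windows separated by less than a
gap ``g``, unions calls across the two ChIP comparisons ("either" rule),
and estimates an FDR by re-running the identical pipeline on the
IgG-vs-input control hybridization.

All coordinates are 0-based half-open.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

# Competitive-hybridization comparison identifiers.
CHIP_VS_IGG = "chip_vs_igg"
CHIP_VS_INPUT = "chip_vs_input"
IGG_VS_INPUT = "igg_vs_input"
CHANNELS = (CHIP_VS_IGG, CHIP_VS_INPUT, IGG_VS_INPUT)
CHIP_CHANNELS = (CHIP_VS_IGG, CHIP_VS_INPUT)


@dataclass
class ProbeTrack:
    """Ordered probe measurements for one hybridization comparison.

    ``values[i]`` is the log-ratio intensity x_i of the probe spanning
    ``[starts[i], ends[i])`` on ``chrom``.
    """

    chrom: str
    starts: np.ndarray
    ends: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if not (len(self.starts) == len(self.ends) == len(self.values)):
            raise ValueError("starts, ends and values must have equal length")
        if np.any(self.ends <= self.starts):
            raise ValueError("every probe must satisfy end > start")
        if np.any(np.diff(self.starts) <= 0):
            raise ValueError("probe starts must be strictly increasing")

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def midpoints(self) -> np.ndarray:
        return (self.starts + self.ends) // 2


@dataclass
class PeakCallParams:
    """Detector parameters; defaults are the published operating point
    (window 400 nt, gap 100 nt, p < 1e-4)."""

    w: int = 400
    g: int = 100
    alpha: float = 1e-4
    trim_fraction: float = 0.10
    min_probes: int = 5

    def __post_init__(self) -> None:
        if self.w <= 0:
            raise ValueError("window size w must be positive")
        if self.g < 0:
            raise ValueError("gap size g must be non-negative")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 <= self.trim_fraction < 0.5:
            raise ValueError("trim_fraction must lie in [0, 0.5)")
        if self.min_probes < 1:
            raise ValueError("min_probes must be >= 1")


@dataclass
class WindowScores:
    """Per-window score table (one candidate window per retained probe)."""

    centers: np.ndarray   # window center = anchoring probe midpoint
    starts: np.ndarray    # window span start
    ends: np.ndarray      # window span end
    n: np.ndarray         # probes per window
    t: np.ndarray         # T = sqrt(n) * trimmed mean

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class NullModel:
    """Empirical null from the mirrored negative score tail.

    ``magnitudes``: sorted |T| of all windows with T < 0; ``m``: total
    window count. ``degenerate`` marks the no-negative-scores case, where
    every p-value floors at 1/(m+1).
    """

    magnitudes: np.ndarray
    m: int
    degenerate: bool = False


@dataclass
class ChIPRegion:
    """A merged run of significant windows."""

    chrom: str
    start: int
    end: int
    best_t: float
    p_value: float
    sources: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("region must satisfy end > start")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "ChIPRegion") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


def trimmed_mean(x: np.ndarray, trim_fraction: float) -> float:
    """Mean after dropping floor(trim_fraction*n) smallest and largest values."""
    x = np.sort(np.asarray(x, dtype=np.float64))
    k = int(math.floor(trim_fraction * len(x)))
    if 2 * k >= len(x):
        k = (len(x) - 1) // 2
    return float(np.mean(x[k:len(x) - k] if k else x))


def compute_window_scores(track: ProbeTrack, params: PeakCallParams) -> WindowScores:
    """Score one candidate window per probe.

    The window anchored on probe i spans ``[mid_i - w/2, mid_i + w/2)``;
    probes belong to a window when their midpoint falls inside the span.
    Windows with fewer than ``min_probes`` probes are dropped.
    T = sqrt(n) * trimmed mean of the n member log-ratios.
    """
    if len(track) == 0:
        logger.info("empty probe track: no windows scored")
        z = np.empty(0)
        return WindowScores(z.astype(np.int64), z.astype(np.int64), z.astype(np.int64),
                            z.astype(np.int64), z)

    mids = track.midpoints
    half = params.w // 2
    win_start = mids - half
    win_end = mids + half
    left = np.searchsorted(mids, win_start, side="left")
    right = np.searchsorted(mids, win_end, side="left")
    n = right - left
    keep = n >= params.min_probes
    left, right, n = left[keep], right[keep], n[keep]
    centers = mids[keep]

    t = np.empty(len(n), dtype=np.float64)
    # Vectorize by grouping windows with equal probe count: gather each
    # group into a dense matrix, sort rows, trim, average.
    vals = track.values
    for size in np.unique(n):
        idx = np.nonzero(n == size)[0]
        mat = vals[left[idx][:, None] + np.arange(size)[None, :]]
        mat = np.sort(mat, axis=1)
        k = int(math.floor(params.trim_fraction * size))
        if 2 * k >= size:
            k = (size - 1) // 2
        core = mat[:, k:size - k] if k else mat
        t[idx] = math.sqrt(size) * core.mean(axis=1)

    return WindowScores(centers=centers, starts=win_start[keep], ends=win_end[keep], n=n, t=t)


def estimate_empirical_null(scores: WindowScores) -> NullModel:
    """Mirror the negative score tail into a null for positive scores."""
    if len(scores) == 0:
        raise ValueError("cannot estimate a null from zero windows")
    neg = scores.t[scores.t < 0]
    if len(neg) == 0:
        logger.warning("degenerate empirical null: no negative window scores; "
                       "all p-values floor at 1/(M+1)")
        return NullModel(magnitudes=np.empty(0), m=len(scores), degenerate=True)
    return NullModel(magnitudes=np.sort(np.abs(neg)), m=len(scores))


def assign_pvalue(t, null: NullModel):
    """Empirical p-value with add-one correction.

    For T > 0: p = (1 + #{null magnitudes >= T}) / (1 + M); scores T <= 0
    get p = 1 (only enrichment is sought). Accepts a scalar or array.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=np.float64))
    exceed = len(null.magnitudes) - np.searchsorted(null.magnitudes, t_arr, side="left")
    p = (1.0 + exceed) / (1.0 + null.m)
    p = np.where(t_arr > 0, p, 1.0)
    return float(p[0]) if np.isscalar(t) or np.ndim(t) == 0 else p


def merge_significant_windows(scores: WindowScores, null: NullModel,
                              params: PeakCallParams, chrom: str = "chr1",
                              sources: frozenset = frozenset()) -> list[ChIPRegion]:
    """Merge significant windows closer than the gap ``g`` into regions.

    A region's span is the union of its member windows, its score the best
    member T, and its p-value that of the best score.
    """
    p = assign_pvalue(scores.t, null) if len(scores) else np.empty(0)
    sig = np.nonzero(p < params.alpha)[0]
    if len(sig) == 0:
        return []
    order = sig[np.argsort(scores.starts[sig], kind="stable")]
    regions: list[ChIPRegion] = []
    cur_start = int(scores.starts[order[0]])
    cur_end = int(scores.ends[order[0]])
    cur_best = float(scores.t[order[0]])
    for i in order[1:]:
        s, e, ti = int(scores.starts[i]), int(scores.ends[i]), float(scores.t[i])
        if s - cur_end < params.g:
            cur_end = max(cur_end, e)
            cur_best = max(cur_best, ti)
        else:
            regions.append(ChIPRegion(chrom, cur_start, cur_end, cur_best,
                                      assign_pvalue(cur_best, null), sources))
            cur_start, cur_end, cur_best = s, e, ti
    regions.append(ChIPRegion(chrom, cur_start, cur_end, cur_best,
                              assign_pvalue(cur_best, null), sources))
    return regions


def call_regions_single(track: ProbeTrack, params: PeakCallParams,
                        source: str = "") -> list[ChIPRegion]:
    """Full single-track pipeline: score, null, merge."""
    scores = compute_window_scores(track, params)
    if len(scores) == 0:
        return []
    null = estimate_empirical_null(scores)
    src = frozenset({source}) if source else frozenset()
    return merge_significant_windows(scores, null, params, chrom=track.chrom, sources=src)


def _union_regions(regions: list[ChIPRegion]) -> list[ChIPRegion]:
    """Union regions overlapping by >= 1 bp; keep max T, min p, merged sources."""
    if not regions:
        return []
    regions = sorted(regions, key=lambda r: (r.chrom, r.start, r.end))
    out = [regions[0]]
    for r in regions[1:]:
        last = out[-1]
        if r.chrom == last.chrom and r.start < last.end:
            out[-1] = ChIPRegion(last.chrom, last.start, max(last.end, r.end),
                                 max(last.best_t, r.best_t),
                                 min(last.p_value, r.p_value),
                                 last.sources | r.sources)
        else:
            out.append(r)
    return out


def call_regions(tracks: dict[str, ProbeTrack], params: PeakCallParams) -> list[ChIPRegion]:
    """Call regions significant in either ChIP comparison.

    Regions are called independently for ChIP-vs-IgG and ChIP-vs-input,
    then unioned by coordinate overlap; each output region records which
    comparisons contributed and carries the smaller p-value.
    """
    present = [c for c in CHIP_CHANNELS if c in tracks]
    if not present:
        raise ValueError("need at least one ChIP comparison "
                         f"({CHIP_VS_IGG} or {CHIP_VS_INPUT})")
    per_channel: list[ChIPRegion] = []
    for channel in present:
        per_channel.extend(call_regions_single(tracks[channel], params, source=channel))
    return _union_regions(per_channel)


@dataclass
class FdrEstimate:
    fdr: float
    n_control_regions: int
    n_chip_regions: int
    defined: bool


def estimate_fdr_from_control(n_chip_regions: int, control_track: ProbeTrack,
                              params: PeakCallParams) -> FdrEstimate:
    """FDR = (# regions called on the IgG-vs-input control at identical
    parameters) / (# ChIP regions), clamped to [0, 1]."""
    if n_chip_regions < 0:
        raise ValueError("n_chip_regions must be >= 0")
    control_regions = call_regions_single(control_track, params, source=IGG_VS_INPUT)
    n_control = len(control_regions)
    if n_chip_regions == 0:
        return FdrEstimate(fdr=float("nan"), n_control_regions=n_control,
                           n_chip_regions=0, defined=False)
    return FdrEstimate(fdr=min(1.0, n_control / n_chip_regions),
                       n_control_regions=n_control,
                       n_chip_regions=n_chip_regions, defined=True)


def null_calibration(scores: WindowScores, null: NullModel,
                     alpha: float = 1e-4) -> tuple[float, float]:
    """Calibration diagnostics on a (presumed signal-free) track.

    Returns ``(fraction of windows with p < alpha, KS distance)``. Because
    the mirrored null is two-sided, positive-score p-values are uniform on
    (0, (1+N_neg)/(1+M)] under symmetric noise, not on (0, 1); the KS
    statistic is computed against that attainable range.
    """
    from scipy import stats as _stats

    p = assign_pvalue(scores.t, null)
    frac = float(np.mean(p < alpha))
    pos = p[scores.t > 0]
    pmax = (1 + len(null.magnitudes)) / (1 + null.m)
    d = float(_stats.kstest(pos / pmax, "uniform").statistic) if len(pos) else float("nan")
    return frac, d


def locate_element(sequence: str, pwm) -> tuple[int, bool]:
    """Locate the binding element inside a called region's sequence.

    Returns ``(offset, fallback)`` where ``offset`` is the start of the
    best-scoring motif hit on either strand (ties broken toward the
    smaller coordinate, '+' strand preferred on exact ties). When no
    position reaches the matrix threshold the region midpoint is returned
    with ``fallback=True``.
    """
    from .motifs import scan_all_scores

    if len(sequence) < pwm.width:
        raise ValueError("sequence shorter than the motif width")
    fwd, rev = scan_all_scores(sequence, pwm)
    best = np.maximum(fwd, rev)
    offset = int(np.argmax(best))  # argmax takes the leftmost maximum
    threshold = pwm.threshold if pwm.threshold is not None else -np.inf
    if best[offset] < threshold:
        return len(sequence) // 2, True
    return offset, False
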