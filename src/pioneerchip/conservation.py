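"""Evolutionary-conservation profiles around bound vs unbound sites.

A fixed-width window (2 kb by default) is extracted around each site
center from a per-base conservation track (PhastCons-style scores in
[0, 1]); per-offset means, per-site means and the grand mean summarize
each site set, and a site-level bootstrap interval quantifies the
bound-minus-unbound difference.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class ConservationTrack:
    """Per-chromosome arrays of per-base scores; NaN marks missing bases."""

    scores: dict

    def __post_init__(self) -> None:
        self.scores = {c: np.asarray(v, dtype=np.float64) for c, v in self.scores.items()}
        for chrom, arr in self.scores.items():
            finite = arr[np.isfinite(arr)]
            if len(finite) and (finite.min() < 0 or finite.max() > 1):
                raise ValueError(f"{chrom}: conservation scores must lie in [0, 1]")


@dataclass
class ProfileResult:
    offsets: np.ndarray        # -half_width .. half_width-1
    mean: np.ndarray           # per-offset mean over sites
    n: np.ndarray              # non-missing site count per offset
    per_site_mean: np.ndarray  # mean score of each site's window
    grand_mean: float          # mean over all non-missing extracted values


def _extract_windows(track: ConservationTrack, sites, half_width: int) -> np.ndarray:
    """Site x offset matrix of scores; out-of-range positions are NaN."""
    win = np.full((len(sites), 2 * half_width), np.nan)
    for i, (chrom, center) in enumerate(sites):
        if chrom not in track.scores:
            logger.info("site %s:%d on a chromosome absent from the track", chrom, center)
            continue
        arr = track.scores[chrom]
        lo, hi = center - half_width, center + half_width
        src_lo, src_hi = max(0, lo), min(len(arr), hi)
        if src_lo >= src_hi:
            logger.info("site %s:%d entirely outside the track", chrom, center)
            continue
        if lo < 0 or hi > len(arr):
            logger.info("site %s:%d near a chromosome edge; padded as missing", chrom, center)
        win[i, src_lo - lo: src_hi - lo] = arr[src_lo:src_hi]
    return win


def average_profile(track: ConservationTrack, sites, half_width: int = 1000) -> ProfileResult:
    """Mean conservation per offset around the site centers.

    ``sites`` is a list of (chrom, center) positions. Missing values are
    skipped offset-wise; the grand mean is the mean of all extracted
    non-missing values (equal to the mean of per-site means when no value
    is missing).
    """
    if len(sites) == 0:
        raise ValueError("need at least one site")
    win = _extract_windows(track, sites, half_width)
    with warnings.catch_warnings():
        # offsets where every site is missing legitimately yield NaN
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean = np.nanmean(win, axis=0)
        per_site = np.nanmean(win, axis=1)
    return ProfileResult(offsets=np.arange(-half_width, half_width),
                         mean=mean, n=np.sum(np.isfinite(win), axis=0),
                         per_site_mean=per_site,
                         grand_mean=float(np.nanmean(win)))


def compare_site_sets(track: ConservationTrack, bound_sites, unbound_sites,
                      half_width: int = 1000, n_boot: int = 1000,
                      seed: int = 0) -> dict:
    """Bound vs unbound profile comparison with a bootstrap interval.

    The difference of grand means is resampled at the site level
    (``n_boot`` replicates, seeded); the interval is the percentile 95%
    CI. The bootstrap is added engineering around the mean curves and is
    labelled as such in the output.
    """
    bound = average_profile(track, bound_sites, half_width)
    unbound = average_profile(track, unbound_sites, half_width)
    diff = bound.grand_mean - unbound.grand_mean

    rng = np.random.default_rng(seed)
    win_b = _extract_windows(track, bound_sites, half_width)
    win_u = _extract_windows(track, unbound_sites, half_width)
    reps = np.empty(n_boot)
    with np.errstate(invalid="ignore"):
        for r in range(n_boot):
            ib = rng.integers(0, len(bound_sites), len(bound_sites))
            iu = rng.integers(0, len(unbound_sites), len(unbound_sites))
            reps[r] = np.nanmean(win_b[ib]) - np.nanmean(win_u[iu])
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return {"bound": bound, "unbound": unbound,
            "difference": float(diff),
            "bootstrap_ci": (float(lo), float(hi)),
            "ci_note": "site-level percentile bootstrap (added engineering; "
                       "not part of the original mean-curve comparison)"}
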