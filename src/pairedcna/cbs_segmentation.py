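"""Circular binary segmentation with permutation split tests and SD-undo.

The engine recursively splits one chromosome's ordered probe signal. For the
current interval it scans every arc (i, j] of the circularised interval and
maximises the pooled-variance two-sample t statistic between in-arc and
out-of-arc probes; the candidate split is accepted when its Monte-Carlo
permutation p-value (shuffles of the probe values within the interval) falls
below ``alpha_split``, and the recursion continues on the resulting
sub-intervals. Accepted breakpoints can later be *undone*: the merge rule
removes, smallest gap first, any breakpoint whose flanking segment means are
fewer than ``undo_sd`` noise standard deviations apart, recomputing means
after every merge.

Noise is estimated robustly from first differences,
``sd = 1.4826 * median(|x[i+1] - x[i]|) / sqrt(2)``, which is insensitive to
true copy-number steps.

The Monte-Carlo split test stops early once enough permuted maxima have
reached the observed maximum to guarantee p >= alpha_split; this changes no
accept/reject decision, only the number of draws spent on clearly
non-significant splits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numba import njit

from .core_io import GAIN, LOSS, NEUTRAL, Segment, SegmentSet

logger = logging.getLogger("pairedcna")


@dataclass(frozen=True)
class CBSParams:
    alpha_split: float = 0.01
    n_perm_split: int = 1000
    undo_sd: float = 2.0
    min_width: int = 2
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.alpha_split < 1.0:
            raise ValueError("alpha_split must lie in (0, 1)")
        if self.undo_sd < 0:
            raise ValueError("undo_sd must be >= 0")
        if self.min_width < 1:
            raise ValueError("min_width must be >= 1")


def estimate_noise_sd(values: np.ndarray) -> float:
    """Robust noise SD from successive differences (MAD-based).

    ``1.4826 * median(|diff|) / sqrt(2)``; steps between true segments only
    contribute a handful of outlying differences, leaving the median intact.
    """
    values = np.asarray(values, dtype=np.float64)
    if len(values) < 3:
        raise ValueError("need at least 3 values to estimate noise")
    return float(1.4826 * np.median(np.abs(np.diff(values))) / np.sqrt(2.0))


@njit(cache=False)
def _max_arc_t2(x, min_width):  # pragma: no cover - exercised via wrapper
    """Max squared pooled-variance t over arcs (i, j]; ties -> smallest (i, j).

    Returns (t2, i, j); t2 = -1 when no admissible arc exists.

    The pooled t^2 = (n-2) SSB / (SST - SSB) is monotone in the
    between-group sum of squares SSB(i, j) = (R_j - R_i)^2 * n / (k (n-k))
    (R = mean-centred partial sums, k = j - i), so the scan maximises SSB
    with no division in the inner loop; whole arc lengths are skipped when
    even the global range of R cannot beat the current best.
    """
    n = x.shape[0]
    r = np.empty(n + 1)
    r[0] = 0.0
    total = 0.0
    total_ss = 0.0
    for k in range(n):
        total += x[k]
        total_ss += x[k] * x[k]
        r[k + 1] = r[k] + x[k]
    mean = total / n
    rmin = 0.0
    rmax = 0.0
    for k in range(1, n + 1):
        r[k] -= mean * k
        if r[k] < rmin:
            rmin = r[k]
        if r[k] > rmax:
            rmax = r[k]
    sst = total_ss - total * mean
    rng2 = (rmax - rmin) * (rmax - rmin)
    best = -1.0
    best_i = -1
    best_j = -1
    for k in range(min_width, n - min_width + 1):
        w = n / (k * (n - k))
        if w * rng2 < best:
            continue
        for i in range(0, n - k + 1):
            d = r[i + k] - r[i]
            v = d * d * w
            if v > best:
                best = v
                best_i = i
                best_j = i + k
            elif v == best and (i < best_i or (i == best_i and i + k < best_j)):
                best_i = i
                best_j = i + k
    if best_i < 0:
        return -1.0, -1, -1
    ssw = sst - best
    if ssw <= 1e-300 * max(1.0, sst):
        t2 = 1e300 if best > 0.0 else 0.0
    else:
        t2 = best * (n - 2) / ssw
    return t2, best_i, best_j


def max_arc_statistic(values: np.ndarray, min_width: int = 2):
    """Best circular-arc split of an interval: (t^2, i, j) with arc (i, j]."""
    values = np.ascontiguousarray(values, dtype=np.float64)
    t2, i, j = _max_arc_t2(values, min_width)
    return float(t2), int(i), int(j)


def _split_significant(x: np.ndarray, t2_obs: float, p: CBSParams, rng) -> bool:
    """Monte-Carlo permutation test of the best split within one interval.

    Early exit (reject) once the exceedance count guarantees p >= alpha.
    """
    if t2_obs <= 0.0:
        return False
    # exceedances that already force (hits+1)/(n_perm+1) >= alpha
    stop_at = int(np.ceil(p.alpha_split * (p.n_perm_split + 1)))
    hits = 0
    for r in range(p.n_perm_split):
        perm = rng.permutation(x)
        t2_perm, _, _ = _max_arc_t2(perm, p.min_width)
        if t2_perm >= t2_obs:
            hits += 1
            if hits >= stop_at:
                return False
    return (hits + 1) / (p.n_perm_split + 1) < p.alpha_split


def _find_breakpoints(x: np.ndarray, lo: int, hi: int, p: CBSParams, rng, out: list):
    n = hi - lo
    if n < 2 * p.min_width:
        return
    t2, i, j = max_arc_statistic(x[lo:hi], p.min_width)
    if t2 <= 0 or i < 0:
        return
    if not _split_significant(np.ascontiguousarray(x[lo:hi]), t2, p, rng):
        return
    cuts = [lo + i, lo + j]
    cuts = [c for c in cuts if lo < c < hi]
    for a, b in zip([lo] + cuts, cuts + [hi]):
        _find_breakpoints(x, a, b, p, rng, out)
    out.extend(cuts)


def call_state(mean: float, threshold: float) -> str:
    if mean > threshold:
        return GAIN
    if mean < -threshold:
        return LOSS
    return NEUTRAL


def _build_segments(values, positions, chrom, breakpoints, offset,
                    state_threshold) -> list:
    bounds = [0] + sorted(breakpoints) + [len(values)]
    segs = []
    for a, b in zip(bounds, bounds[1:]):
        mean = float(np.mean(values[a:b]))
        segs.append(
            Segment(
                chrom=chrom,
                start_pos=int(positions[a]),
                end_pos=int(positions[b - 1]) + 1,
                start_idx=offset + a,
                end_idx=offset + b,
                mean=mean,
                n_probes=b - a,
                state=call_state(mean, state_threshold),
            )
        )
    return segs


def cbs_segment(values: np.ndarray, positions: np.ndarray, p: CBSParams | None = None,
                chrom: str = "chr1", sample_id: str = "sample",
                rng=None, offset: int = 0,
                state_threshold: float = 0.2) -> SegmentSet:
    """Segment one chromosome's ordered probe signal.

    ``positions`` are the probe midpoints (bp). ``offset`` shifts the probe
    indices recorded in the output (useful when the chromosome is a slice of
    a genome-wide array). Segment states are called at
    ``±state_threshold`` log2. Reproducible given ``p.seed`` (or an explicit
    ``rng``).
    """
    p = p or CBSParams()
    values = np.ascontiguousarray(values, dtype=np.float64)
    positions = np.asarray(positions)
    if len(values) != len(positions):
        raise ValueError("values and positions must have equal length")
    if len(values) == 0:
        raise ValueError("empty chromosome")
    if rng is None:
        rng = np.random.default_rng(p.seed)
    breakpoints: list = []
    _find_breakpoints(values, 0, len(values), p, rng, breakpoints)
    segs = _build_segments(values, positions, chrom, breakpoints, offset,
                           state_threshold)
    return SegmentSet(sample_id=sample_id, segments=segs)


def sd_undo(segs: SegmentSet, values: np.ndarray, undo_sd: float,
            noise_sd: float, offset: int = 0,
            state_threshold: float = 0.2) -> SegmentSet:
    """Merge breakpoints whose flanking means are < ``undo_sd`` SDs apart.

    Iterative, smallest gap first: while the smallest adjacent-segment mean
    gap |m_a - m_b| is below ``undo_sd * noise_sd``, that breakpoint is
    removed, the two segments merged and the mean recomputed from the probe
    values; with ``noise_sd == 0`` only zero gaps merge. Operates per
    chromosome; ``values``/``offset`` address the same probe window the
    segments were fitted on.
    """
    by_chrom = segs.by_chrom()
    merged_all = []
    for chrom in by_chrom:
        ss = sorted(by_chrom[chrom], key=lambda s: s.start_idx)
        while len(ss) > 1:
            gaps = [abs(a.mean - b.mean) for a, b in zip(ss, ss[1:])]
            k = int(np.argmin(gaps))
            limit = undo_sd * noise_sd
            if not (gaps[k] < limit or (noise_sd == 0.0 and gaps[k] == 0.0)):
                break
            a, b = ss[k], ss[k + 1]
            lo = a.start_idx - offset
            hi = b.end_idx - offset
            mean = float(np.mean(values[lo:hi]))
            ss[k : k + 2] = [
                Segment(
                    chrom=chrom,
                    start_pos=a.start_pos,
                    end_pos=b.end_pos,
                    start_idx=a.start_idx,
                    end_idx=b.end_idx,
                    mean=mean,
                    n_probes=a.n_probes + b.n_probes,
                    state=call_state(mean, state_threshold),
                )
            ]
        merged_all.extend(ss)
    return SegmentSet(sample_id=segs.sample_id, segments=merged_all)


def segment_chromosome(values, positions, p: CBSParams | None = None,
                       chrom: str = "chr1", sample_id: str = "sample",
                       noise_sd: float | None = None, rng=None,
                       offset: int = 0,
                       state_threshold: float = 0.2) -> SegmentSet:
    """CBS followed by the SD-undo merge rule (noise estimated if not given)."""
    p = p or CBSParams()
    segs = cbs_segment(values, positions, p, chrom, sample_id, rng, offset,
                       state_threshold)
    if noise_sd is None:
        noise_sd = estimate_noise_sd(values) if len(values) >= 3 else 0.0
    return sd_undo(segs, values, p.undo_sd, noise_sd, offset, state_threshold)


__all__ = [
    "CBSParams",
    "estimate_noise_sd",
    "max_arc_statistic",
    "cbs_segment",
    "sd_undo",
    "segment_chromosome",
    "call_state",
]
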