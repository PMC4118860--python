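"""Permutation test for recurrent regional copy-number differences.

Two groups of kernel-smoothed profiles (lymph-node metastases vs primary
tumours) are compared through the pointwise difference curve

    D(g) = mean_LNM s(g) - mean_tumour s(g).

Significance is assessed with the maximum statistic max_g |D(g)| for
familywise control: the null distribution comes from random relabelings —
in the default paired mode each pair's tumour/LNM labels are swapped
independently (a sign flip of that pair's difference curve), in unpaired
mode group labels are permuted. Significant regions are maximal runs of
grid points whose |D| exceeds the (1 - alpha) null quantile; each region
carries its direction and an empirical p-value. When the number of distinct
relabelings is no larger than ``n_perm`` the null is enumerated exhaustively
instead of sampled.

A pointwise threshold mode (per-grid-point null quantiles, no familywise
control) is available for sensitivity analysis.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np

from .core_io import PairTable, sort_chromosomes

logger = logging.getLogger("pairedcna")


@dataclass(frozen=True)
class CompareParams:
    sigma_bp: float = 1_000_000.0
    alpha: float = 0.05
    n_perm: int = 1000
    paired: bool = True
    seed: int = 0
    threshold_mode: str = "max"  # "max" (familywise) | "pointwise"

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        if self.threshold_mode not in ("max", "pointwise"):
            raise ValueError("threshold_mode must be 'max' or 'pointwise'")


@dataclass
class SignificantRegion:
    chrom: str
    start_pos: float
    end_pos: float
    direction: int  # +1: higher in LNM, -1: lower in LNM
    max_abs_d: float
    p_value: float


@dataclass
class ComparisonResult:
    chrom_labels: np.ndarray
    positions: np.ndarray
    difference: np.ndarray  # D(g) = mean LNM - mean tumour
    threshold: np.ndarray | float
    null_max: np.ndarray
    regions: list
    exhaustive: bool
    params: CompareParams

    @property
    def n_significant(self) -> int:
        return len(self.regions)


def difference_curve(smoothed: np.ndarray, labels) -> np.ndarray:
    """Mean smoothed LNM profile minus mean smoothed tumour profile.

    ``labels`` holds "lnm"/"tumour" per row of ``smoothed``.
    """
    labels = np.asarray(labels, dtype=object)
    bad = set(labels) - {"lnm", "tumour"}
    if bad:
        raise ValueError(f"unknown labels: {sorted(bad)}")
    lnm = smoothed[labels == "lnm"]
    tum = smoothed[labels == "tumour"]
    if len(lnm) == 0 or len(tum) == 0:
        raise ValueError("both groups must be non-empty")
    return lnm.mean(axis=0) - tum.mean(axis=0)


def _pair_differences(smoothed, ids, pairs: PairTable) -> np.ndarray:
    """Per-pair smoothed LNM - tumour difference curves (pairs x grid)."""
    idx = {s: i for i, s in enumerate(ids)}
    missing = [
        pr.patient_id
        for pr in pairs
        if pr.lnm_id not in idx or pr.tumour_id not in idx
    ]
    if missing:
        raise KeyError(f"pairs with samples missing from matrix: {missing}")
    return np.vstack(
        [smoothed[idx[pr.lnm_id]] - smoothed[idx[pr.tumour_id]] for pr in pairs]
    )


def _regions_from_runs(chrom_labels, positions, diff, exceed) -> list:
    """Maximal runs of exceeding grid points, never spanning chromosomes."""
    regions = []
    order = sort_chromosomes(chrom_labels)
    for chrom in order:
        m = chrom_labels == chrom
        pos = positions[m]
        d = diff[m]
        ex = exceed[m]
        i = 0
        while i < len(ex):
            if not ex[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(ex) and ex[j + 1]:
                j += 1
            seg = d[i : j + 1]
            peak = int(np.argmax(np.abs(seg)))
            regions.append(
                SignificantRegion(
                    chrom=chrom,
                    start_pos=float(pos[i]),
                    end_pos=float(pos[j]),
                    direction=int(np.sign(seg[peak])),
                    max_abs_d=float(np.abs(seg[peak])),
                    p_value=np.nan,
                )
            )
            i = j + 1
    return regions


def _null_difference_curves(smoothed, ids, labels, pairs, cp):
    """Null D(g) curves from relabelings; returns (curves, exhaustive)."""
    labels = np.asarray(labels, dtype=object)

    if cp.paired:
        if pairs is None:
            raise ValueError("paired mode requires a PairTable")
        in_pairs = {s for pr in pairs for s in (pr.lnm_id, pr.tumour_id)}
        extra = set(ids) - in_pairs
        if extra:
            raise ValueError(f"paired mode: samples not in any pair: {sorted(extra)}")
        diffs = _pair_differences(smoothed, ids, pairs)
        n_pairs = len(diffs)
        exhaustive = 2 ** n_pairs <= cp.n_perm
        if exhaustive:
            logger.info(
                "2^%d = %d sign patterns <= n_perm=%d: exhaustive enumeration",
                n_pairs, 2 ** n_pairs, cp.n_perm,
            )
            signs = np.array(
                list(itertools.product((1.0, -1.0), repeat=n_pairs))
            )
        else:
            rng = np.random.default_rng(cp.seed)
            signs = rng.choice([1.0, -1.0], size=(cp.n_perm, n_pairs))
        null_curves = (signs @ diffs) / n_pairs
    else:
        group = labels == "lnm"
        n = len(labels)
        k = int(group.sum())
        from math import comb

        exhaustive = comb(n, k) <= cp.n_perm
        if exhaustive:
            logger.info("C(%d,%d) <= n_perm: exhaustive label permutation", n, k)
            assignments = list(itertools.combinations(range(n), k))
            null_curves = np.empty((len(assignments), smoothed.shape[1]))
            for r, idx_lnm in enumerate(assignments):
                perm = np.full(n, "tumour", dtype=object)
                perm[list(idx_lnm)] = "lnm"
                null_curves[r] = difference_curve(smoothed, perm)
        else:
            rng = np.random.default_rng(cp.seed)
            null_curves = np.empty((cp.n_perm, smoothed.shape[1]))
            for r in range(cp.n_perm):
                perm = labels[rng.permutation(n)]
                null_curves[r] = difference_curve(smoothed, perm)
    return null_curves, exhaustive


def permutation_test(smoothed: np.ndarray, ids, labels, chrom_labels, positions,
                     pairs: PairTable | None = None,
                     cp: CompareParams | None = None) -> ComparisonResult:
    """Max-|D| permutation test between tumours and LNMs.

    ``smoothed`` is the stacked samples-by-grid matrix (as produced by
    :func:`pairedcna.kernel_smoothing.smooth_cohort`) with per-row
    tumour/lnm ``labels``; paired mode additionally needs the
    :class:`PairTable`. Monte-Carlo region p-values carry the +1 correction
    (so p >= 1/(n_perm+1)); exhaustive enumerations do not need it.
    """
    cp = cp or CompareParams()
    labels = np.asarray(labels, dtype=object)
    observed = difference_curve(smoothed, labels)
    null_curves, exhaustive = _null_difference_curves(smoothed, ids, labels, pairs, cp)

    null_abs = np.abs(null_curves)
    null_max = null_abs.max(axis=1)
    if cp.threshold_mode == "max":
        threshold = float(np.quantile(null_max, 1.0 - cp.alpha, method="higher"))
        exceed = np.abs(observed) > threshold
    else:
        threshold = np.quantile(null_abs, 1.0 - cp.alpha, axis=0, method="higher")
        exceed = np.abs(observed) > threshold

    chrom_labels = np.asarray(chrom_labels, dtype=object)
    positions = np.asarray(positions, dtype=float)
    regions = _regions_from_runs(chrom_labels, positions, observed, exceed)
    n_null = len(null_max)
    for reg in regions:
        hits = int(np.sum(null_max >= reg.max_abs_d))
        reg.p_value = max(hits, 1) / n_null if exhaustive else (hits + 1) / (n_null + 1)

    return ComparisonResult(
        chrom_labels=chrom_labels,
        positions=positions,
        difference=observed,
        threshold=threshold,
        null_max=null_max,
        regions=regions,
        exhaustive=exhaustive,
        params=cp,
    )


__all__ = [
    "CompareParams",
    "SignificantRegion",
    "ComparisonResult",
    "difference_curve",
    "permutation_test",
]
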