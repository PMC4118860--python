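"""Pairwise tumour / lymph-node-metastasis divergence ("delta-profile") analysis.

For each patient the tumour and LNM profiles are quantile-normalised against
each other, subtracted (LNM - tumour) to form the delta profile, and the
delta is segmented per chromosome by circular binary segmentation with the
2-SD breakpoint-undo rule (noise SD estimated once from the whole delta
profile). Delta segments are then

* flagged when |segment mean| exceeds ``abs_delta_threshold`` (0.2 log2) and
  additionally when they contain >= ``min_probes`` probes (10),
* annotated with the copy-number state of the segment span in each of the
  two normalised samples (gain if that sample's mean over the span > 0.2,
  loss if < -0.2, neutral otherwise),
* counted per patient and compared between subtypes with the Wilcoxon
  rank-sum test,
* searched for recurrent overlaps across patients (|mean| > 0.1 candidates;
  connected components of the cross-patient interval-overlap graph) with a
  direction-consistency check.

Pairs whose delta noise SD exceeds a configurable multiple of the cohort
median are flagged as noisy hybridisations and excluded from the group
statistics (with a logged reason), mirroring the exclusion of
quality-compromised pairs from a real cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cbs_segmentation import (
    CBSParams,
    call_state,
    cbs_segment,
    estimate_noise_sd,
    sd_undo,
)
from .core_io import CNProfile, PairTable, ProbeGrid, SegmentSet

logger = logging.getLogger("pairedcna")


@dataclass(frozen=True)
class DeltaParams:
    abs_delta_threshold: float = 0.2  # log2; a "real" delta segment
    min_probes: int = 10
    state_threshold: float = 0.2  # gain/loss call in individual samples
    overlap_abs_threshold: float = 0.1  # candidate threshold for overlap search
    noisy_exclude_multiplier: float = 3.0  # x cohort median delta noise SD
    chain_overlaps: bool = True  # transitive overlap grouping
    cbs: CBSParams = field(default_factory=CBSParams)

    def __post_init__(self):
        for name in ("abs_delta_threshold", "state_threshold",
                     "overlap_abs_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.min_probes < 1:
            raise ValueError("min_probes must be >= 1")


@dataclass
class SegmentAnnotation:
    tumour_state: str
    lnm_state: str
    passes_threshold: bool
    passes_min_probes: bool


@dataclass
class DeltaProfile:
    """One patient's probe-level delta (LNM - tumour) and its segmentation."""

    patient_id: str
    grid: ProbeGrid
    values: np.ndarray
    segments: SegmentSet | None = None
    annotations: list | None = None  # parallel to segments
    noise_sd: float | None = None

    def qualifying_segments(self):
        """(segment, annotation) pairs passing both delta-segment filters."""
        if self.segments is None:
            return []
        return [
            (s, a)
            for s, a in zip(self.segments, self.annotations)
            if a.passes_threshold and a.passes_min_probes
        ]


# ---------------------------------------------------------------------------
# Normalisation and delta construction
# ---------------------------------------------------------------------------


def quantile_normalize_pair(tumour: CNProfile, lnm: CNProfile):
    """Two-sample quantile normalisation.

    The rank-k value of each sample is replaced by the mean of the two
    samples' rank-k values; tied values within a sample receive the average
    of the replacement values over their tied ranks, so the output
    distributions are identical (up to ties) and tied inputs stay tied.
    """
    if not tumour.grid.same_coords(lnm.grid):
        raise ValueError("paired profiles must share one probe grid")
    a, b = tumour.log2ratio, lnm.log2ratio
    ref = (np.sort(a) + np.sort(b)) / 2.0

    def transform(x):
        order = np.argsort(x, kind="stable")
        out = np.empty_like(x)
        out[order] = ref
        # average replacement values over tied ranks
        xs = x[order]
        k = 0
        while k < len(xs):
            m = k
            while m + 1 < len(xs) and xs[m + 1] == xs[k]:
                m += 1
            if m > k:
                out[order[k : m + 1]] = ref[k : m + 1].mean()
            k = m + 1
        return out

    return (
        CNProfile(tumour.grid, transform(a), tumour.meta),
        CNProfile(lnm.grid, transform(b), lnm.meta),
    )


def make_delta(tumour: CNProfile, lnm: CNProfile, patient_id: str) -> DeltaProfile:
    """Probe-wise LNM - tumour difference of an (already normalised) pair."""
    if not tumour.grid.same_coords(lnm.grid):
        raise ValueError("paired profiles must share one probe grid")
    return DeltaProfile(
        patient_id=patient_id,
        grid=tumour.grid,
        values=lnm.log2ratio - tumour.log2ratio,
    )


# ---------------------------------------------------------------------------
# Segmentation and per-segment annotation
# ---------------------------------------------------------------------------


def segment_delta(delta: DeltaProfile, tumour: CNProfile, lnm: CNProfile,
                  dp: DeltaParams | None = None) -> DeltaProfile:
    """Segment the delta profile and annotate each segment.

    CBS + SD-undo run per chromosome; the noise SD feeding the undo rule is
    estimated once from the whole delta profile. Tumour/LNM states come from
    the normalised individual samples averaged over each segment's span.
    """
    dp = dp or DeltaParams()
    noise_sd = estimate_noise_sd(delta.values)
    segments = []
    for ci, (chrom, sl) in enumerate(delta.grid.chrom_slices().items()):
        rng = np.random.default_rng(np.random.SeedSequence(
            entropy=dp.cbs.seed, spawn_key=(ci,)))
        segs = cbs_segment(
            delta.values[sl], delta.grid.pos[sl], dp.cbs, chrom=chrom,
            sample_id=delta.patient_id, rng=rng, offset=sl.start,
            state_threshold=dp.abs_delta_threshold,
        )
        segs = sd_undo(segs, delta.values[sl], dp.cbs.undo_sd, noise_sd,
                       offset=sl.start, state_threshold=dp.abs_delta_threshold)
        segments.extend(segs.segments)
    segset = SegmentSet(sample_id=delta.patient_id, segments=segments)

    annotations = []
    for s in segset:
        t_mean = float(np.mean(tumour.log2ratio[s.start_idx:s.end_idx]))
        l_mean = float(np.mean(lnm.log2ratio[s.start_idx:s.end_idx]))
        annotations.append(
            SegmentAnnotation(
                tumour_state=call_state(t_mean, dp.state_threshold),
                lnm_state=call_state(l_mean, dp.state_threshold),
                passes_threshold=abs(s.mean) > dp.abs_delta_threshold,
                passes_min_probes=s.n_probes >= dp.min_probes,
            )
        )
    return DeltaProfile(delta.patient_id, delta.grid, delta.values, segset,
                        annotations, noise_sd)


def count_delta_segments(delta: DeltaProfile, dp: DeltaParams | None = None):
    """(segments with |mean| > threshold, those also with >= min_probes probes)."""
    dp = dp or DeltaParams()
    if delta.segments is None:
        raise ValueError("delta profile is not segmented")
    above = [s for s in delta.segments if abs(s.mean) > dp.abs_delta_threshold]
    strict = [s for s in above if s.n_probes >= dp.min_probes]
    return len(above), len(strict)


# ---------------------------------------------------------------------------
# Subtype comparison
# ---------------------------------------------------------------------------


@dataclass
class WilcoxonResult:
    statistic: float  # rank-sum W of the first (TNBC) group
    p_value: float
    method: str  # "exact" | "normal"
    n1: int
    n2: int


def compare_subtype_counts(counts: dict, subtypes: dict) -> WilcoxonResult:
    """Two-sided Wilcoxon rank-sum of delta-segment counts, TNBC vs ER+.

    Exact enumeration is used when both groups have <= 10 patients and the
    counts are untied; the tie-corrected normal approximation otherwise.
    """
    x = [counts[p] for p in sorted(counts) if subtypes[p] == "TNBC"]
    y = [counts[p] for p in sorted(counts) if subtypes[p] == "ERpos"]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need >=2 patients per subtype")
    pooled = x + y
    no_ties = len(set(pooled)) == len(pooled)
    exact = no_ties and len(x) <= 10 and len(y) <= 10
    if len(set(pooled)) == 1:  # degenerate: all counts identical
        u1 = len(x) * len(y) / 2.0
        return WilcoxonResult(u1 + len(x) * (len(x) + 1) / 2.0, 1.0,
                              "normal", len(x), len(y))
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=False,
    )
    w = float(res.statistic) + len(x) * (len(x) + 1) / 2.0  # U1 -> rank-sum W
    return WilcoxonResult(w, min(1.0, float(res.pvalue)),
                          "exact" if exact else "normal", len(x), len(y))


# ---------------------------------------------------------------------------
# Recurrent overlap search
# ---------------------------------------------------------------------------


@dataclass
class OverlapGroup:
    """Delta segments from >=2 patients sharing genomic overlap."""

    chrom: str
    start_pos: int
    end_pos: int
    members: list  # (patient_id, Segment, direction sign)
    consistent_direction: bool

    @property
    def n_patients(self) -> int:
        return len({pid for pid, _, _ in self.members})


class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, i):
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i, j):
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def _group_interval(members):
    """Common intersection; falls back to the deepest-coverage window when
    transitive chaining makes the full intersection empty."""
    start = max(s.start_pos for _, s, _ in members)
    end = min(s.end_pos for _, s, _ in members)
    if start < end:
        return start, end
    events = []
    for _, s, _ in members:
        events.append((s.start_pos, 1))
        events.append((s.end_pos, -1))
    events.sort()
    depth = best = 0
    best_start = best_end = None
    for i, (pos, step) in enumerate(events):
        depth += step
        if depth > best:
            best = depth
            best_start = pos
            best_end = events[i + 1][0] if i + 1 < len(events) else pos
    return best_start, best_end


def find_overlaps(deltas: list, dp: DeltaParams | None = None) -> list:
    """Recurrent delta segments: cross-patient overlap groups.

    Candidates are delta segments with |mean| above the
    ``overlap_abs_threshold`` (0.1 log2) criterion. Overlapping candidates
    from different patients are joined — transitively into connected
    components when ``chain_overlaps`` (default), otherwise only maximal
    pairwise-intersecting cliques of two. Each group reports its member
    directions (sign of the delta-segment mean) and whether all members agree
    (``consistent_direction``).
    """
    dp = dp or DeltaParams()
    if len(deltas) < 2:
        raise ValueError("need >=2 patients to search for overlaps")
    cands = []
    for d in deltas:
        if d.segments is None:
            raise ValueError(f"{d.patient_id}: delta profile not segmented")
        for s in d.segments:
            if abs(s.mean) > dp.overlap_abs_threshold:
                cands.append((d.patient_id, s, 1 if s.mean > 0 else -1))

    def overlapping(a, b):
        return a[0] != b[0] and a[1].overlaps(b[1])

    groups = []
    if dp.chain_overlaps:
        uf = _UnionFind(len(cands))
        for i in range(len(cands)):
            for j in range(i + 1, len(cands)):
                if overlapping(cands[i], cands[j]):
                    uf.union(i, j)
        comp = {}
        for i in range(len(cands)):
            comp.setdefault(uf.find(i), []).append(cands[i])
        raw_groups = [g for g in comp.values() if len(g) >= 2]
    else:
        raw_groups = [
            [cands[i], cands[j]]
            for i in range(len(cands))
            for j in range(i + 1, len(cands))
            if overlapping(cands[i], cands[j])
        ]
    for g in raw_groups:
        if len({pid for pid, _, _ in g}) < 2:
            continue
        start, end = _group_interval(g)
        signs = {sign for _, _, sign in g}
        groups.append(
            OverlapGroup(
                chrom=g[0][1].chrom,
                start_pos=start,
                end_pos=end,
                members=g,
                consistent_direction=len(signs) == 1,
            )
        )
    groups.sort(key=lambda gr: (gr.chrom, gr.start_pos))
    return groups


# ---------------------------------------------------------------------------
# Cohort-level driver
# ---------------------------------------------------------------------------


@dataclass
class DeltaReport:
    deltas: dict  # patient_id -> DeltaProfile (segmented)
    counts: pd.DataFrame  # patient, subtype, noise_sd, excluded, n_segments, n_segments_min10
    wilcoxon: WilcoxonResult | None
    wilcoxon_min10: WilcoxonResult | None
    overlaps: list
    excluded: list  # patient ids


def run_delta_pipeline(profiles: list, pairs: PairTable,
                       dp: DeltaParams | None = None) -> DeltaReport:
    """Full pairwise analysis over a cohort.

    Normalises, subtracts and segments every pair, counts qualifying delta
    segments, excludes noisy pairs from group statistics, runs the subtype
    Wilcoxon comparison on both counts and searches for recurrent overlaps
    among the retained pairs.
    """
    dp = dp or DeltaParams()
    by_id = {p.sample_id: p for p in profiles}
    deltas, rows = {}, []
    for pr in pairs:
        t, l = by_id[pr.tumour_id], by_id[pr.lnm_id]
        tn, ln = quantile_normalize_pair(t, l)
        delta = make_delta(tn, ln, pr.patient_id)
        delta = segment_delta(delta, tn, ln, dp)
        deltas[pr.patient_id] = delta
        n_above, n_strict = count_delta_segments(delta, dp)
        rows.append(
            {
                "patient_id": pr.patient_id,
                "subtype": pr.subtype,
                "noise_sd": delta.noise_sd,
                "n_segments": n_above,
                "n_segments_min10": n_strict,
            }
        )
    counts = pd.DataFrame(rows)
    median_noise = float(counts["noise_sd"].median())
    counts["excluded"] = counts["noise_sd"] > dp.noisy_exclude_multiplier * median_noise
    excluded = counts.loc[counts["excluded"], "patient_id"].tolist()
    for pid in excluded:
        noise = float(counts.loc[counts.patient_id == pid, "noise_sd"].iloc[0])
        logger.warning(
            "excluding pair %s from group statistics: delta noise SD %.3f > "
            "%.1fx cohort median (%.3f)",
            pid, noise, dp.noisy_exclude_multiplier, median_noise,
        )
    kept = counts.loc[~counts["excluded"]]
    subtype_of = dict(zip(counts["patient_id"], counts["subtype"]))

    def _wilcoxon(col):
        c = dict(zip(kept["patient_id"], kept[col]))
        try:
            return compare_subtype_counts(c, subtype_of)
        except ValueError as exc:
            logger.warning("subtype comparison skipped (%s): %s", col, exc)
            return None

    wilcoxon = _wilcoxon("n_segments")
    wilcoxon_min10 = _wilcoxon("n_segments_min10")
    kept_deltas = [deltas[p] for p in kept["patient_id"]]
    overlaps = find_overlaps(kept_deltas, dp) if len(kept_deltas) >= 2 else []
    return DeltaReport(deltas, counts, wilcoxon, wilcoxon_min10, overlaps, excluded)


def overlaps_table(overlaps: list) -> pd.DataFrame:
    rows = []
    for k, g in enumerate(overlaps):
        for pid, seg, sign in g.members:
            rows.append(
                {
                    "group": k,
                    "chrom": g.chrom,
                    "group_start": g.start_pos,
                    "group_end": g.end_pos,
                    "consistent_direction": g.consistent_direction,
                    "patient_id": pid,
                    "seg_start": seg.start_pos,
                    "seg_end": seg.end_pos,
                    "seg_mean": seg.mean,
                    "direction": sign,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "group", "chrom", "group_start", "group_end",
            "consistent_direction", "patient_id", "seg_start", "seg_end",
            "seg_mean", "direction",
        ],
    )


__all__ = [
    "DeltaParams",
    "DeltaProfile",
    "SegmentAnnotation",
    "WilcoxonResult",
    "OverlapGroup",
    "DeltaReport",
    "quantile_normalize_pair",
    "make_delta",
    "segment_delta",
    "count_delta_segments",
    "compare_subtype_counts",
    "find_overlaps",
    "run_delta_pipeline",
    "overlaps_table",
]
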