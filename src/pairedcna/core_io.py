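"""Domain types and file I/O for probe-level copy-number data.

Conventions used throughout the package:

* coordinates are 0-based, half-open; probes are points (midpoints);
* SEG files are written 1-based inclusive, BED files 0-based half-open;
* chromosomes are opaque strings ordered naturally (chr1 < chr2 < ... <
  chr10 < ... < chrX < chrY), no genome build is assumed;
* log2 ratios are dimensionless (0 = copy-neutral, >0 gain, <0 loss).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("pairedcna")

TISSUES = ("tumour", "lnm")
SUBTYPES = ("TNBC", "ERpos")

GAIN = "gain"
LOSS = "loss"
NEUTRAL = "neutral"

_FLOAT_FMT = "%.6f"  # reader/writer round-trips are lossless at 6 decimals


def chrom_sort_key(chrom: str):
    """Natural ordering key: chr1 < chr2 < ... < chr10 < ... < chrX."""
    name = chrom[3:] if chrom.lower().startswith("chr") else chrom
    m = re.fullmatch(r"(\d+)", name)
    if m:
        return (0, int(m.group(1)), "")
    return (1, 0, name)


def sort_chromosomes(chroms) -> list:
    return sorted(set(chroms), key=chrom_sort_key)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ProbeGrid:
    """Ordered genomic probe coordinates defining an array platform.

    Probes are sorted by (chromosome, position) with strictly increasing
    positions within a chromosome and globally unique probe ids.
    """

    probe_id: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray

    def __post_init__(self):
        self.probe_id = np.asarray(self.probe_id, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        if not (len(self.probe_id) == len(self.chrom) == len(self.pos)):
            raise ValueError("probe_id, chrom and pos must have equal length")
        if len(np.unique(self.probe_id)) != len(self.probe_id):
            raise ValueError("duplicate probe ids in grid")
        order = sort_chromosomes(self.chrom)
        expected = order
        seen = []
        for c in self.chrom:
            if not seen or seen[-1] != c:
                seen.append(c)
        if len(seen) != len(set(seen)) or seen != [c for c in expected if c in seen]:
            raise ValueError("probes are not grouped by naturally ordered chromosome")
        for c, sl in self.chrom_slices().items():
            p = self.pos[sl]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    def __len__(self) -> int:
        return len(self.pos)

    @property
    def n_probes(self) -> int:
        return len(self.pos)

    def chromosomes(self) -> list:
        out = []
        for c in self.chrom:
            if not out or out[-1] != c:
                out.append(c)
        return out

    def chrom_slices(self) -> dict:
        """Mapping chromosome -> slice into the probe arrays."""
        out = {}
        start = 0
        for i in range(1, len(self.chrom) + 1):
            if i == len(self.chrom) or self.chrom[i] != self.chrom[start]:
                out[self.chrom[start]] = slice(start, i)
                start = i
        return out

    def index_of(self, probe_ids) -> np.ndarray:
        lookup = {p: i for i, p in enumerate(self.probe_id)}
        try:
            return np.array([lookup[p] for p in probe_ids], dtype=np.int64)
        except KeyError as exc:
            raise KeyError(f"unknown probe id {exc.args[0]!r}") from None

    def subset(self, mask: np.ndarray) -> "ProbeGrid":
        return ProbeGrid(self.probe_id[mask], self.chrom[mask], self.pos[mask])

    def same_coords(self, other: "ProbeGrid") -> bool:
        return (
            len(self) == len(other)
            and bool(np.all(self.probe_id == other.probe_id))
            and bool(np.all(self.chrom == other.chrom))
            and bool(np.all(self.pos == other.pos))
        )


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    patient_id: str
    tissue: str  # "tumour" | "lnm"
    subtype: str  # "TNBC" | "ERpos"

    def __post_init__(self):
        if self.tissue not in TISSUES:
            raise ValueError(f"tissue must be one of {TISSUES}, got {self.tissue!r}")
        if self.subtype not in SUBTYPES:
            raise ValueError(f"subtype must be one of {SUBTYPES}, got {self.subtype!r}")


@dataclass
class CNProfile:
    """Per-sample probe-level log2 ratios aligned to a ProbeGrid."""

    grid: ProbeGrid
    log2ratio: np.ndarray
    meta: SampleMeta

    def __post_init__(self):
        self.log2ratio = np.asarray(self.log2ratio, dtype=np.float64)
        if len(self.log2ratio) != len(self.grid):
            raise ValueError(
                f"profile {self.meta.sample_id}: {len(self.log2ratio)} values "
                f"for a grid of {len(self.grid)} probes"
            )
        if not np.all(np.isfinite(self.log2ratio)):
            raise ValueError(f"profile {self.meta.sample_id}: non-finite log2 ratios")

    @property
    def sample_id(self) -> str:
        return self.meta.sample_id


@dataclass
class Segment:
    """Half-open genomic interval with a constant fitted log2 mean."""

    chrom: str
    start_pos: int
    end_pos: int
    start_idx: int
    end_idx: int
    mean: float
    n_probes: int
    state: str = NEUTRAL

    def __post_init__(self):
        if not self.start_pos < self.end_pos:
            raise ValueError("segment requires start_pos < end_pos")
        if self.n_probes != self.end_idx - self.start_idx or self.n_probes < 1:
            raise ValueError("n_probes must equal end_idx - start_idx >= 1")
        if self.state not in (GAIN, LOSS, NEUTRAL):
            raise ValueError(f"bad state {self.state!r}")

    def overlaps(self, other: "Segment") -> bool:
        return (
            self.chrom == other.chrom
            and self.start_pos < other.end_pos
            and other.start_pos < self.end_pos
        )


@dataclass
class SegmentSet:
    """Piecewise-constant description of one sample's profile.

    Segments tile each chromosome without overlap (checked on request via
    :meth:`validate_tiling`).
    """

    sample_id: str
    segments: list = field(default_factory=list)

    def __iter__(self):
        return iter(self.segments)

    def __len__(self):
        return len(self.segments)

    def by_chrom(self) -> dict:
        out = {}
        for s in self.segments:
            out.setdefault(s.chrom, []).append(s)
        return out

    def validate_tiling(self, grid: ProbeGrid):
        for c, sl in grid.chrom_slices().items():
            segs = sorted(
                (s for s in self.segments if s.chrom == c), key=lambda s: s.start_idx
            )
            if not segs:
                raise ValueError(f"{self.sample_id}: chromosome {c} not covered")
            if segs[0].start_idx != sl.start or segs[-1].end_idx != sl.stop:
                raise ValueError(f"{self.sample_id}: segments do not span {c}")
            for a, b in zip(segs, segs[1:]):
                if a.end_idx != b.start_idx:
                    raise ValueError(f"{self.sample_id}: gap/overlap in {c} segments")


@dataclass(frozen=True)
class PairRecord:
    patient_id: str
    tumour_id: str
    lnm_id: str
    subtype: str


@dataclass
class PairTable:
    """One row per patient linking its tumour and LNM samples."""

    pairs: list

    def __iter__(self):
        return iter(self.pairs)

    def __len__(self):
        return len(self.pairs)

    @property
    def patient_ids(self) -> list:
        return [p.patient_id for p in self.pairs]

    @classmethod
    def from_samples(cls, metas) -> "PairTable":
        """Build the pairing from sample metadata, one tumour + one LNM each."""
        by_patient = {}
        for m in metas:
            by_patient.setdefault(m.patient_id, []).append(m)
        pairs = []
        for pid in sorted(by_patient):
            ms = by_patient[pid]
            tums = [m for m in ms if m.tissue == "tumour"]
            lnms = [m for m in ms if m.tissue == "lnm"]
            if len(tums) != 1 or len(lnms) != 1:
                raise ValueError(
                    f"patient {pid}: expected exactly one tumour and one lnm sample, "
                    f"got {len(tums)} tumour(s) / {len(lnms)} lnm(s)"
                )
            if tums[0].subtype != lnms[0].subtype:
                raise ValueError(f"patient {pid}: subtype mismatch between samples")
            pairs.append(
                PairRecord(pid, tums[0].sample_id, lnms[0].sample_id, tums[0].subtype)
            )
        return cls(pairs)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_sample_sheet(path) -> list:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "patient_id", "tissue", "subtype"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    return [
        SampleMeta(r.sample_id, r.patient_id, r.tissue, r.subtype)
        for r in df.itertuples()
    ]


def write_sample_sheet(metas, path):
    pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in metas],
            "patient_id": [m.patient_id for m in metas],
            "tissue": [m.tissue for m in metas],
            "subtype": [m.subtype for m in metas],
        }
    ).to_csv(path, sep="\t", index=False)


def read_probe_matrix(path, sample_sheet, na_policy: str = "drop"):
    """Read a probe-level log2-ratio matrix plus its sample sheet.

    The matrix is tab-delimited with columns ``probe_id``, ``chrom``, ``pos``
    and one column per sample. Rows are re-sorted to natural (chrom, pos)
    order. Probes with a missing value in any sample are dropped from the
    grid for all samples (logged); this is the only supported policy, so that
    pairwise analyses always see identical grids.

    Returns ``(ProbeGrid, list[CNProfile])`` with profiles in sheet order.
    """
    if na_policy != "drop":
        raise ValueError("only na_policy='drop' is supported")
    metas = (
        read_sample_sheet(sample_sheet)
        if not isinstance(sample_sheet, list)
        else sample_sheet
    )
    by_id = {m.sample_id: m for m in metas}
    df = pd.read_csv(path, sep="\t")
    for col in ("probe_id", "chrom", "pos"):
        if col not in df.columns:
            raise ValueError(f"probe matrix missing column {col!r}")
    sample_cols = [c for c in df.columns if c not in ("probe_id", "chrom", "pos")]
    unknown = [c for c in sample_cols if c not in by_id]
    if unknown:
        raise ValueError(f"samples in matrix missing from sample sheet: {unknown}")
    if df["probe_id"].duplicated().any():
        dups = df.loc[df["probe_id"].duplicated(), "probe_id"].tolist()[:5]
        raise ValueError(f"duplicate probe ids in matrix (e.g. {dups})")

    df = df.sort_values(
        by=["chrom", "pos"],
        key=lambda s: s.map(chrom_sort_key) if s.name == "chrom" else s,
        kind="stable",
    ).reset_index(drop=True)

    bad = df[sample_cols].isna().any(axis=1)
    if bad.any():
        logger.warning(
            "dropping %d/%d probes with missing values", int(bad.sum()), len(df)
        )
        df = df.loc[~bad].reset_index(drop=True)

    counts = df["chrom"].value_counts()
    thin = counts[counts < 2]
    if len(thin):
        raise ValueError(f"chromosome(s) with <2 probes: {sorted(thin.index)}")

    grid = ProbeGrid(
        df["probe_id"].to_numpy(dtype=object),
        df["chrom"].astype(str).to_numpy(dtype=object),
        df["pos"].to_numpy(dtype=np.int64),
    )
    profiles = []
    for m in metas:
        if m.sample_id in sample_cols:
            profiles.append(
                CNProfile(grid, df[m.sample_id].to_numpy(dtype=np.float64), m)
            )
    return grid, profiles


def write_probe_matrix(grid: ProbeGrid, profiles, path):
    df = pd.DataFrame(
        {"probe_id": grid.probe_id, "chrom": grid.chrom, "pos": grid.pos}
    )
    for p in profiles:
        if not p.grid.same_coords(grid):
            raise ValueError(f"profile {p.sample_id} not aligned to the grid")
        df[p.sample_id] = p.log2ratio
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def subset_to_platform(profile: CNProfile, keep) -> CNProfile:
    """Restrict a profile to a probe subset (e.g. 720K -> 135K downscaling).

    ``keep`` is a set of probe ids, all of which must exist on the grid;
    probe order is preserved.
    """
    keep = set(keep)
    unknown = keep - set(profile.grid.probe_id)
    if unknown:
        raise KeyError(f"unknown probe ids in keep set (e.g. {sorted(unknown)[:5]})")
    mask = np.array([p in keep for p in profile.grid.probe_id])
    return CNProfile(profile.grid.subset(mask), profile.log2ratio[mask], profile.meta)


_SEG_COLS = [
    "sample",
    "chrom",
    "start",
    "end",
    "n_probes",
    "mean",
    "state",
    "start_idx",
    "end_idx",
]


def write_segments(segs: SegmentSet, path, format: str = "seg"):
    """Write a SegmentSet as SEG (1-based inclusive) or BED (0-based half-open).

    SEG carries the extra ``state``/``start_idx``/``end_idx`` columns so that
    a SEG round-trip is lossless; BED uses name=state and score=|mean|*1000
    clamped to [0, 1000].
    """
    if format == "seg":
        rows = [
            (
                segs.sample_id,
                s.chrom,
                s.start_pos + 1,
                s.end_pos,
                s.n_probes,
                s.mean,
                s.state,
                s.start_idx,
                s.end_idx,
            )
            for s in segs
        ]
        pd.DataFrame(rows, columns=_SEG_COLS).to_csv(
            path, sep="\t", index=False, float_format=_FLOAT_FMT
        )
    elif format == "bed":
        with open(path, "w") as fh:
            fh.write(f'track name="{segs.sample_id}"\n')
            for s in segs:
                score = int(min(1000, max(0, round(abs(s.mean) * 1000))))
                fh.write(
                    f"{s.chrom}\t{s.start_pos}\t{s.end_pos}\t{s.state}\t{score}\n"
                )
    else:
        raise ValueError(f"unknown segment format {format!r}")


def read_segments(path) -> SegmentSet:
    """Read a SEG file written by :func:`write_segments`."""
    df = pd.read_csv(path, sep="\t")
    if len(df) == 0:
        return SegmentSet(sample_id="", segments=[])
    sample_ids = df["sample"].unique()
    if len(sample_ids) != 1:
        raise ValueError("SEG file must contain exactly one sample")
    segs = [
        Segment(
            chrom=str(r.chrom),
            start_pos=int(r.start) - 1,
            end_pos=int(r.end),
            start_idx=int(r.start_idx),
            end_idx=int(r.end_idx),
            mean=float(r.mean),
            n_probes=int(r.n_probes),
            state=str(r.state),
        )
        for r in df.itertuples()
    ]
    return SegmentSet(sample_id=str(sample_ids[0]), segments=segs)


__all__ = [
    "GAIN",
    "LOSS",
    "NEUTRAL",
    "TISSUES",
    "SUBTYPES",
    "ProbeGrid",
    "SampleMeta",
    "CNProfile",
    "Segment",
    "SegmentSet",
    "PairRecord",
    "PairTable",
    "chrom_sort_key",
    "sort_chromosomes",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_probe_matrix",
    "write_probe_matrix",
    "subset_to_platform",
    "write_segments",
    "read_segments",
]
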