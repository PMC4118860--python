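"""Gaussian kernel-convolution smoothing of probe-level log2 ratios.

Each chromosome is smoothed independently onto a regular evaluation mesh
using a normalised (Nadaraya-Watson) Gaussian kernel,

    s(g) = sum_i w_i x_i / sum_i w_i,   w_i = exp(-(pos_i - g)^2 / (2 sigma^2)),

truncated at ``truncation_sigmas * sigma``. The normalised form is
mean-preserving: constant profiles stay constant, chromosome edges are not
attenuated, and profiles measured at different probe densities (e.g. a dense
platform and its sparse subset) remain directly comparable. Smoothing is
linear in the input, so smoothing and per-pair differencing commute.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core_io import CNProfile, ProbeGrid, sort_chromosomes

logger = logging.getLogger("pairedcna")


@dataclass(frozen=True)
class SmoothParams:
    sigma_bp: float = 1_000_000.0  # kernel scale
    grid_spacing_bp: int | None = None  # default sigma/4
    truncation_sigmas: float = 5.0

    def __post_init__(self):
        if self.sigma_bp <= 0:
            raise ValueError("sigma_bp must be > 0")
        if self.grid_spacing_bp is not None and self.grid_spacing_bp <= 0:
            raise ValueError("grid_spacing_bp must be > 0")
        if self.truncation_sigmas < 3:
            raise ValueError("truncation_sigmas must be >= 3")

    @property
    def spacing(self) -> int:
        return (
            self.grid_spacing_bp
            if self.grid_spacing_bp is not None
            else max(1, int(round(self.sigma_bp / 4)))
        )


@dataclass
class SmoothedProfile:
    """Per-chromosome smoothed signal on a regular grid."""

    sample_id: str
    params: SmoothParams
    chroms: dict  # chrom -> (grid positions, smoothed values)

    def chromosomes(self) -> list:
        return sort_chromosomes(self.chroms.keys())

    def concat(self) -> np.ndarray:
        return np.concatenate([self.chroms[c][1] for c in self.chromosomes()])


def _mesh(pos: np.ndarray, spacing: int) -> np.ndarray:
    """Evaluation mesh covering [0, max pos]: points at (k + 1/2) * spacing."""
    n_pts = int(pos.max() // spacing) + 1
    return (np.arange(n_pts) + 0.5) * spacing


class SmoothingOperator:
    """Precomputed per-chromosome kernel weight matrices for one ProbeGrid.

    Building the operator once and applying it to a whole sample-by-probe
    matrix is the fast path used by cohort-level analyses.
    """

    def __init__(self, grid: ProbeGrid, params: SmoothParams):
        self.grid = grid
        self.params = params
        self.weights = {}  # chrom -> (mesh, row-normalised weight matrix)
        sigma = params.sigma_bp
        cutoff = params.truncation_sigmas * sigma
        if sigma < grid_min_spacing(grid) / 2:
            logger.warning(
                "sigma_bp=%.0f below half the probe spacing: under-smoothing", sigma
            )
        for chrom, sl in grid.chrom_slices().items():
            pos = grid.pos[sl].astype(float)
            if len(pos) < 2:
                raise ValueError(f"chromosome {chrom} has <2 probes")
            mesh = _mesh(pos, params.spacing)
            d = mesh[:, None] - pos[None, :]
            w = np.exp(-0.5 * (d / sigma) ** 2)
            w[np.abs(d) > cutoff] = 0.0
            rowsum = w.sum(axis=1)
            empty = rowsum == 0.0
            if np.any(empty):
                # grid point beyond kernel support of every probe: fall back
                # to its nearest probe
                nearest = np.abs(d[empty]).argmin(axis=1)
                w[np.where(empty)[0], nearest] = 1.0
                rowsum = w.sum(axis=1)
            self.weights[chrom] = (mesh, w / rowsum[:, None])

    def apply(self, values: np.ndarray) -> dict:
        """Smooth one probe-level vector; returns chrom -> (mesh, smoothed)."""
        out = {}
        for chrom, sl in self.grid.chrom_slices().items():
            mesh, w = self.weights[chrom]
            out[chrom] = (mesh, w @ values[sl])
        return out

    def apply_matrix(self, matrix: np.ndarray):
        """Smooth a samples-by-probes matrix; returns (mesh dict, samples x grid)."""
        blocks, meshes = [], {}
        for chrom, sl in self.grid.chrom_slices().items():
            mesh, w = self.weights[chrom]
            meshes[chrom] = mesh
            blocks.append(matrix[:, sl] @ w.T)
        return meshes, np.hstack(blocks)


def grid_min_spacing(grid: ProbeGrid) -> float:
    gaps = [np.diff(grid.pos[sl]).min() for sl in grid.chrom_slices().values()
            if sl.stop - sl.start >= 2]
    return float(min(gaps)) if gaps else np.inf


def smooth_profile(profile: CNProfile, sp: SmoothParams | None = None,
                   operator: SmoothingOperator | None = None) -> SmoothedProfile:
    """Kernel-smooth one profile onto the evaluation mesh.

    A prebuilt :class:`SmoothingOperator` may be supplied to amortise the
    weight computation across samples sharing a grid.
    """
    if operator is None:
        operator = SmoothingOperator(profile.grid, sp or SmoothParams())
    elif not operator.grid.same_coords(profile.grid):
        raise ValueError("operator was built for a different grid")
    return SmoothedProfile(profile.sample_id, operator.params,
                           operator.apply(profile.log2ratio))


def stack_smoothed(profiles) -> tuple:
    """Concatenate smoothed profiles genome-wide (fixed chromosome order).

    Returns ``(sample_ids, chrom_labels, positions, matrix)`` with one row
    per sample; all inputs must share the evaluation grid.
    """
    if not profiles:
        raise ValueError("no smoothed profiles")
    ref = profiles[0]
    order = ref.chromosomes()
    for p in profiles[1:]:
        if p.chromosomes() != order:
            raise ValueError("smoothed profiles have different chromosomes")
        for c in order:
            if not np.array_equal(p.chroms[c][0], ref.chroms[c][0]):
                raise ValueError(f"grid mismatch on {c}")
    chrom_labels = np.concatenate(
        [np.repeat(c, len(ref.chroms[c][0])) for c in order]
    )
    positions = np.concatenate([ref.chroms[c][0] for c in order])
    matrix = np.vstack([p.concat() for p in profiles])
    return [p.sample_id for p in profiles], chrom_labels, positions, matrix


def smooth_cohort(grid: ProbeGrid, profiles, sp: SmoothParams | None = None):
    """Smooth and stack a list of CNProfiles sharing one grid (fast path)."""
    sp = sp or SmoothParams()
    op = SmoothingOperator(grid, sp)
    matrix = np.vstack([p.log2ratio for p in profiles])
    meshes, smoothed = op.apply_matrix(matrix)
    order = sort_chromosomes(meshes.keys())
    chrom_labels = np.concatenate([np.repeat(c, len(meshes[c])) for c in order])
    positions = np.concatenate([meshes[c] for c in order])
    return [p.sample_id for p in profiles], chrom_labels, positions, smoothed


__all__ = [
    "SmoothParams",
    "SmoothedProfile",
    "SmoothingOperator",
    "smooth_profile",
    "stack_smoothed",
    "smooth_cohort",
]
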