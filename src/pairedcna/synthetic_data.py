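"""Synthetic paired tumour / lymph-node-metastasis aCGH cohorts.

Generates probe-level log2-ratio profiles with the statistical structure the
downstream analyses assume, together with full ground truth:

* each patient carries a *clonal* copy-number backbone (piecewise-constant
  log2 means) shared exactly between tumour and LNM;
* divergence between the pair enters only through explicit *private* focal
  events added to one sample, so truth is unambiguous;
* TNBC clones draw more clonal CNAs than ER+ clones (higher genomic
  instability);
* probe noise is i.i.d. Gaussian; occasional "noisy hybridisation" samples
  have their noise SD multiplied;
* optional biphasic tumours mix two molecularly distinct clones in linear
  copy space, with the LNM derived from one component only.

One root seed spawns per-patient child streams, so growing a cohort never
perturbs earlier patients.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .core_io import (
    CNProfile,
    PairTable,
    ProbeGrid,
    SampleMeta,
    write_probe_matrix,
    write_sample_sheet,
)

logger = logging.getLogger("pairedcna")


@dataclass
class SimParams:
    """Generator parameters; defaults are the package's study conditions.

    The default genome is a desk-scale stand-in for a whole-genome tiling
    array: 3 chromosomes x 60 Mb at 25 kb probe spacing (7200 probes).
    ``dense_preset``/``sparse_subset`` below mirror the 720K/135K platform
    relationship at the same scale.
    """

    n_chrom: int = 3
    chrom_length_bp: int = 60_000_000
    probe_spacing_bp: int = 25_000
    # Poisson means of clonal CNA counts; TNBC > ERpos (instability contrast)
    n_cna_mean_per_subtype: dict = field(
        default_factory=lambda: {"TNBC": 12.0, "ERpos": 5.0}
    )
    # log-normal clonal CNA lengths: median exp(15.2) ~ 4 Mb
    cna_length_log_mean: float = 15.2
    cna_length_log_sd: float = 0.8
    # signed log2 amplitudes: |amp| ~ N(0.6, 0.15) clipped at 0.2, sign +/- p_gain
    cna_amp_mean: float = 0.6
    cna_amp_sd: float = 0.15
    cna_min_abs_amp: float = 0.2
    p_gain: float = 0.5
    noise_sd: float = 0.15
    noisy_hyb_sd_multiplier: float = 6.0
    p_noisy_hyb: float = 0.0
    p_private_lnm_event: float = 0.8
    p_private_tumour_event: float = 0.2
    private_event_length_bp: tuple = (300_000, 2_000_000)
    biphasic: bool = False
    mixture_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self):
        for name in ("p_gain", "p_noisy_hyb", "p_private_lnm_event",
                     "p_private_tumour_event", "mixture_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.probe_spacing_bp <= 0:
            raise ValueError("probe_spacing_bp must be > 0")
        if self.noisy_hyb_sd_multiplier < 1.0:
            raise ValueError("noisy_hyb_sd_multiplier must be >= 1")
        if self.cna_amp_mean <= 0 or self.cna_min_abs_amp < 0:
            raise ValueError("amplitude parameters must be positive")
        lo, hi = self.private_event_length_bp
        if not 0 < lo <= hi:
            raise ValueError("private_event_length_bp must be a (lo, hi) range")


def dense_preset(**kw) -> SimParams:
    """720K-like preset: same genome at 5 kb probe spacing."""
    kw.setdefault("probe_spacing_bp", 5_000)
    return SimParams(**kw)


def sparse_subset_ids(grid: ProbeGrid, step: int = 5) -> set:
    """135K-like subset of a dense grid: every ``step``-th probe."""
    return set(grid.probe_id[::step])


@dataclass(frozen=True)
class TrueEvent:
    """A simulated CNA with its exact span and amplitude."""

    chrom: str
    start_idx: int
    end_idx: int  # half-open probe indices into the full grid
    start_pos: int
    end_pos: int
    amplitude: float


@dataclass
class PatientTruth:
    patient_id: str
    subtype: str
    clonal_events: list
    lnm_private: list
    tumour_private: list
    noisy_hyb: str | None = None  # None | "tumour" | "lnm"
    biphasic: bool = False


@dataclass
class CohortTruth:
    """Ground truth for a simulated cohort: clone maps, private events, pairing."""

    patients: list
    pair_table: PairTable
    params: SimParams

    def patient(self, pid: str) -> PatientTruth:
        for p in self.patients:
            if p.patient_id == pid:
                return p
        raise KeyError(pid)


# ---------------------------------------------------------------------------
# Genome and clone construction
# ---------------------------------------------------------------------------


def make_toy_genome(p: SimParams) -> ProbeGrid:
    """Regularly spaced probe grid: first probe at spacing/2 on each chromosome."""
    ids, chroms, poss = [], [], []
    for ci in range(p.n_chrom):
        chrom = f"chr{ci + 1}"
        positions = np.arange(
            p.probe_spacing_bp // 2, p.chrom_length_bp, p.probe_spacing_bp
        )
        if len(positions) < 10:
            raise ValueError(f"{chrom}: fewer than 10 probes ({len(positions)})")
        for k, pos in enumerate(positions):
            ids.append(f"{chrom}_p{k:06d}")
            chroms.append(chrom)
            poss.append(int(pos))
    return ProbeGrid(np.array(ids, dtype=object), np.array(chroms, dtype=object),
                     np.array(poss, dtype=np.int64))


def _draw_amplitude(p: SimParams, rng) -> float:
    mag = max(p.cna_min_abs_amp, rng.normal(p.cna_amp_mean, p.cna_amp_sd))
    sign = 1.0 if rng.random() < p.p_gain else -1.0
    return sign * mag


def _place_event(grid: ProbeGrid, length_bp: float, rng,
                 occupied: list) -> tuple | None:
    """Pick a non-overlapping probe interval of ~length_bp; None if it clashes."""
    n = len(grid)
    start = int(rng.integers(0, n))
    chrom = grid.chrom[start]
    sl = grid.chrom_slices()[chrom]
    end_pos_target = grid.pos[start] + length_bp
    end = start
    while end < sl.stop and grid.pos[end] <= end_pos_target:
        end += 1
    end = min(end, sl.stop)
    if end - start < 1:
        return None
    for (s, e) in occupied:
        if start < e and s < end:
            return None
    return start, end


def simulate_clone(grid: ProbeGrid, subtype: str, p: SimParams, rng):
    """Draw a clonal copy-number backbone for one patient.

    Returns ``(values, events)`` where ``values`` is the true per-probe log2
    mean (background 0) and ``events`` the list of placed :class:`TrueEvent`.
    K ~ Poisson(subtype mean) non-overlapping intervals are drawn; overlaps
    are rejection-resampled with bounded retries (K reduced with a warning if
    placement keeps failing).
    """
    k = int(rng.poisson(p.n_cna_mean_per_subtype[subtype]))
    values = np.zeros(len(grid))
    events = []
    occupied = []
    placed = 0
    attempts = 0
    while placed < k and attempts < 100 * max(k, 1):
        attempts += 1
        length = float(np.exp(rng.normal(p.cna_length_log_mean, p.cna_length_log_sd)))
        spot = _place_event(grid, length, rng, occupied)
        if spot is None:
            continue
        s, e = spot
        amp = _draw_amplitude(p, rng)
        values[s:e] += amp
        occupied.append((s, e))
        events.append(
            TrueEvent(grid.chrom[s], s, e, int(grid.pos[s]),
                      int(grid.pos[e - 1]) + 1, amp)
        )
        placed += 1
    if placed < k:
        logger.warning("clone placement: reduced K from %d to %d", k, placed)
    return values, events


def _draw_private_event(grid: ProbeGrid, p: SimParams, rng) -> tuple:
    lo, hi = p.private_event_length_bp
    while True:
        length = float(rng.uniform(lo, hi))
        spot = _place_event(grid, length, rng, occupied=[])
        if spot is not None:
            s, e = spot
            break
    amp = _draw_amplitude(p, rng)
    return TrueEvent(grid.chrom[s], s, e, int(grid.pos[s]),
                     int(grid.pos[e - 1]) + 1, amp)


def _apply_events(values: np.ndarray, events) -> np.ndarray:
    out = values.copy()
    for ev in events:
        out[ev.start_idx:ev.end_idx] += ev.amplitude
    return out


def simulate_pair(grid: ProbeGrid, clone_values: np.ndarray, p: SimParams, rng,
                  noisy_hyb: str | None = None):
    """Tumour and LNM signals from one clone plus private events and noise.

    Returns ``(tumour_values, lnm_values, lnm_private, tumour_private)``.
    Both samples share the clone exactly; with probability
    ``p_private_lnm_event`` one focal event is added to the LNM only (and
    symmetrically for the tumour). ``noisy_hyb`` multiplies that sample's
    noise SD by ``noisy_hyb_sd_multiplier``.
    """
    lnm_private = [
        _draw_private_event(grid, p, rng)
    ] if rng.random() < p.p_private_lnm_event else []
    tumour_private = [
        _draw_private_event(grid, p, rng)
    ] if rng.random() < p.p_private_tumour_event else []

    tumour_signal = _apply_events(clone_values, tumour_private)
    lnm_signal = _apply_events(clone_values, lnm_private)

    sd_t = p.noise_sd * (p.noisy_hyb_sd_multiplier if noisy_hyb == "tumour" else 1.0)
    sd_l = p.noise_sd * (p.noisy_hyb_sd_multiplier if noisy_hyb == "lnm" else 1.0)
    tumour = tumour_signal + rng.normal(0.0, sd_t, len(grid)) if sd_t > 0 else tumour_signal
    lnm = lnm_signal + rng.normal(0.0, sd_l, len(grid)) if sd_l > 0 else lnm_signal
    return tumour, lnm, lnm_private, tumour_private


def mix_linear(a: np.ndarray, b: np.ndarray, fraction: float) -> np.ndarray:
    """Mix two log2 profiles in linear copy space: log2(f*2^a + (1-f)*2^b)."""
    if fraction == 1.0:
        return a.copy()
    if fraction == 0.0:
        return b.copy()
    return np.log2(fraction * np.exp2(a) + (1.0 - fraction) * np.exp2(b))


def simulate_biphasic_case(grid: ProbeGrid, p: SimParams, rng,
                           subtype: str = "TNBC"):
    """A tumour composed of two molecularly distinct components.

    Two independent clones A and B are drawn; the bulk tumour is their linear
    copy-space mixture and the LNM descends from clone A only. The two
    component signals are returned separately (emulating separate
    re-hybridisation of the dissected components).

    Returns ``(tumour, lnm, component_a, component_b, truth)`` where the
    first four are noisy per-probe value arrays.
    """
    clone_a, events_a = simulate_clone(grid, subtype, p, rng)
    clone_b, events_b = simulate_clone(grid, subtype, p, rng)
    mixture = mix_linear(clone_a, clone_b, p.mixture_fraction)

    def noisy(sig):
        return sig + rng.normal(0.0, p.noise_sd, len(grid)) if p.noise_sd > 0 else sig.copy()

    truth = {
        "events_a": events_a,
        "events_b": events_b,
        "mixture_fraction": p.mixture_fraction,
    }
    return noisy(mixture), noisy(clone_a), noisy(clone_a), noisy(clone_b), truth


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RecurrentInjection:
    """A recurrent differential CNA added to every LNM (power testing)."""

    chrom: str
    start_pos: int
    end_pos: int
    amplitude: float

    def as_event(self, grid: ProbeGrid) -> TrueEvent:
        sl = grid.chrom_slices()[self.chrom]
        pos = grid.pos[sl]
        s = sl.start + int(np.searchsorted(pos, self.start_pos, side="left"))
        e = sl.start + int(np.searchsorted(pos, self.end_pos, side="left"))
        if e - s < 1:
            raise ValueError("injected region covers no probes")
        return TrueEvent(self.chrom, s, e, int(grid.pos[s]),
                         int(grid.pos[e - 1]) + 1, self.amplitude)


def simulate_cohort(n_tnbc: int = 10, n_erpos: int = 10,
                    p: SimParams | None = None,
                    inject_recurrent: RecurrentInjection | None = None,
                    noisy_patients: dict | None = None):
    """Simulate a paired cohort (default 10 TNBC + 10 ER+ pairs).

    ``noisy_patients`` maps patient_id -> "tumour"|"lnm" to force noisy
    hybridisations; otherwise each pair is noisy with ``p_noisy_hyb`` on a
    random side. ``inject_recurrent`` adds the same event to every LNM.

    Returns ``(grid, profiles, pair_table, truth)``; fully reproducible from
    ``p.seed``.
    """
    p = p if p is not None else SimParams()
    grid = make_toy_genome(p)
    root = np.random.SeedSequence(p.seed)
    subtypes = ["TNBC"] * n_tnbc + ["ERpos"] * n_erpos
    children = root.spawn(len(subtypes))
    injected = inject_recurrent.as_event(grid) if inject_recurrent else None
    noisy_patients = noisy_patients or {}

    profiles, metas, patients = [], [], []
    n_by_subtype = {"TNBC": 0, "ERpos": 0}
    for subtype, child in zip(subtypes, children):
        n_by_subtype[subtype] += 1
        pid = f"{'TN' if subtype == 'TNBC' else 'ER'}{n_by_subtype[subtype]:02d}"
        rng = np.random.default_rng(child)
        clone, clonal_events = simulate_clone(grid, subtype, p, rng)
        if pid in noisy_patients:
            noisy = noisy_patients[pid]
        elif rng.random() < p.p_noisy_hyb:
            noisy = "tumour" if rng.random() < 0.5 else "lnm"
        else:
            noisy = None
        tum, lnm, lnm_priv, tum_priv = simulate_pair(grid, clone, p, rng, noisy)
        if injected is not None:
            lnm = _apply_events(lnm, [injected])
            lnm_priv = list(lnm_priv) + [injected]
        meta_t = SampleMeta(f"{pid}_T", pid, "tumour", subtype)
        meta_l = SampleMeta(f"{pid}_L", pid, "lnm", subtype)
        profiles += [CNProfile(grid, tum, meta_t), CNProfile(grid, lnm, meta_l)]
        metas += [meta_t, meta_l]
        patients.append(
            PatientTruth(pid, subtype, clonal_events, lnm_priv, tum_priv, noisy)
        )
    pair_table = PairTable.from_samples(metas)
    truth = CohortTruth(patients, pair_table, p)
    return grid, profiles, pair_table, truth


def write_cohort(grid, profiles, truth: CohortTruth, outdir):
    """Write matrix TSV + sample sheet + truth JSON into ``outdir``."""
    import os

    os.makedirs(outdir, exist_ok=True)
    write_probe_matrix(grid, profiles, os.path.join(outdir, "probe_matrix.tsv"))
    write_sample_sheet([pr.meta for pr in profiles],
                       os.path.join(outdir, "sample_sheet.tsv"))

    def ev(e: TrueEvent):
        return {
            "chrom": e.chrom, "start_idx": int(e.start_idx),
            "end_idx": int(e.end_idx), "start_pos": int(e.start_pos),
            "end_pos": int(e.end_pos), "amplitude": float(e.amplitude),
        }

    payload = {
        "params": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(truth.params).items()},
        "patients": [
            {
                "patient_id": t.patient_id,
                "subtype": t.subtype,
                "noisy_hyb": t.noisy_hyb,
                "biphasic": t.biphasic,
                "clonal_events": [ev(e) for e in t.clonal_events],
                "lnm_private": [ev(e) for e in t.lnm_private],
                "tumour_private": [ev(e) for e in t.tumour_private],
            }
            for t in truth.patients
        ],
    }
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump(payload, fh, indent=1)


__all__ = [
    "SimParams",
    "TrueEvent",
    "PatientTruth",
    "CohortTruth",
    "RecurrentInjection",
    "make_toy_genome",
    "simulate_clone",
    "simulate_pair",
    "simulate_biphasic_case",
    "simulate_cohort",
    "mix_linear",
    "dense_preset",
    "sparse_subset_ids",
    "write_cohort",
]
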