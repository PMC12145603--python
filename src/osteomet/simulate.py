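"""Synthetic cohort generator.

Emulates the study design: 3 donors, CTR vs OI arms, cells sampled in
triplicate on D0/D1/D4/D7/D14/D21 and conditioned media on
D1/D4/D7/D11/D14/D18/D21 with media exchanges on D0/D4/D7/D11/D14/D18/D21,
fresh-medium (blank) spectra per exchange batch, donor-specific baseline
offsets on confounder metabolites, planted signature effects, chemical-shift
jitter, and the study's missing-replicate pattern.

Spectra are sums of bin-integrated Lorentzian multiplets (the exact integral
of each line over every grid cell), a TSP reference singlet at 0.00 ppm and
additive Gaussian noise.  Everything is driven by one seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import Spectrum, SpectrumSet
from .library import (
    ARMS, CELL_DAYS, EXCHANGE_DAYS, MEDIA_DAYS, SPECTROMETER_MHZ,
    MetaboliteLibrary, build_default_library, integrate_profile,
    media_cumulative,
)

__all__ = [
    "CohortConfig", "GroundTruth", "simulate_cohort", "simulate_tables",
    "default_missing_pattern", "render_peaks", "build_default_library",
]


def default_missing_pattern() -> list[tuple]:
    """The study's missing-replicate groups:
    (donor, arm, day, compartment, n_available)."""
    return [
        (1, "CTR", 0, "cell", 2),
        (1, "OI", 7, "media", 0),
        (2, "CTR", 7, "media", 2),
        (2, "CTR", 18, "media", 2),
        (2, "OI", 11, "media", 2),
        (2, "OI", 21, "media", 1),
        (2, "OI", 21, "cell", 1),
    ]


@dataclass
class CohortConfig:
    n_donors: int = 3
    replicates: int = 3
    cell_days: tuple = CELL_DAYS
    media_days: tuple = MEDIA_DAYS
    exchange_days: tuple = EXCHANGE_DAYS
    arms: tuple = ARMS
    ppm_range: tuple = (-0.5, 10.0)
    n_points: int = 8192
    noise_sd: float = 1.0              # additive spectral noise, a.u.
    shift_jitter_sd: float = 0.0015    # per-metabolite ppm jitter
    global_shift_sd: float = 0.003     # whole-spectrum ppm shift (TSP too)
    bio_cv: float = 0.08               # lognormal replicate variability
    blank_cv: float = 0.01             # batch-to-batch blank variability
    n_blank_replicates: int = 3
    tsp_area: float = 50.0
    spectrometer_mhz: float = SPECTROMETER_MHZ
    missing_pattern: list = field(default_factory=default_missing_pattern)
    seed: int = 0

    def __post_init__(self):
        horizon = 21.0
        if max(self.cell_days) > horizon or max(self.media_days) > horizon:
            raise ValueError("configured days outside the simulation horizon")
        if min(self.media_days) <= min(self.exchange_days):
            raise ValueError("first media sampling precedes any media exchange")

    def grid(self) -> np.ndarray:
        return np.linspace(self.ppm_range[0], self.ppm_range[1], self.n_points)


@dataclass
class GroundTruth:
    planted_signature: pd.DataFrame   # metabolite, compartment, direction, ...
    true_values: pd.DataFrame         # per-sample true integrals (cells+media)


# ---------------------------------------------------------------------------
# rendering

def render_peaks(ppm: np.ndarray, centers, areas, widths_hz,
                 spectrometer_mhz: float = SPECTROMETER_MHZ) -> np.ndarray:
    """Sum of Lorentzians rendered as exact per-cell integrals.

    Each grid cell receives area/(pi) * [atan((e2-c)/hw) - atan((e1-c)/hw)]
    divided by the cell width, so trapezoidal integration of the output
    recovers each line's closed-form area within the grid range.
    """
    centers = np.asarray(centers, dtype=float)
    areas = np.asarray(areas, dtype=float)
    hw = np.asarray(widths_hz, dtype=float) / spectrometer_mhz / 2.0  # half-width, ppm
    dx = ppm[1] - ppm[0]
    edges = np.concatenate([ppm - dx / 2.0, [ppm[-1] + dx / 2.0]])
    # (n_peaks, n_edges) arctan table
    z = (edges[None, :] - centers[:, None]) / hw[:, None]
    at = np.arctan(z)
    cell = (at[:, 1:] - at[:, :-1]) / np.pi
    return (areas[:, None] * cell).sum(axis=0) / dx


def _n_available(cfg: CohortConfig, donor, arm, day, compartment) -> int:
    for (d, a, dy, comp, n) in cfg.missing_pattern or []:
        if (d, a, dy, comp) == (donor, arm, day, compartment):
            return int(n)
    return cfg.replicates


# ---------------------------------------------------------------------------
# ground-truth concentrations

def _cell_conc(lib, donor, arm, day, rng, bio_cv):
    out = {}
    for m in lib:
        if m.baseline_level <= 0:
            continue
        mu = (m.baseline_level * m.donor_offset(donor)
              * m.multiplier(arm, "cell", day))
        out[m.name] = mu * float(np.exp(rng.normal(0.0, bio_cv))) if bio_cv > 0 else mu
    return out


def _prev_exchange(day, exchange_days):
    candidates = [e for e in exchange_days if e < day]
    if not candidates:
        raise ValueError(f"no media exchange precedes sampling day {day}")
    return max(candidates)


def _media_value(m, donor, arm, day, blank_value, exchange_days, rng, bio_cv):
    """Blank composition plus signed cumulative footprint since last exchange."""
    beh = m.media_behavior
    if beh.sign == 0.0 or beh.rate == 0.0:
        return blank_value
    prev = _prev_exchange(day, exchange_days)
    weight = integrate_profile(m.effect_profiles.get((arm, "media")), prev, day)
    delta = beh.sign * beh.rate * m.media_rate_offset(donor) * weight
    if bio_cv > 0:
        delta *= float(np.exp(rng.normal(0.0, bio_cv)))
    return max(blank_value + delta, 0.0)


def _render_sample(lib, values: dict, cfg: CohortConfig, ppm, rng,
                   noise: bool = True) -> np.ndarray:
    centers, areas, widths = [], [], []
    g = rng.normal(0.0, cfg.global_shift_sd) if cfg.global_shift_sd > 0 else 0.0
    for m in lib:
        v = values.get(m.name, 0.0)
        if v <= 0:
            continue
        jit = (rng.normal(0.0, cfg.shift_jitter_sd)
               if cfg.shift_jitter_sd > 0 else 0.0)
        for mult in m.multiplets:
            centers.append(mult.center + g + jit)
            areas.append(v * mult.rel_area)
            widths.append(mult.width_hz)
    if cfg.tsp_area > 0:
        centers.append(0.0 + g)
        areas.append(cfg.tsp_area)
        widths.append(1.2)
    y = render_peaks(ppm, centers, areas, widths, cfg.spectrometer_mhz)
    if noise and cfg.noise_sd > 0:
        y = y + rng.normal(0.0, cfg.noise_sd, size=ppm.size)
    return y


# ---------------------------------------------------------------------------
# planted-signature bookkeeping

def planted_signature(lib: MetaboliteLibrary, cfg: CohortConfig,
                      tol: float = 1e-9) -> pd.DataFrame:
    rows = []
    final_cell = max(cfg.cell_days)
    for m in lib:
        # intracellular: direct multiplier contrast
        if m.baseline_level > 0:
            ratio = (m.multiplier("OI", "cell", final_cell)
                     / m.multiplier("CTR", "cell", final_cell))
            if abs(ratio - 1.0) > tol:
                onset = next(d for d in cfg.cell_days
                             if abs(m.multiplier("OI", "cell", d)
                                    / m.multiplier("CTR", "cell", d) - 1) > tol)
                rows.append((m.name, "cell",
                             "up" if ratio > 1 else "down", onset,
                             100.0 * (ratio - 1.0)))
        # extracellular: cumulative exchange-referenced trajectory contrast
        beh = m.media_behavior
        if beh.sign != 0.0 and beh.rate > 0:
            oi = m.effect_profiles.get(("OI", "media"))
            ctr = m.effect_profiles.get(("CTR", "media"))
            c_oi = media_cumulative(oi, cfg.media_days, cfg.exchange_days)
            c_ctr = media_cumulative(ctr, cfg.media_days, cfg.exchange_days)
            if abs(c_oi / c_ctr - 1.0) > tol:
                onset = next(
                    d for d in cfg.media_days
                    if abs(media_cumulative(oi, cfg.media_days,
                                            cfg.exchange_days, through_day=d)
                           / media_cumulative(ctr, cfg.media_days,
                                              cfg.exchange_days, through_day=d)
                           - 1.0) > tol)
                rows.append((m.name, "media",
                             "up" if c_oi > c_ctr else "down", onset,
                             100.0 * (c_oi / c_ctr - 1.0)))
    return pd.DataFrame(rows, columns=["metabolite", "compartment",
                                       "direction", "onset_day",
                                       "magnitude_pct"])


# ---------------------------------------------------------------------------
# cohort simulation

def simulate_cohort(library: MetaboliteLibrary | None = None,
                    config: CohortConfig | None = None):
    """Simulate (cells, media, blanks, ground_truth) for one cohort.

    Identical (library, config, seed) give identical output arrays.
    """
    lib = library if library is not None else build_default_library()
    cfg = config if config is not None else CohortConfig()
    if len(lib) == 0:
        raise ValueError("empty metabolite library")
    rng = np.random.default_rng(cfg.seed)
    ppm = cfg.grid()
    donors = list(range(1, cfg.n_donors + 1))

    # fresh-medium batch composition, one draw per exchange day
    exo_names = lib.exometabolites()
    blank_batches = {}
    for e in cfg.exchange_days:
        blank_batches[e] = {
            m.name: m.media_behavior.blank_level
            * (float(np.exp(rng.normal(0.0, cfg.blank_cv)))
               if cfg.blank_cv > 0 else 1.0)
            for m in lib if m.name in exo_names}

    truth_rows = []
    cell_rows, cell_meta = [], []
    for donor in donors:
        for arm in cfg.arms:
            for day in cfg.cell_days:
                n = _n_available(cfg, donor, arm, day, "cell")
                for rep in range(1, n + 1):
                    conc = _cell_conc(lib, donor, arm, day, rng, cfg.bio_cv)
                    sid = f"cell-d{donor}-{arm}-D{day}-r{rep}"
                    cell_rows.append(_render_sample(lib, conc, cfg, ppm, rng))
                    cell_meta.append((sid, donor, arm, day, rep, "cell"))
                    truth_rows.append({"sample_id": sid, **conc})

    media_rows, media_meta = [], []
    for donor in donors:
        for arm in cfg.arms:
            for day in cfg.media_days:
                n = _n_available(cfg, donor, arm, day, "media")
                for rep in range(1, n + 1):
                    prev = _prev_exchange(day, cfg.exchange_days)
                    vals = {name: _media_value(lib[name], donor, arm, day,
                                               blank_batches[prev][name],
                                               cfg.exchange_days, rng,
                                               cfg.bio_cv)
                            for name in exo_names}
                    sid = f"media-d{donor}-{arm}-D{day}-r{rep}"
                    media_rows.append(_render_sample(lib, vals, cfg, ppm, rng))
                    media_meta.append((sid, donor, arm, day, rep, "media"))
                    truth_rows.append({"sample_id": sid, **vals})

    blank_rows, blank_meta = [], []
    for e in cfg.exchange_days:
        for rep in range(1, cfg.n_blank_replicates + 1):
            vals = blank_batches[e]
            sid = f"blank-D{e}-r{rep}"
            blank_rows.append(_render_sample(lib, vals, cfg, ppm, rng))
            blank_meta.append((sid, 0, "", e, rep, "blank"))
            truth_rows.append({"sample_id": sid, **vals})

    cols = ["sample_id", "donor", "arm", "day", "replicate", "compartment"]
    cells = SpectrumSet(ppm, np.vstack(cell_rows),
                        pd.DataFrame(cell_meta, columns=cols))
    media = SpectrumSet(ppm, np.vstack(media_rows),
                        pd.DataFrame(media_meta, columns=cols))
    blanks = SpectrumSet(ppm, np.vstack(blank_rows),
                         pd.DataFrame(blank_meta, columns=cols))
    truth = GroundTruth(
        planted_signature=planted_signature(lib, cfg),
        true_values=pd.DataFrame(truth_rows).set_index("sample_id"),
    )
    return cells, media, blanks, truth


# ---------------------------------------------------------------------------
# integral-table fast path (no spectral rendering)

def simulate_tables(library: MetaboliteLibrary | None = None,
                    config: CohortConfig | None = None) -> dict:
    """Simulate the cohort directly at integral-table level.

    Returns a dict with:

    ``cells``       total-sum-normalized endometabolite table (+ meta columns)
    ``media_long``  long table (sample_id, donor, arm, day, replicate,
                    variable, raw, total_area)
    ``blanks``      long blank table (day = sampling day it applies to,
                    variable, value) ready for the exchange correction
    ``truth``       GroundTruth

    Equivalent in design (not in bytes) to rendering spectra, preprocessing
    and integrating; used where spectral detail is irrelevant.
    """
    lib = library if library is not None else build_default_library()
    cfg = config if config is not None else CohortConfig()
    rng = np.random.default_rng(cfg.seed)
    donors = list(range(1, cfg.n_donors + 1))
    exo_names = lib.exometabolites()

    blank_batches = {}
    for e in cfg.exchange_days:
        blank_batches[e] = {
            m.name: m.media_behavior.blank_level
            * (float(np.exp(rng.normal(0.0, cfg.blank_cv)))
               if cfg.blank_cv > 0 else 1.0)
            for m in lib if m.name in exo_names}

    cell_recs = []
    for donor in donors:
        for arm in cfg.arms:
            for day in cfg.cell_days:
                n = _n_available(cfg, donor, arm, day, "cell")
                for rep in range(1, n + 1):
                    conc = _cell_conc(lib, donor, arm, day, rng, cfg.bio_cv)
                    sid = f"cell-d{donor}-{arm}-D{day}-r{rep}"
                    cell_recs.append({"sample_id": sid, "donor": donor,
                                      "arm": arm, "day": day,
                                      "replicate": rep, **conc})
    cells = pd.DataFrame(cell_recs)
    met_cols = [c for c in cells.columns
                if c not in ("sample_id", "donor", "arm", "day", "replicate")]
    cells[met_cols] = cells[met_cols].div(cells[met_cols].sum(axis=1), axis=0)

    media_recs = []
    for donor in donors:
        for arm in cfg.arms:
            for day in cfg.media_days:
                n = _n_available(cfg, donor, arm, day, "media")
                for rep in range(1, n + 1):
                    prev = _prev_exchange(day, cfg.exchange_days)
                    vals = {name: _media_value(lib[name], donor, arm, day,
                                               blank_batches[prev][name],
                                               cfg.exchange_days, rng,
                                               cfg.bio_cv)
                            for name in exo_names}
                    ta = sum(vals.values())
                    sid = f"media-d{donor}-{arm}-D{day}-r{rep}"
                    for name, v in vals.items():
                        media_recs.append({
                            "sample_id": sid, "donor": donor, "arm": arm,
                            "day": day, "replicate": rep, "variable": name,
                            "raw": v, "total_area": ta})
    media_long = pd.DataFrame(media_recs)

    blank_recs = []
    for day in cfg.media_days:
        prev = _prev_exchange(day, cfg.exchange_days)
        for name in exo_names:
            blank_recs.append({"day": day, "variable": name,
                               "value": blank_batches[prev][name]})
    blanks = pd.DataFrame(blank_recs)

    truth = GroundTruth(planted_signature=planted_signature(lib, cfg),
                        true_values=cells.set_index("sample_id")[met_cols])
    return {"cells": cells, "media_long": media_long, "blanks": blanks,
            "truth": truth}
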