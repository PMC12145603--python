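"""Synthetic metabolite library for the hAMSC osteodifferentiation cohort.

Each :class:`MetaboliteSpec` describes a metabolite as a set of Lorentzian
multiplets (ppm center, relative area, FWHM in Hz), an intracellular
baseline level, a fresh-medium (blank) level with an uptake/secretion rate,
per-donor multiplicative offsets for donor-sensitive species, and
time-course effect multipliers per (arm, compartment).

Effect multipliers are piecewise-linear in time.  Intracellular effects act
directly on concentration; extracellular effects act on the uptake/secretion
*rate*, so their footprint accumulates between media exchanges.  The default
library plants, at the stated magnitudes:

* the 9-endometabolite osteogenic signature (Cho, Etn, UDP-GlcNAc,
  UDP-GalNAc and the unassigned singlet U3.48 up by more than 80 % at day
  21; ADP, MG, PCho and PCr down) with onset around day 4;
* the 14-endometabolite proliferation signature (HTau, MG, GPC, PEtn, Ino
  up by more than 85 % over 21 days in both arms; ADP and ATP down by more
  than 55 %; Asp, Pro, GSH, Ile, Leu, Val and PCho modulated mildly);
* the 17-exometabolite osteogenic signature (reduced uptake of Gln, Ile,
  Leu, Val, 2-HIBA, Pyr, Glc; increased secretion of 3-HBA, Orn, PyroGlu,
  Lac; reduced secretion of 3-HIBA, a-KG, Cit; donor-dependent patterns but
  donor-independent end levels for Ala, Cho, His), expressed as the relative
  change of the cumulative, exchange-corrected trajectory at day 21;
* donor-dependent confounders (glycerol, GPC, formate, Cr, Tau, 2-HIC, Lac,
  acetate, acetone, Glu, Gly) whose offsets make full-spectrum PCA group by
  donor.

Chemical shifts are approximate literature values; a few crowded resonances
(choline head groups, the creatine region) are spaced slightly wider than in
real spectra so that the default integration windows stay resolvable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

SPECTROMETER_MHZ = 500.13

ARMS = ("CTR", "OI")

#: media sampling days and media-exchange days of the study design
CELL_DAYS = (0, 1, 4, 7, 14, 21)
MEDIA_DAYS = (1, 4, 7, 11, 14, 18, 21)
EXCHANGE_DAYS = (0, 4, 7, 11, 14, 18, 21)

ENDO_SIGNATURE_UP = ("Cho", "Etn", "UDP-GlcNAc", "UDP-GalNAc", "U3.48")
ENDO_SIGNATURE_DOWN = ("ADP", "MG", "PCho", "PCr")
ENDO_SIGNATURE = ENDO_SIGNATURE_UP + ENDO_SIGNATURE_DOWN

PROLIF_SIGNATURE_UP = ("HTau", "MG", "GPC", "PEtn", "Ino")
PROLIF_SIGNATURE_DOWN = ("ADP", "ATP")
PROLIF_SIGNATURE_MODULATED = ("Asp", "Pro", "GSH", "Ile", "Leu", "Val", "PCho")
PROLIF_SIGNATURE = (PROLIF_SIGNATURE_UP + PROLIF_SIGNATURE_DOWN
                    + PROLIF_SIGNATURE_MODULATED)

EXO_REDUCED_UPTAKE = ("Gln", "Ile", "Leu", "Val", "2-HIBA", "Pyr", "Glc")
EXO_INCREASED_SECRETION = ("3-HBA", "Orn", "PyroGlu", "Lac")
EXO_REDUCED_SECRETION = ("3-HIBA", "a-KG", "Cit")
EXO_DI_END_LEVEL = ("Ala", "Cho", "His")
EXO_SIGNATURE = (EXO_REDUCED_UPTAKE + EXO_INCREASED_SECRETION
                 + EXO_REDUCED_SECRETION + EXO_DI_END_LEVEL)

CONFOUNDERS = ("glycerol", "GPC", "formate", "Cr", "Tau", "2-HIC", "Lac",
               "acetate", "acetone", "Glu", "Gly")


@dataclass
class Multiplet:
    center: float        # ppm
    rel_area: float      # fraction of the metabolite's total area
    width_hz: float = 1.5  # FWHM


@dataclass
class MediaBehavior:
    mode: str = "inert"          # 'uptaken' | 'secreted' | 'inert'
    rate: float = 0.0            # area units per day, always >= 0
    blank_level: float = 0.0     # level in fresh medium

    def __post_init__(self):
        if self.mode not in ("uptaken", "secreted", "inert"):
            raise ValueError(f"unknown media mode {self.mode!r}")
        if self.rate < 0 or self.blank_level < 0:
            raise ValueError("rate and blank_level must be >= 0")

    @property
    def sign(self) -> float:
        return {"uptaken": -1.0, "secreted": 1.0, "inert": 0.0}[self.mode]


@dataclass
class MetaboliteSpec:
    name: str
    multiplets: list[Multiplet]
    baseline_level: float = 0.0                       # intracellular, a.u.
    donor_offsets: dict[int, float] | None = None     # multiplicative
    # (arm, compartment) -> piecewise-linear breakpoints [(day, multiplier)]
    effect_profiles: dict[tuple[str, str], list[tuple[float, float]]] = field(
        default_factory=dict)
    media_behavior: MediaBehavior = field(default_factory=MediaBehavior)
    # per-donor multiplicative offsets applied to the media rate
    media_rate_offsets: dict[int, float] | None = None

    def __post_init__(self):
        total = sum(m.rel_area for m in self.multiplets)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"{self.name}: multiplet rel_areas sum to {total}")
        if any(m.width_hz <= 0 for m in self.multiplets):
            raise ValueError(f"{self.name}: widths must be > 0")
        if self.baseline_level < 0:
            raise ValueError(f"{self.name}: baseline_level must be >= 0")

    def multiplier(self, arm: str, compartment: str, day: float) -> float:
        """Effect multiplier at `day`; identity when no profile is set."""
        bps = self.effect_profiles.get((arm, compartment))
        return eval_profile(bps, day)

    def donor_offset(self, donor: int) -> float:
        return 1.0 if not self.donor_offsets else self.donor_offsets.get(donor, 1.0)

    def media_rate_offset(self, donor: int) -> float:
        if not self.media_rate_offsets:
            return 1.0
        return self.media_rate_offsets.get(donor, 1.0)


def eval_profile(bps: list[tuple[float, float]] | None, day: float) -> float:
    if not bps:
        return 1.0
    days = [b[0] for b in bps]
    vals = [b[1] for b in bps]
    return float(np.interp(day, days, vals))


def integrate_profile(bps: list[tuple[float, float]] | None,
                      a: float, b: float) -> float:
    """Exact integral of a piecewise-linear multiplier over [a, b]."""
    if a > b:
        raise ValueError("empty integration interval")
    if not bps:
        return b - a
    knots = sorted({a, b, *[d for d, _ in bps if a < d < b]})
    total = 0.0
    for lo, hi in zip(knots[:-1], knots[1:]):
        total += 0.5 * (eval_profile(bps, lo) + eval_profile(bps, hi)) * (hi - lo)
    return total


def compose_profiles(bps1, bps2) -> list[tuple[float, float]]:
    """Pointwise product of two piecewise-linear profiles, re-sampled at the
    union of their knots (the product is then stored piecewise-linearly)."""
    knots = sorted({d for d, _ in (bps1 or [(0.0, 1.0)])}
                   | {d for d, _ in (bps2 or [(0.0, 1.0)])})
    return [(d, eval_profile(bps1, d) * eval_profile(bps2, d)) for d in knots]


# ---------------------------------------------------------------------------
# profile builders

def ramp(mag_pct: float, onset: float = 0.0, end: float = 21.0):
    """Multiplier ramping linearly from 1 at `onset` to 1 + mag/100 at `end`."""
    out = [(0.0, 1.0)]
    if onset > 0:
        out.append((float(onset), 1.0))
    out.append((float(end), 1.0 + mag_pct / 100.0))
    return out


def media_cumulative(bps, media_days=MEDIA_DAYS, exchange_days=EXCHANGE_DAYS,
                     through_day: float | None = None) -> float:
    """Cumulative exchange-referenced footprint weight up to `through_day`.

    Mirrors the correction recursion: each sampling day contributes the
    integral of the rate multiplier since the last exchange strictly before
    that day.
    """
    last = media_days[-1] if through_day is None else through_day
    total = 0.0
    for d in media_days:
        if d > last:
            break
        prev = max(e for e in exchange_days if e < d)
        total += integrate_profile(bps, prev, d)
    return total


def media_step(target_pct: float, onset: float = 4.0, ramp_days: float = 1.0,
               media_days=MEDIA_DAYS, exchange_days=EXCHANGE_DAYS):
    """Rate multiplier (step at `onset`, short linear ramp) whose cumulative
    trajectory at the final sampling day differs from control by
    `target_pct` percent.  The step factor is solved from the sampling /
    exchange schedule, under which the cumulative weight is affine in it.
    """
    def prof(f):
        return [(0.0, 1.0), (float(onset), 1.0),
                (float(onset + ramp_days), f), (21.0, f)]

    c1 = media_cumulative(prof(1.0), media_days, exchange_days)
    c2 = media_cumulative(prof(2.0), media_days, exchange_days)
    target = c1 * (1.0 + target_pct / 100.0)
    f = 1.0 + (target - c1) / (c2 - c1)
    if f < 0:
        raise ValueError("target change too large for a nonnegative rate")
    return prof(f)


# ---------------------------------------------------------------------------
# default library

def _m(name, peaks, cell=0.0, offsets=None, mode="inert", rate=0.0, blank=0.0,
       rate_offsets=None, prolif=None, osteo_cell=None, exo_pct=None,
       exo_onset=4.0):
    """Assemble one MetaboliteSpec from compact arguments.

    prolif      -- %-change over D0..D21 in *both* arms (cells)
    osteo_cell  -- extra %-change of the OI arm vs CTR (cells), onset D4
    exo_pct     -- %-change of the OI cumulative media trajectory at D21
    """
    mults = [Multiplet(c, a, w) for c, a, w in peaks]
    profiles = {}
    ctr_bps = ramp(prolif, onset=0.0) if prolif else None
    if ctr_bps:
        profiles[("CTR", "cell")] = ctr_bps
    if osteo_cell:
        oi_extra = ramp(osteo_cell, onset=4.0)
        profiles[("OI", "cell")] = (compose_profiles(ctr_bps, oi_extra)
                                    if ctr_bps else oi_extra)
    elif ctr_bps:
        profiles[("OI", "cell")] = list(ctr_bps)
    if exo_pct:
        profiles[("OI", "media")] = media_step(exo_pct, onset=exo_onset)
    return MetaboliteSpec(
        name=name, multiplets=mults, baseline_level=cell,
        donor_offsets=offsets,
        media_behavior=MediaBehavior(mode=mode, rate=rate, blank_level=blank),
        media_rate_offsets=rate_offsets, effect_profiles=profiles)


@dataclass
class MetaboliteLibrary:
    metabolites: list[MetaboliteSpec]

    def __post_init__(self):
        names = [m.name for m in self.metabolites]
        if len(set(names)) != len(names):
            raise ValueError("duplicate metabolite names")
        self._by_name = {m.name: m for m in self.metabolites}

    def __getitem__(self, name: str) -> MetaboliteSpec:
        return self._by_name[name]

    def __contains__(self, name) -> bool:
        return name in self._by_name

    def __iter__(self):
        return iter(self.metabolites)

    def __len__(self):
        return len(self.metabolites)

    @property
    def names(self) -> list[str]:
        return [m.name for m in self.metabolites]

    def endometabolites(self) -> list[str]:
        return [m.name for m in self.metabolites if m.baseline_level > 0]

    def exometabolites(self) -> list[str]:
        return [m.name for m in self.metabolites
                if m.media_behavior.blank_level > 0 or m.media_behavior.rate > 0]


def build_default_library() -> MetaboliteLibrary:
    """The study-design library: >=30 endometabolites, >=20 exometabolites,
    planted proliferation / osteogenic signatures and donor confounders."""
    up = "secreted"
    dn = "uptaken"
    mets = [
        # --- 9-endometabolite osteogenic signature ------------------------
        _m("Cho", [(3.190, 1.0, 1.2)], cell=1.0, osteo_cell=150,
           mode=dn, rate=0.05, blank=1.2, exo_pct=-40,
           rate_offsets={1: 1.3, 2: 0.8, 3: 1.0}),
        _m("Etn", [(3.130, 0.6, 1.5), (3.820, 0.4, 1.5)], cell=0.8,
           osteo_cell=110),
        _m("UDP-GlcNAc", [(5.510, 0.5, 1.5), (2.070, 0.5, 1.5)], cell=0.9,
           osteo_cell=150),
        _m("UDP-GalNAc", [(5.550, 0.5, 1.5), (2.020, 0.5, 1.5)], cell=0.7,
           osteo_cell=120),
        _m("U3.48", [(3.480, 1.0, 1.3)], cell=0.8, osteo_cell=110),
        _m("ADP", [(8.510, 0.6, 1.8), (6.125, 0.4, 1.8)], cell=0.6,
           prolif=-60, osteo_cell=-50),
        _m("MG", [(2.830, 1.0, 1.3)], cell=0.5, prolif=130, osteo_cell=-60),
        _m("PCho", [(3.220, 0.7, 1.2), (4.170, 0.3, 1.5)], cell=1.2,
           prolif=25, osteo_cell=-40),
        _m("PCr", [(3.075, 0.6, 1.3), (3.955, 0.4, 1.5)], cell=0.9,
           osteo_cell=-55),
        # --- remaining proliferation signature ----------------------------
        _m("HTau", [(2.640, 1.0, 1.5)], cell=0.8, prolif=140),
        _m("GPC", [(3.250, 1.0, 1.2)], cell=1.5, prolif=125,
           offsets={1: 0.4, 2: 1.0, 3: 1.1}),
        _m("PEtn", [(3.980, 1.0, 1.5)], cell=1.0, prolif=125),
        _m("Ino", [(6.100, 0.5, 1.6), (8.340, 0.5, 1.6)], cell=0.5,
           prolif=135),
        _m("ATP", [(8.545, 0.6, 1.8), (6.170, 0.4, 1.8)], cell=0.8,
           prolif=-60),
        _m("Asp", [(2.805, 0.5, 1.6), (2.680, 0.5, 1.6)], cell=2.0,
           prolif=15),
        _m("Pro", [(2.000, 0.6, 1.6), (4.130, 0.4, 1.6)], cell=1.5,
           prolif=-15),
        _m("GSH", [(2.950, 1.0, 1.6)], cell=2.0, prolif=-25),
        _m("Ile", [(0.990, 1.0, 1.5)], cell=1.0, prolif=-20,
           mode=dn, rate=0.06, blank=1.2, exo_pct=-50),
        _m("Leu", [(0.950, 1.0, 1.5)], cell=1.5, prolif=-20,
           mode=dn, rate=0.08, blank=1.5, exo_pct=-50),
        _m("Val", [(1.035, 1.0, 1.5)], cell=1.2, prolif=-20,
           mode=dn, rate=0.07, blank=1.3, exo_pct=-50),
        # --- donor confounders (offsets tuned so PCA separates donors) ----
        _m("Lac", [(1.330, 0.6, 1.3), (4.110, 0.4, 1.5)], cell=8.0,
           offsets={1: 0.8, 2: 0.9, 3: 1.5},
           mode=up, rate=0.8, blank=0.3, exo_pct=80),
        _m("glycerol", [(3.560, 0.6, 1.6), (3.770, 0.4, 1.6)], cell=4.0,
           offsets={1: 0.45, 2: 1.0, 3: 1.2}),
        _m("formate", [(8.460, 1.0, 1.2)], cell=0.8,
           offsets={1: 1.8, 2: 1.0, 3: 0.9}, mode=up, rate=0.02, blank=0.05),
        _m("Cr", [(3.040, 0.6, 1.2), (3.930, 0.4, 1.4)], cell=3.0,
           offsets={1: 0.9, 2: 1.5, 3: 0.6}, mode=dn, rate=0.04, blank=1.0),
        _m("Tau", [(3.425, 0.5, 1.5), (3.285, 0.5, 1.5)], cell=10.0,
           offsets={1: 0.9, 2: 1.5, 3: 0.9}),
        _m("2-HIC", [(0.875, 0.7, 1.5), (1.640, 0.3, 1.5)], cell=0.6,
           offsets={1: 0.8, 2: 0.9, 3: 1.7}),
        _m("acetate", [(1.920, 1.0, 1.2)], cell=1.2,
           offsets={1: 0.8, 2: 1.6, 3: 0.9}, mode=dn, rate=0.03, blank=0.6),
        _m("acetone", [(2.220, 1.0, 1.2)], cell=0.5,
           offsets={1: 0.8, 2: 1.6, 3: 0.9}),
        _m("Glu", [(2.340, 1.0, 1.6)], cell=9.0,
           offsets={1: 0.9, 2: 0.9, 3: 1.4},
           mode=up, rate=0.02, blank=0.5,
           rate_offsets={1: 1.4, 2: 0.8, 3: 1.0}),
        _m("Gly", [(3.550, 1.0, 1.2)], cell=7.0,
           offsets={1: 0.9, 2: 0.9, 3: 1.3}),
        # --- other endometabolites ----------------------------------------
        _m("m-Ino", [(4.060, 1.0, 1.5)], cell=6.0, mode=dn, rate=0.01,
           blank=0.4),
        _m("AMP", [(8.600, 1.0, 1.6)], cell=0.4),
        _m("Ado", [(8.270, 0.5, 1.6), (6.050, 0.5, 1.6)], cell=0.3),
        _m("Glc", [(3.450, 0.7, 1.6), (5.235, 0.3, 1.5)], cell=1.0,
           mode=dn, rate=0.5, blank=15.0, exo_pct=-50),
        _m("Gln", [(2.450, 1.0, 1.6)], cell=3.0,
           mode=dn, rate=0.15, blank=4.0, exo_pct=-50),
        # --- exometabolite signature (media-only members) -----------------
        _m("2-HIBA", [(1.360, 1.0, 1.3)], mode=dn, rate=0.01, blank=0.3,
           exo_pct=-50),
        _m("Pyr", [(2.385, 1.0, 1.3)], mode=dn, rate=0.04, blank=1.0,
           exo_pct=-50),
        _m("3-HBA", [(2.310, 0.6, 1.5), (2.410, 0.4, 1.5)], mode=up,
           rate=0.05, exo_pct=80),
        _m("Orn", [(3.105, 1.0, 1.5)], mode=up, rate=0.015, blank=0.2,
           exo_pct=80),
        _m("PyroGlu", [(2.510, 1.0, 1.5)], mode=up, rate=0.03, exo_pct=80),
        _m("3-HIBA", [(1.080, 1.0, 1.4)], mode=up, rate=0.04, exo_pct=-55),
        _m("a-KG", [(3.005, 1.0, 1.5)], mode=up, rate=0.04, exo_pct=-55),
        _m("Cit", [(2.545, 0.5, 1.5), (2.685, 0.5, 1.5)], mode=up,
           rate=0.06, exo_pct=-55),
        _m("Ala", [(1.480, 1.0, 1.3)], mode=up, rate=0.03, blank=0.8,
           rate_offsets={1: 1.4, 2: 0.7, 3: 1.0}, exo_pct=45),
        _m("His", [(7.090, 0.6, 1.5), (7.850, 0.4, 1.5)], mode=up,
           rate=0.015, blank=0.8, rate_offsets={1: 1.2, 2: 0.7, 3: 1.1},
           exo_pct=45),
        # --- other exometabolites (proliferation footprint, both arms) ----
        _m("Thr", [(4.250, 1.0, 1.5)], mode=dn, rate=0.03, blank=1.0),
        _m("Ser", [(3.960, 1.0, 1.5)], mode=dn, rate=0.03, blank=1.2),
        _m("Met", [(2.130, 1.0, 1.4)], mode=dn, rate=0.02, blank=0.8),
        _m("Phe", [(7.370, 1.0, 1.5)], mode=dn, rate=0.02, blank=0.9),
        _m("Tyr", [(6.900, 1.0, 1.5)], mode=dn, rate=0.02, blank=0.8),
        _m("Lys", [(1.725, 1.0, 1.6)], mode=dn, rate=0.04, blank=1.5),
        _m("Arg", [(1.685, 1.0, 1.6)], mode=dn, rate=0.03, blank=1.2),
        _m("3M2OV", [(0.905, 1.0, 1.4)], mode=up, rate=0.02),
    ]
    return MetaboliteLibrary(mets)


def strip_effects(library: MetaboliteLibrary,
                  which: str = "all") -> MetaboliteLibrary:
    """Return a copy with effect profiles removed.

    which='all'  -- every profile set to unity (no time trends at all)
    which='arm'  -- OI profiles set equal to CTR (null arm contrast; the
                    shared proliferation trends remain)
    """
    out = []
    for m in library:
        if which == "all":
            out.append(replace(m, effect_profiles={}))
        elif which == "arm":
            prof = {k: list(v) for k, v in m.effect_profiles.items()
                    if k[0] == "CTR"}
            for (arm, comp), v in list(prof.items()):
                prof[("OI", comp)] = list(v)
            out.append(replace(m, effect_profiles=prof))
        else:
            raise ValueError("which must be 'all' or 'arm'")
    return MetaboliteLibrary(out)
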