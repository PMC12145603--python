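"""Spectral preprocessing: TSP referencing, region exclusion, recursive
segment-wise alignment and total-area normalization.

Order matters: reference -> exclude -> align -> normalize.  Normalization is
computed over retained (post-exclusion) points only, so solvent and water
areas never influence the scaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import Spectrum, SpectrumSet


class ReferencingError(ValueError):
    """Raised when the reference window contains no usable maximum."""


@dataclass
class ExclusionMask:
    """Closed ppm intervals to drop before statistics; overlaps are merged."""

    regions: list

    def __post_init__(self):
        regs = sorted((min(a, b), max(a, b)) for a, b in self.regions)
        merged: list[tuple[float, float]] = []
        for lo, hi in regs:
            if merged and lo <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
            else:
                merged.append((lo, hi))
        self.regions = merged

    def contains(self, ppm: np.ndarray) -> np.ndarray:
        ppm = np.asarray(ppm)
        inside = np.zeros(ppm.shape, dtype=bool)
        for lo, hi in self.regions:
            inside |= (ppm >= lo) & (ppm <= hi)
        return inside

    def overlap(self, lo: float, hi: float) -> float:
        """Length of the mask's intersection with [lo, hi]."""
        return sum(max(0.0, min(hi, b) - max(lo, a)) for a, b in self.regions)

    def union(self, other: "ExclusionMask") -> "ExclusionMask":
        return ExclusionMask(list(self.regions) + list(other.regions))


#: default exclusions for cell-extract spectra: water, TSP, methanol, ethanol
ENDO_MASK = ExclusionMask([(4.5, 5.2), (0.0, 0.6), (3.3, 3.4),
                           (1.1, 1.2), (3.6, 3.7)])
#: media add beta-GP/glycerol and DMSO regions
MEDIA_MASK = ENDO_MASK.union(ExclusionMask([(3.5, 3.9), (4.1, 4.2),
                                            (2.7, 2.8)]))


# ---------------------------------------------------------------------------
# TSP referencing

def _tsp_shift_points(ppm, intensity, window) -> int:
    lo, hi = min(window), max(window)
    sel = np.flatnonzero((ppm >= lo) & (ppm <= hi))
    if sel.size == 0:
        raise ReferencingError("reference window outside the ppm axis")
    vals = intensity[sel]
    if np.ptp(vals) == 0:
        raise ReferencingError("flat reference window: no maximum to lock on")
    imax = sel[int(np.argmax(vals))]
    i0 = int(np.argmin(np.abs(ppm)))
    return i0 - imax


def _shift_intensity(y: np.ndarray, s: int) -> np.ndarray:
    """Shift by s grid points, padding with the edge value (no wrap-around)."""
    if s == 0:
        return y.copy()
    out = np.empty_like(y)
    if s > 0:
        out[s:] = y[:-s]
        out[:s] = y[0]
    else:
        out[:s] = y[-s:]
        out[s:] = y[-1]
    return out


def reference_to_tsp(s: Spectrum, search_window=(-0.05, 0.05)) -> Spectrum:
    """Lock the maximum inside `search_window` onto 0.00 ppm.

    The spectrum is shifted by an integer number of grid steps (intensity
    values are preserved, only re-positioned), so the correction is exact to
    within one grid step.
    """
    shift = _tsp_shift_points(s.ppm, s.intensity, search_window)
    return Spectrum(s.ppm.copy(), _shift_intensity(s.intensity, shift),
                    dict(s.meta))


def reference_set_to_tsp(sset: SpectrumSet,
                         search_window=(-0.05, 0.05)) -> SpectrumSet:
    out = sset.copy()
    for i in range(len(out)):
        shift = _tsp_shift_points(out.ppm, out.intensity[i], search_window)
        out.intensity[i] = _shift_intensity(out.intensity[i], shift)
    return out


# ---------------------------------------------------------------------------
# exclusion

def exclude_regions(s: Spectrum, mask: ExclusionMask) -> Spectrum:
    keep = ~mask.contains(s.ppm)
    return Spectrum(s.ppm[keep], s.intensity[keep], dict(s.meta))


def exclude_regions_set(sset: SpectrumSet, mask: ExclusionMask) -> SpectrumSet:
    keep = ~mask.contains(sset.ppm)
    return SpectrumSet(sset.ppm[keep], sset.intensity[:, keep],
                       sset.meta.copy())


# ---------------------------------------------------------------------------
# normalization

def normalize_total_area(s: Spectrum) -> Spectrum:
    total = float(s.intensity.sum())
    if total <= 0:
        raise ValueError("nonpositive total area; cannot normalize")
    return Spectrum(s.ppm.copy(), s.intensity / total, dict(s.meta))


def normalize_set(sset: SpectrumSet) -> SpectrumSet:
    totals = sset.intensity.sum(axis=1)
    if np.any(totals <= 0):
        bad = sset.meta["sample_id"][totals <= 0].tolist()
        raise ValueError(f"nonpositive total area for samples {bad}")
    return SpectrumSet(sset.ppm.copy(), sset.intensity / totals[:, None],
                       sset.meta.copy())


# ---------------------------------------------------------------------------
# recursive segment-wise alignment

def _best_shift(seg: np.ndarray, ref: np.ndarray, max_pts: int) -> int:
    """Integer shift maximizing normalized cross-correlation with the
    reference.

    The correlation is normalized by the shifted segment's norm, so edge
    padding cannot buy a spurious gain on sloping baseline segments.
    Candidates are visited in order of increasing |shift| and only strict
    improvements are kept, so ties break toward zero shift.
    """
    def score(sft: int) -> float:
        sh = _shift_intensity(seg, sft)
        n = float(np.linalg.norm(sh))
        return float(np.dot(sh, ref)) / n if n > 0 else 0.0

    best_s = 0
    best_v = score(0)
    tol = 1e-9 * max(abs(best_v), 1.0)
    order = []
    for k in range(1, max_pts + 1):
        order.extend([k, -k])
    for sft in order:
        v = score(sft)
        if v > best_v + tol:
            best_v, best_s = v, sft
    return best_s


def _split_point(ref: np.ndarray, min_segment: int) -> int:
    """Split where the reference is lowest inside the admissible middle
    band, so segment seams fall on baseline rather than through peaks."""
    lo, hi = min_segment, ref.size - min_segment
    if hi <= lo:
        return ref.size // 2
    return lo + int(np.argmin(ref[lo:hi]))


def _align_recursive(seg, ref, max_pts, min_segment):
    out = _shift_intensity(seg, _best_shift(seg, ref, max_pts))
    if out.size >= 2 * min_segment:
        mid = _split_point(ref, min_segment)
        left = _align_recursive(out[:mid], ref[:mid], max_pts, min_segment)
        right = _align_recursive(out[mid:], ref[mid:], max_pts, min_segment)
        out = np.concatenate([left, right])
    return out


def align_segments(sset: SpectrumSet, reference: Spectrum | str = "mean",
                   max_shift: float = 0.02,
                   min_segment: int = 64) -> SpectrumSet:
    """Recursive binary-segmentation alignment against a reference spectrum.

    Each segment is shifted by the integer number of grid points (bounded by
    `max_shift` ppm) that maximizes its cross-correlation with the reference;
    segments are then halved and re-aligned until shorter than
    ``2 * min_segment``.  Edge points vacated by a shift are padded with the
    segment's boundary value, keeping the total integral stable.
    """
    if max_shift <= 0:
        raise ValueError("max_shift must be > 0")
    if min_segment > sset.ppm.size:
        raise ValueError("min_segment larger than the spectrum")
    if isinstance(reference, str):
        if reference == "mean":
            ref = sset.mean_spectrum()
        elif reference == "first":
            ref = sset.spectrum(0)
        else:
            raise ValueError(f"unknown reference {reference!r}")
    else:
        ref = reference
    if ref.ppm.size != sset.ppm.size:
        raise ValueError("reference not on the set's ppm grid")
    dx = float(np.mean(np.diff(sset.ppm)))
    max_pts = max(1, int(round(max_shift / abs(dx))))
    out = sset.copy()
    for i in range(len(out)):
        out.intensity[i] = _align_recursive(out.intensity[i], ref.intensity,
                                            max_pts, min_segment)
    return out
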