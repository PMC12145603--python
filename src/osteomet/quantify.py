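"""Window integration of named metabolite signals and marker ratios."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import Spectrum, SpectrumSet
from .library import MetaboliteLibrary
from .preprocess import ExclusionMask

#: default integration half-width around a multiplet center, ppm
DEFAULT_HALFWIDTH = 0.009


def default_windows(library: MetaboliteLibrary, compartment: str,
                    mask: ExclusionMask | None = None,
                    halfwidth: float = DEFAULT_HALFWIDTH) -> dict:
    """Derive one integration window per metabolite present in `compartment`.

    For each metabolite the multiplet is chosen whose window does not touch
    the exclusion mask and is farthest from any other metabolite's peak
    (least-overlapped rule); rel_area breaks ties toward the major multiplet.
    """
    if compartment == "cell":
        names = library.endometabolites()
    elif compartment == "media":
        names = library.exometabolites()
    else:
        raise ValueError("compartment must be 'cell' or 'media'")
    all_centers = {m.name: [mult.center for mult in m.multiplets]
                   for m in library}
    windows = {}
    for name in names:
        best = None
        for mult in library[name].multiplets:
            lo, hi = mult.center - halfwidth, mult.center + halfwidth
            if mask is not None and mask.overlap(lo, hi) > 0:
                continue
            others = [c for other, cs in all_centers.items()
                      if other != name for c in cs]
            dist = min((abs(mult.center - c) for c in others), default=np.inf)
            key = (dist, mult.rel_area)
            if best is None or key > best[0]:
                best = (key, (lo, hi))
        if best is not None:
            windows[name] = best[1]
    return windows


def integrate_windows(s: Spectrum, windows: dict,
                      mask: ExclusionMask | None = None) -> dict:
    """Trapezoidal integrals over ppm windows; masked windows come back NaN.

    A window overlapping the exclusion mask by more than 50% of its width is
    flagged missing (NaN) rather than integrated.
    """
    lo_axis, hi_axis = float(s.ppm.min()), float(s.ppm.max())
    out = {}
    for name, (lo, hi) in windows.items():
        lo, hi = min(lo, hi), max(lo, hi)
        if hi < lo_axis or lo > hi_axis:
            raise ValueError(f"window for {name!r} outside the ppm axis")
        if mask is not None and mask.overlap(lo, hi) > 0.5 * (hi - lo):
            out[name] = np.nan
            continue
        sel = (s.ppm >= lo) & (s.ppm <= hi)
        if sel.sum() < 2:
            out[name] = np.nan
            continue
        out[name] = float(np.trapezoid(s.intensity[sel], s.ppm[sel]))
    return out


def integrate_set(sset: SpectrumSet, windows: dict,
                  mask: ExclusionMask | None = None) -> pd.DataFrame:
    """IntegralTable: rows = samples (meta columns kept), columns = windows."""
    recs = []
    for i in range(len(sset)):
        recs.append(integrate_windows(sset.spectrum(i), windows, mask))
    table = pd.DataFrame(recs)
    return pd.concat([sset.meta.reset_index(drop=True), table], axis=1)


def total_area_column(sset: SpectrumSet) -> np.ndarray:
    """Per-sample total retained intensity (the TA proxy for cell number)."""
    return sset.intensity.sum(axis=1)


def compute_ratio(table: pd.DataFrame, num: str, den: str) -> pd.Series:
    """Element-wise num/den ratio; nonpositive denominators give NaN."""
    for col in (num, den):
        if col not in table.columns:
            raise KeyError(f"column {col!r} not in integral table")
    den_vals = table[den].to_numpy(dtype=float)
    num_vals = table[num].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(den_vals > 0, num_vals / den_vals, np.nan)
    return pd.Series(ratio, index=table.index, name=f"{num}/{den}")
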