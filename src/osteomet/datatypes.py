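"""Core in-memory containers for 1H NMR spectra and cohorts.

A :class:`Spectrum` is a single trace (ppm axis + intensities + sample
metadata).  A :class:`SpectrumSet` holds many spectra that share one ppm
grid, which is the natural unit for alignment, exclusion and multivariate
work.  Axes are stored ascending; plotting code may reverse them to follow
the NMR display convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: metadata columns every simulated / imported sample sheet carries
META_COLUMNS = ["sample_id", "donor", "arm", "day", "replicate", "compartment"]


@dataclass
class Spectrum:
    """One 1H NMR spectrum on a strictly monotone ppm axis."""

    ppm: np.ndarray
    intensity: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.ndim != 1 or self.intensity.ndim != 1:
            raise ValueError("ppm and intensity must be 1-D")
        if self.ppm.size != self.intensity.size:
            raise ValueError("ppm and intensity lengths differ")
        d = np.diff(self.ppm)
        if self.ppm.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("ppm axis must be strictly monotone")

    def copy(self) -> "Spectrum":
        return Spectrum(self.ppm.copy(), self.intensity.copy(), dict(self.meta))

    def __len__(self) -> int:
        return self.ppm.size


@dataclass
class SpectrumSet:
    """A stack of spectra on a common ppm grid with a sample sheet.

    ``intensity`` has shape ``(n_samples, n_points)``; ``meta`` is a
    DataFrame with one row per sample (columns as in :data:`META_COLUMNS`,
    extra columns allowed).
    """

    ppm: np.ndarray
    intensity: np.ndarray
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.atleast_2d(np.asarray(self.intensity, dtype=float))
        if self.intensity.shape[1] != self.ppm.size:
            raise ValueError("intensity width does not match ppm grid")
        if len(self.meta) != self.intensity.shape[0]:
            raise ValueError("meta rows do not match number of spectra")
        self.meta = self.meta.reset_index(drop=True)

    def __len__(self) -> int:
        return self.intensity.shape[0]

    def spectrum(self, i: int) -> Spectrum:
        return Spectrum(self.ppm.copy(), self.intensity[i].copy(),
                        self.meta.iloc[i].to_dict())

    def copy(self) -> "SpectrumSet":
        return SpectrumSet(self.ppm.copy(), self.intensity.copy(), self.meta.copy())

    def subset(self, mask) -> "SpectrumSet":
        """Row-subset by a boolean mask or index array over samples."""
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return SpectrumSet(self.ppm.copy(), self.intensity[idx],
                           self.meta.iloc[idx].reset_index(drop=True))

    def mean_spectrum(self) -> Spectrum:
        return Spectrum(self.ppm.copy(), self.intensity.mean(axis=0),
                        {"sample_id": "__mean__"})


def concat_sets(sets: list[SpectrumSet]) -> SpectrumSet:
    """Stack SpectrumSets sharing the same grid."""
    first = sets[0]
    for s in sets[1:]:
        if s.ppm.size != first.ppm.size or not np.allclose(s.ppm, first.ppm):
            raise ValueError("spectrum sets are not on a common ppm grid")
    return SpectrumSet(
        first.ppm.copy(),
        np.vstack([s.intensity for s in sets]),
        pd.concat([s.meta for s in sets], ignore_index=True),
    )
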