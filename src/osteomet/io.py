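"""Reading and writing of the package's plain-text formats.

Spectra travel as two-column ``ppm intensity`` text files plus a CSV sample
sheet; tables (integrals, screen results, ground truth) as CSV.  All writers
use fixed float formatting so that a given seed reproduces output bytes.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import META_COLUMNS, Spectrum, SpectrumSet

_FLOAT_FMT = "%.6f %.8e"


def write_spectrum(path: str | Path, s: Spectrum) -> None:
    header = " ".join(f"{k}={s.meta[k]}" for k in META_COLUMNS if k in s.meta)
    np.savetxt(path, np.column_stack([s.ppm, s.intensity]),
               fmt=_FLOAT_FMT, header=header)


def read_spectrum(path: str | Path, meta: dict | None = None) -> Spectrum:
    arr = np.loadtxt(path)
    return Spectrum(arr[:, 0], arr[:, 1], meta or {})


def write_spectrum_set(outdir: str | Path, sset: SpectrumSet,
                       sheet_name: str = "samples.csv") -> Path:
    """One text file per spectrum plus a sample sheet; returns the sheet path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = sset.meta.copy()
    fnames = []
    for i in range(len(sset)):
        fname = f"{meta['sample_id'].iloc[i]}.txt"
        write_spectrum(outdir / fname, sset.spectrum(i))
        fnames.append(fname)
    meta["file"] = fnames
    sheet = outdir / sheet_name
    meta.to_csv(sheet, index=False, float_format="%.6g")
    return sheet


def read_spectrum_set(outdir: str | Path,
                      sheet_name: str = "samples.csv") -> SpectrumSet:
    outdir = Path(outdir)
    meta = pd.read_csv(outdir / sheet_name)
    rows = []
    ppm = None
    for fname in meta["file"]:
        s = read_spectrum(outdir / fname)
        if ppm is None:
            ppm = s.ppm
        rows.append(s.intensity)
    return SpectrumSet(ppm, np.vstack(rows), meta.drop(columns=["file"]))


def write_table(path: str | Path, df: pd.DataFrame, index: bool = True) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=index, float_format="%.10g")


def write_json(path: str | Path, obj) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")
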