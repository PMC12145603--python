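"""End-to-end orchestration: simulate -> preprocess -> correct -> integrate
-> screen -> fit -> validate, with a serializable config, a run manifest and
optional figures.

The heavy lifting lives in the per-stage modules; this module wires them
together and defines the two canonical processing paths:

* cells:  TSP referencing -> alignment -> exclusion (endo mask) ->
          total-area normalization -> window integration
* media:  TSP referencing -> alignment -> exclusion (media mask) ->
          raw window integration + total retained area ->
          exchange correction (recursive blank-referenced accumulation)
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .datatypes import SpectrumSet
from .library import MetaboliteLibrary, build_default_library
from .media import correct_table, corrected_wide
from .preprocess import (ENDO_MASK, MEDIA_MASK, ExclusionMask, align_segments,
                         exclude_regions_set, normalize_set,
                         reference_set_to_tsp)
from .quantify import default_windows, integrate_set, total_area_column
from .screen import SelectionRules, screen_table, select_donor_independent
from .simulate import CohortConfig, simulate_cohort, _prev_exchange
from .validate import MCCVConfig, run_mccv

META_COLS = ["sample_id", "donor", "arm", "day", "replicate", "compartment"]


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "runs/demo"
    compartment: str = "both"          # 'cells' | 'media' | 'both'
    cohort: dict = field(default_factory=dict)      # CohortConfig overrides
    endo_mask: list | None = None      # ppm pairs; None -> defaults
    media_mask: list | None = None
    align_max_shift: float = 0.02
    align_min_segment: int = 64
    window_halfwidth: float = 0.009
    mccv: dict = field(default_factory=dict)        # MCCVConfig overrides
    rules: dict = field(default_factory=dict)       # SelectionRules overrides
    endo_day_cutoff: float = 14.0      # samples used for the endo PLS-DA model
    exo_day_cutoff: float = 7.0
    make_figures: bool = True
    write_spectra: bool = False
    resume: bool = False

    def cohort_config(self) -> CohortConfig:
        return CohortConfig(**{**self.cohort, "seed": self.seed})

    def mccv_config(self) -> MCCVConfig:
        return MCCVConfig(**{"seed": self.seed, **self.mccv})

    def selection_rules(self) -> SelectionRules:
        return SelectionRules(**self.rules)

    def masks(self) -> tuple[ExclusionMask, ExclusionMask]:
        endo = (ExclusionMask([tuple(r) for r in self.endo_mask])
                if self.endo_mask else ENDO_MASK)
        media = (ExclusionMask([tuple(r) for r in self.media_mask])
                 if self.media_mask else MEDIA_MASK)
        return endo, media

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


# ---------------------------------------------------------------------------
# canonical processing paths

def process_cells(cells: SpectrumSet, library: MetaboliteLibrary,
                  mask: ExclusionMask = ENDO_MASK, max_shift: float = 0.02,
                  min_segment: int = 64,
                  window_halfwidth: float = 0.009) -> pd.DataFrame:
    """Cell-extract spectra to a normalized endometabolite integral table."""
    sset = reference_set_to_tsp(cells)
    sset = align_segments(sset, "mean", max_shift=max_shift,
                          min_segment=min_segment)
    sset = exclude_regions_set(sset, mask)
    sset = normalize_set(sset)
    windows = default_windows(library, "cell", mask,
                              halfwidth=window_halfwidth)
    return integrate_set(sset, windows, mask)


def process_media(media: SpectrumSet, blanks: SpectrumSet,
                  library: MetaboliteLibrary,
                  mask: ExclusionMask = MEDIA_MASK,
                  exchange_days=(0, 4, 7, 11, 14, 18, 21),
                  max_shift: float = 0.02, min_segment: int = 64,
                  window_halfwidth: float = 0.009):
    """Media + blank spectra to corrected exometabolite trajectories.

    Returns (corrected_long, corrected_wide) where the wide table has one
    row per conditioned-media sample and one column per exometabolite,
    holding exchange-corrected values (positive = net secretion).
    """
    windows = default_windows(library, "media", mask,
                              halfwidth=window_halfwidth)
    m = reference_set_to_tsp(media)
    reference = m.mean_spectrum()
    m = align_segments(m, reference, max_shift=max_shift,
                       min_segment=min_segment)
    m = exclude_regions_set(m, mask)
    bl = reference_set_to_tsp(blanks)
    bl = align_segments(bl, reference, max_shift=max_shift,
                        min_segment=min_segment)
    bl = exclude_regions_set(bl, mask)

    ta = total_area_column(m)
    raw = integrate_set(m, windows, mask)
    blank_int = integrate_set(bl, windows, mask)

    # batch (exchange-day) blank means, mapped onto the sampling days
    batch_means = (blank_int.groupby("day")[list(windows)].mean())
    media_days = sorted(raw["day"].unique())
    blank_rows = []
    for d in media_days:
        batch = _prev_exchange(d, exchange_days)
        if batch not in batch_means.index:
            raise ValueError(f"no blank batch for exchange day {batch}")
        for var in windows:
            blank_rows.append({"day": d, "variable": var,
                               "value": batch_means.loc[batch, var]})
    blanks_tbl = pd.DataFrame(blank_rows)

    long = raw.melt(id_vars=META_COLS, var_name="variable", value_name="raw")
    ta_map = pd.Series(ta, index=raw["sample_id"])
    long["total_area"] = long["sample_id"].map(ta_map)
    corrected_long = correct_table(
        long.drop(columns=["compartment"]), blanks_tbl,
        exchange_days=exchange_days)
    return corrected_long, corrected_wide(corrected_long)


# ---------------------------------------------------------------------------
# run directory orchestration

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig,
                 library: MetaboliteLibrary | None = None) -> dict:
    """Execute the configured stages, writing tables, models, figures and a
    manifest under ``cfg.outdir``.  Returns the in-memory results dict."""
    lib = library if library is not None else build_default_library()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    endo_mask, media_mask = cfg.masks()
    results: dict = {}
    manifest = {"seed": cfg.seed, "stages": [], "outputs": {},
                "config": dataclasses.asdict(cfg)}

    def record(name: str, outputs: dict[str, pd.DataFrame]):
        manifest["stages"].append(name)
        for fname, df in outputs.items():
            path = outdir / fname
            io.write_table(path, df, index=False)
            manifest["outputs"][fname] = _sha256(path)

    def stage(name, fn):
        try:
            fn()
        except Exception as exc:  # noqa: BLE001 - re-raise with stage name
            io.write_json(outdir / "manifest.json", manifest)
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

    # --- simulate ---------------------------------------------------------
    def _simulate():
        ccfg = cfg.cohort_config()
        cells, media, blanks, truth = simulate_cohort(lib, ccfg)
        results.update(cells=cells, media=media, blanks=blanks, truth=truth,
                       cohort_config=ccfg)
        if cfg.write_spectra:
            io.write_spectrum_set(outdir / "spectra" / "cells", cells)
            io.write_spectrum_set(outdir / "spectra" / "media", media)
            io.write_spectrum_set(outdir / "spectra" / "blanks", blanks)
        record("simulate", {
            "ground_truth_signature.csv": truth.planted_signature,
            "ground_truth_values.csv": truth.true_values.reset_index(),
        })

    stage("simulate", _simulate)

    do_cells = cfg.compartment in ("cells", "both")
    do_media = cfg.compartment in ("media", "both")

    if do_cells:
        def _cells():
            table = process_cells(results["cells"], lib, endo_mask,
                                  cfg.align_max_shift, cfg.align_min_segment,
                                  cfg.window_halfwidth)
            results["endo_table"] = table
            record("preprocess_cells", {"endo_integrals.csv": table})

        def _screen_endo():
            table = results["endo_table"]
            scr = screen_table(table, mode="osteo")
            sel = select_donor_independent(scr, cfg.selection_rules())
            results["endo_screen"] = scr
            results["endo_signature"] = sel
            record("screen_endo", {
                "endo_screen.csv": scr,
                "endo_signature.csv": pd.DataFrame({"metabolite": sel}),
            })

        def _mccv_endo():
            table = results["endo_table"]
            sel = results["endo_signature"] or [
                c for c in table.columns if c not in META_COLS]
            sub = table[table["day"] >= cfg.endo_day_cutoff]
            X = sub[sel].to_numpy()
            res = run_mccv(X, sub["arm"].to_numpy(), cfg.mccv_config())
            results["endo_mccv"] = res
            io.write_json(outdir / "endo_mccv.json", res.summary)
            manifest["stages"].append("mccv_endo")
            manifest["outputs"]["endo_mccv.json"] = _sha256(
                outdir / "endo_mccv.json")

        stage("preprocess_cells", _cells)
        stage("screen_endo", _screen_endo)
        stage("mccv_endo", _mccv_endo)

    if do_media:
        def _media():
            long, wide = process_media(
                results["media"], results["blanks"], lib, media_mask,
                results["cohort_config"].exchange_days,
                cfg.align_max_shift, cfg.align_min_segment,
                cfg.window_halfwidth)
            results["exo_long"] = long
            results["exo_table"] = wide
            record("correct_media", {"exo_corrected.csv": wide})

        def _screen_exo():
            scr = screen_table(results["exo_table"], mode="osteo")
            sel = select_donor_independent(scr, cfg.selection_rules())
            results["exo_screen"] = scr
            results["exo_signature"] = sel
            record("screen_exo", {
                "exo_screen.csv": scr,
                "exo_signature.csv": pd.DataFrame({"metabolite": sel}),
            })

        def _mccv_exo():
            table = results["exo_table"]
            sel = results["exo_signature"] or [
                c for c in table.columns if c not in META_COLS]
            sub = table[table["day"] >= cfg.exo_day_cutoff]
            X = sub[sel].to_numpy()
            res = run_mccv(X, sub["arm"].to_numpy(), cfg.mccv_config())
            results["exo_mccv"] = res
            io.write_json(outdir / "exo_mccv.json", res.summary)
            manifest["stages"].append("mccv_exo")
            manifest["outputs"]["exo_mccv.json"] = _sha256(
                outdir / "exo_mccv.json")

        stage("correct_media", _media)
        stage("screen_exo", _screen_exo)
        stage("mccv_exo", _mccv_exo)

    if cfg.make_figures:
        stage("report", lambda: make_figures(results, outdir, manifest))

    io.write_json(outdir / "manifest.json", manifest)
    results["manifest"] = manifest
    return results


def make_figures(results: dict, outdir: Path, manifest: dict | None = None):
    """Percent-variation heatmaps and PCA scores plots (PNG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .chemometrics import PCA

    outdir = Path(outdir)
    made = []
    for key, fname in (("endo_screen", "endo_heatmap.png"),
                       ("exo_screen", "exo_heatmap.png")):
        scr = results.get(key)
        if scr is None:
            continue
        pooled = scr[scr["donor"] == "pooled"]
        mat = pooled.pivot_table(index="metabolite", columns="day",
                                 values="pct_variation")
        fig, ax = plt.subplots(figsize=(6, max(3, 0.22 * len(mat))))
        vmax = np.nanpercentile(np.abs(mat.to_numpy()), 95) or 1.0
        im = ax.imshow(mat.to_numpy(), aspect="auto", cmap="RdBu_r",
                       vmin=-vmax, vmax=vmax)
        ax.set_xticks(range(mat.shape[1]),
                      [f"D{int(d)}" for d in mat.columns])
        ax.set_yticks(range(mat.shape[0]), mat.index, fontsize=6)
        fig.colorbar(im, ax=ax, label="% variation (OI vs CTR)")
        fig.tight_layout()
        fig.savefig(outdir / fname, dpi=120)
        plt.close(fig)
        made.append(fname)

    for key, fname in (("endo_table", "endo_pca.png"),
                       ("exo_table", "exo_pca.png")):
        table = results.get(key)
        if table is None:
            continue
        cols = [c for c in table.columns if c not in META_COLS]
        X = table[cols].to_numpy()
        ok = np.all(np.isfinite(X), axis=1)
        model = PCA(n_components=2, scale="uv").fit(X[ok])
        sc = model.scores_
        fig, ax = plt.subplots(figsize=(5, 4))
        sub = table.loc[ok]
        for donor in sorted(sub["donor"].unique()):
            for arm, mk in (("CTR", "o"), ("OI", "^")):
                pick = ((sub["donor"] == donor) & (sub["arm"] == arm)).to_numpy()
                if pick.any():
                    ax.scatter(sc[pick, 0], sc[pick, 1], marker=mk,
                               label=f"donor {donor} {arm}", s=18, alpha=0.8)
        ax.set_xlabel(f"PC1 ({100 * model.explained_variance_ratio_[0]:.0f}%)")
        ax.set_ylabel(f"PC2 ({100 * model.explained_variance_ratio_[1]:.0f}%)")
        ax.legend(fontsize=6)
        fig.tight_layout()
        fig.savefig(outdir / fname, dpi=120)
        plt.close(fig)
        made.append(fname)

    if manifest is not None:
        manifest["stages"].append("report")
        manifest.setdefault("figures", []).extend(made)
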