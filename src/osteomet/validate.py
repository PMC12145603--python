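"""Monte Carlo cross-validation of PLS-DA.

Each iteration draws a stratified random partition of the samples into
``n_blocks`` blocks and holds one block out.  Scaling, latent-variable
selection and model fitting use the training complement only; held-out
samples are predicted on the 0/1 dummy scale.  Reported per iteration:

* Q2 = 1 - PRESS/TSS, with TSS taken about the training-set class-mean
  coding (predicting the training mean gives Q2 = 0 exactly);
* sensitivity, specificity and classification rate at the 0.5 cutoff.

Aggregates are means/SDs over iterations plus pooled confusion counts and a
pooled Q2 over all held-out predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chemometrics import PLSDA


@dataclass
class MCCVConfig:
    n_blocks: int = 7
    n_iterations: int = 500
    seed: int = 0
    scale: str = "uv"
    # fixed LV count, or None to pick 1..max_components by inner Q2
    n_components: int | None = None
    max_components: int = 3
    inner_splits: int = 3
    max_retries: int = 100

    def __post_init__(self):
        if self.n_blocks < 2:
            raise ValueError("n_blocks must be >= 2")


@dataclass
class MCCVResult:
    q2: np.ndarray
    sens: np.ndarray
    spec: np.ndarray
    cr: np.ndarray
    pooled_confusion: dict = field(default_factory=dict)
    pooled_q2: float = float("nan")
    n_samples: int = 0
    n_variables: int = 0
    chosen_components: np.ndarray | None = None

    @property
    def summary(self) -> dict:
        def _ms(x):
            x = np.asarray(x, dtype=float)
            ok = np.isfinite(x)
            return (float(np.mean(x[ok])) if ok.any() else float("nan"),
                    float(np.std(x[ok])) if ok.any() else float("nan"))
        out = {}
        for name, arr in (("q2", self.q2), ("sens", self.sens),
                          ("spec", self.spec), ("cr", self.cr)):
            m, s = _ms(arr)
            out[f"{name}_mean"] = m
            out[f"{name}_sd"] = s
        out["pooled_q2"] = self.pooled_q2
        out.update({f"pooled_{k}": v for k, v in self.pooled_confusion.items()})
        out["n_samples"] = self.n_samples
        out["n_variables"] = self.n_variables
        return out


def q2_score(y_true, y_pred, y_train_mean: float) -> float:
    """Q2 = 1 - PRESS/TSS with TSS about the training-set mean coding.

    Predicting the training mean for every held-out sample gives exactly 0;
    negative values mean worse than that baseline.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    press = float(np.sum((y_true - y_pred) ** 2))
    tss = float(np.sum((y_true - y_train_mean) ** 2))
    if tss <= 0:
        return float("nan")
    return 1.0 - press / tss


def confusion_metrics(truth, predicted, positive) -> tuple:
    """(sensitivity, specificity, classification rate); empty classes in the
    truth yield NaN for the metric that is undefined."""
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.size == 0 or truth.shape != predicted.shape:
        raise ValueError("truth and predicted must be equal-length, non-empty")
    pos = truth == positive
    tp = int(np.sum(pos & (predicted == positive)))
    fn = int(np.sum(pos & (predicted != positive)))
    tn = int(np.sum(~pos & (predicted != positive)))
    fp = int(np.sum(~pos & (predicted == positive)))
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    cr = (tp + tn) / truth.size
    return sens, spec, cr


def _stratified_blocks(y01, n_blocks, rng):
    """Random block labels, each class spread round-robin across blocks."""
    blocks = np.empty(y01.size, dtype=int)
    for cls in (0, 1):
        idx = np.flatnonzero(y01 == cls)
        rng.shuffle(idx)
        offset = rng.integers(n_blocks)
        blocks[idx] = (np.arange(idx.size) + offset) % n_blocks
    return blocks


def _inner_q2(Xtr, ytr, n_comp, n_splits, scale, rng):
    """Pooled inner-CV Q2 used only to pick the LV count inside a split."""
    blocks = _stratified_blocks(ytr, n_splits, rng)
    press = tss = 0.0
    for b in range(n_splits):
        te = blocks == b
        tr = ~te
        if len(np.unique(ytr[tr])) < 2 or te.sum() == 0:
            continue
        model = PLSDA(n_components=n_comp, scale=scale).fit(Xtr[tr], ytr[tr])
        yhat = model.decision_function(Xtr[te])
        ymean = float(np.mean(ytr[tr]))
        press += float(np.sum((ytr[te] - yhat) ** 2))
        tss += float(np.sum((ytr[te] - ymean) ** 2))
    if tss <= 0:
        return -np.inf
    return 1.0 - press / tss


def run_mccv(X, y, cfg: MCCVConfig | None = None) -> MCCVResult:
    """Monte Carlo cross-validation of a two-class PLS-DA model."""
    cfg = cfg or MCCVConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("MCCV requires exactly two classes")
    y01 = (y == classes[1]).astype(int)
    if min(np.bincount(y01)) < 2:
        raise ValueError("need at least 2 samples per class")
    rng = np.random.default_rng(cfg.seed)

    q2s, senss, specs, crs, comps = [], [], [], [], []
    press_pool = tss_pool = 0.0
    tp = tn = fp = fn = 0
    for _ in range(cfg.n_iterations):
        for _retry in range(cfg.max_retries):
            blocks = _stratified_blocks(y01, cfg.n_blocks, rng)
            hold = int(rng.integers(cfg.n_blocks))
            te = blocks == hold
            tr = ~te
            if te.sum() > 0 and len(np.unique(y01[tr])) == 2:
                break
        else:
            raise RuntimeError("could not draw a split with both classes "
                               "in training")
        if cfg.n_components is None:
            best_a, best_q = 1, -np.inf
            for a in range(1, cfg.max_components + 1):
                qa = _inner_q2(X[tr], y01[tr], a, cfg.inner_splits,
                               cfg.scale, rng)
                if qa > best_q + 1e-12:
                    best_a, best_q = a, qa
            a_use = best_a
        else:
            a_use = cfg.n_components
        comps.append(a_use)
        model = PLSDA(n_components=a_use, scale=cfg.scale).fit(X[tr], y01[tr])
        yhat = model.decision_function(X[te])
        ypred = (yhat > 0.5).astype(int)
        ymean_tr = float(np.mean(y01[tr]))
        q2s.append(q2_score(y01[te], yhat, ymean_tr))
        press_pool += float(np.sum((y01[te] - yhat) ** 2))
        tss_pool += float(np.sum((y01[te] - ymean_tr) ** 2))
        s, p, c = confusion_metrics(y01[te], ypred, positive=1)
        senss.append(s)
        specs.append(p)
        crs.append(c)
        yt = y01[te]
        tp += int(np.sum((yt == 1) & (ypred == 1)))
        fn += int(np.sum((yt == 1) & (ypred == 0)))
        tn += int(np.sum((yt == 0) & (ypred == 0)))
        fp += int(np.sum((yt == 0) & (ypred == 1)))

    return MCCVResult(
        q2=np.asarray(q2s), sens=np.asarray(senss), spec=np.asarray(specs),
        cr=np.asarray(crs),
        pooled_confusion={"tp": tp, "tn": tn, "fp": fp, "fn": fn},
        pooled_q2=1.0 - press_pool / tss_pool if tss_pool > 0 else float("nan"),
        n_samples=X.shape[0], n_variables=X.shape[1],
        chosen_components=np.asarray(comps),
    )


def progressive_timepoint_models(X, y, days, cutoffs,
                                 cfg: MCCVConfig | None = None
                                 ) -> list[tuple[float, MCCVResult]]:
    """One MCCV per day cutoff, using samples from day >= cutoff only.

    Mirrors the model series built by excluding progressively earlier
    timepoints; returns [(cutoff, MCCVResult), ...].
    """
    cfg = cfg or MCCVConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    days = np.asarray(days)
    out = []
    for cut in cutoffs:
        if cut > days.max():
            raise ValueError(f"cutoff {cut} beyond the last sampled day")
        keep = days >= cut
        ysub = y[keep]
        counts = pd.Series(ysub).value_counts()
        if len(counts) < 2 or counts.min() < 2:
            raise ValueError(f"cutoff {cut} leaves fewer than 2 samples "
                             "in a class")
        sub_cfg = MCCVConfig(**{**cfg.__dict__})
        out.append((cut, run_mccv(X[keep], ysub, sub_cfg)))
    return out
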