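"""Univariate screening and donor-independent signature selection.

Percent variation is 100*(mean_alt - mean_ref)/mean_ref per (metabolite,
donor, day); the alternative group is OI (vs CTR) in osteogenesis mode or
day i (vs day 0 within the same arm) in proliferation mode.  Two-group
p-values come from an exact two-sided Wilcoxon rank-sum (full enumeration
with mid-rank ties up to 12 total samples, normal approximation with tie
correction above).  With triplicate groups the smallest attainable exact
two-sided p is 0.1, so per-donor significance at alpha = 0.05 is impossible
and selection falls back to the Wilcoxon test pooled across donors.

Spearman correlation maps pair variables by group means and keep pairs
passing both |rho| and p thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations, permutations

import numpy as np
import pandas as pd
from scipy import stats

# ---------------------------------------------------------------------------
# exact Wilcoxon rank-sum

EXACT_LIMIT = 12  # enumerate up to this many total observations


@lru_cache(maxsize=64)
def _comb_indices(total: int, k: int) -> np.ndarray:
    """All k-subsets of range(total) as an array (C(total,k) x k)."""
    return np.array(list(combinations(range(total), k)), dtype=np.intp)


def _rank_sum_distribution(ranks: np.ndarray, k: int) -> np.ndarray:
    """All equally likely rank sums of a k-subset (handles mid-rank ties)."""
    idx = _comb_indices(ranks.size, k)
    return np.asarray(ranks)[idx].sum(axis=1)


def wilcoxon_exact(a, b) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact by complete enumeration of rank assignments (mid-ranks for ties)
    when n_a + n_b <= 12; otherwise the normal approximation with tie
    correction.  Two-sided p is twice the smaller tail, capped at 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n, m = a.size, b.size
    if n + m <= EXACT_LIMIT:
        ranks = stats.rankdata(np.concatenate([a, b]))
        w_obs = float(ranks[:n].sum())
        sums = _rank_sum_distribution(ranks, n)
        lo = np.mean(sums <= w_obs + 1e-9)
        hi = np.mean(sums >= w_obs - 1e-9)
        return float(min(1.0, 2.0 * min(lo, hi)))
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method="asymptotic")
    return float(res.pvalue)


def _stratum_pmf(ranks: np.ndarray, n_alt: int):
    """Exact pmf of the alt-group rank sum within one stratum.

    Returns (values, probabilities); rank sums are stored doubled so that
    mid-ranks stay integral."""
    doubled = np.round(2 * ranks).astype(int)
    sums = _rank_sum_distribution(doubled, n_alt)
    lo, hi = int(sums.min()), int(sums.max())
    counts = np.bincount(sums - lo)
    return np.arange(lo, hi + 1), counts / counts.sum()


def wilcoxon_stratified(strata: list[tuple]) -> float:
    """Two-sided donor-stratified Wilcoxon rank-sum p-value.

    `strata` is a list of (ref_values, alt_values) blocks (one per donor);
    ranks are formed within each block and the alt rank sums are added
    across blocks, so block-level (donor) offsets cancel.  The combined null
    is exact (convolution of per-block enumerations) when every block has at
    most 12 observations; otherwise a normal approximation with tie
    correction is used.  Blocks missing one of the groups are skipped.
    """
    used = [(np.asarray(a, float), np.asarray(b, float))
            for a, b in strata
            if np.asarray(a).size > 0 and np.asarray(b).size > 0]
    if not used:
        raise ValueError("no stratum has both groups")
    exact = all(a.size + b.size <= EXACT_LIMIT for a, b in used)
    if exact:
        vals = np.array([0])
        pmf = np.array([1.0])
        w_obs = 0
        for a, b in used:
            ranks = stats.rankdata(np.concatenate([a, b]))
            w_obs += int(np.round(2 * ranks[a.size:].sum()))
            v, p = _stratum_pmf(ranks, b.size)
            # support of the sum = outer sum of supports (dense convolution)
            new_lo = vals[0] + v[0]
            pmf = np.convolve(pmf, p)
            vals = np.arange(new_lo, new_lo + pmf.size)
        lo_tail = pmf[vals <= w_obs].sum()
        hi_tail = pmf[vals >= w_obs].sum()
        return float(min(1.0, 2.0 * min(lo_tail, hi_tail)))
    # normal approximation: sum per-stratum centered rank sums
    w = mu = var = 0.0
    for a, b in used:
        n, m = a.size, b.size
        ranks = stats.rankdata(np.concatenate([a, b]))
        w += float(ranks[n:].sum())
        N = n + m
        mu += m * (N + 1) / 2.0
        _, t = np.unique(np.concatenate([a, b]), return_counts=True)
        tie = ((t ** 3 - t).sum() / (N * (N - 1))) if N > 1 else 0.0
        var += n * m / 12.0 * ((N + 1) - tie)
    if var <= 0:
        return 1.0
    z = (w - mu) / np.sqrt(var)
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def percent_variation(ref, alt) -> float:
    """100 * (mean(alt) - mean(ref)) / mean(ref); sign encodes direction."""
    ref = np.asarray(ref, dtype=float)
    alt = np.asarray(alt, dtype=float)
    mref = float(np.mean(ref))
    if mref == 0:
        raise ValueError("reference mean is zero; percent variation undefined")
    return 100.0 * (float(np.mean(alt)) - mref) / mref


# ---------------------------------------------------------------------------
# screening

MIN_N_FOR_P = 3  # groups smaller than this never carry p-values


def _one_contrast(ref_vals, alt_vals):
    ref_vals = np.asarray(ref_vals, dtype=float)
    alt_vals = np.asarray(alt_vals, dtype=float)
    ref_vals = ref_vals[np.isfinite(ref_vals)]
    alt_vals = alt_vals[np.isfinite(alt_vals)]
    n_ref, n_alt = ref_vals.size, alt_vals.size
    if n_ref == 0 or n_alt == 0 or np.mean(ref_vals) == 0:
        return n_ref, n_alt, np.nan, np.nan
    pct = percent_variation(ref_vals, alt_vals)
    if min(n_ref, n_alt) < MIN_N_FOR_P:
        return n_ref, n_alt, pct, np.nan
    return n_ref, n_alt, pct, wilcoxon_exact(ref_vals, alt_vals)


def screen_table(table: pd.DataFrame, metabolites: list[str] | None = None,
                 mode: str = "osteo", alpha: float = 0.05) -> pd.DataFrame:
    """Per-(metabolite, donor, day) percent variation and Wilcoxon p.

    `table` holds meta columns (donor, arm, day) plus one column per
    metabolite.  mode='osteo' contrasts OI vs CTR per day; mode='prolif'
    contrasts each day vs the earliest day within the CTR arm.  Rows with
    donor='pooled' aggregate replicates across donors.
    """
    if mode not in ("osteo", "prolif"):
        raise ValueError("mode must be 'osteo' or 'prolif'")
    if metabolites is None:
        metabolites = [c for c in table.columns
                       if c not in ("sample_id", "donor", "arm", "day",
                                    "replicate", "compartment")]
    donors = sorted(table["donor"].unique())
    groups = table.groupby(["donor", "arm", "day"]).indices
    columns = {met: table[met].to_numpy(dtype=float) for met in metabolites}

    def pick(col, donor, arm, day):
        idx = groups.get((donor, arm, day))
        if idx is None:
            return np.empty(0)
        v = col[idx]
        return v[np.isfinite(v)]

    # (day, donor) -> (ref_idx_getter args, alt args)
    contrast_keys = []
    days = sorted(table["day"].unique())
    if mode == "osteo":
        for donor in donors:
            for day in days:
                if ((donor, "CTR", day) in groups
                        or (donor, "OI", day) in groups):
                    contrast_keys.append(
                        (donor, day, (donor, "CTR", day), (donor, "OI", day)))
    else:  # prolif: each later day vs the earliest day, CTR arm only
        ctr_days = sorted(d for (dn, arm, d) in groups if arm == "CTR")
        base_day = ctr_days[0]
        for donor in donors:
            for day in [d for d in ctr_days if d != base_day]:
                if (donor, "CTR", day) in groups:
                    contrast_keys.append(
                        (donor, day, (donor, "CTR", base_day),
                         (donor, "CTR", day)))

    rows = []
    for met in metabolites:
        col = columns[met]
        strata_by_day: dict = {}
        for donor, day, ref_key, alt_key in contrast_keys:
            ref_vals = pick(col, *ref_key)
            alt_vals = pick(col, *alt_key)
            strata_by_day.setdefault(day, []).append((ref_vals, alt_vals))
            n_ref, n_alt, pct, p = _one_contrast(ref_vals, alt_vals)
            rows.append({
                "metabolite": met, "donor": donor, "day": day,
                "n_ref": n_ref, "n_alt": n_alt,
                "pct_variation": pct, "p_value": p,
                "significant": bool(np.isfinite(p) and p < alpha),
                "visual_only": min(n_ref, n_alt) < MIN_N_FOR_P,
            })
        # pooled rows: percent variation over all replicates; p from the
        # donor-stratified rank-sum so donor-level offsets cannot mask or
        # fake an arm contrast
        for day, strata in sorted(strata_by_day.items()):
            ref_all = np.concatenate([s[0] for s in strata])
            alt_all = np.concatenate([s[1] for s in strata])
            n_ref, n_alt = ref_all.size, alt_all.size
            if n_ref == 0 or n_alt == 0 or np.mean(ref_all) == 0:
                pct = np.nan
            else:
                pct = percent_variation(ref_all, alt_all)
            usable = [s for s in strata if s[0].size and s[1].size]
            if min(n_ref, n_alt) < MIN_N_FOR_P or not usable:
                p = np.nan
            else:
                p = wilcoxon_stratified(usable)
            rows.append({
                "metabolite": met, "donor": "pooled", "day": day,
                "n_ref": n_ref, "n_alt": n_alt,
                "pct_variation": pct, "p_value": p,
                "significant": bool(np.isfinite(p) and p < alpha),
                "visual_only": min(n_ref, n_alt) < MIN_N_FOR_P,
            })
    return pd.DataFrame(rows)


@dataclass
class SelectionRules:
    """Explicit operationalization of donor-independent selection.

    A metabolite is selected iff
    * in every donor the percent-variation sign is identical over all
      assessed days (days >= onset_day with an estimate available);
    * it is significant (p < alpha) on >= min_sig_days assessed days in each
      donor — or, when any group is smaller than min_n_per_group (the
      triplicate case), in the screen pooled across donors;
    * the pooled |percent variation| at the final assessed day reaches
      magnitude_floor (a proxy for visual spectral confirmation).
    """

    onset_day: float = 14.0
    min_sig_days: int = 2
    magnitude_floor: float = 20.0
    alpha: float = 0.05
    min_n_per_group: int = 4


def select_donor_independent(screen: pd.DataFrame,
                             rules: SelectionRules | None = None) -> list[str]:
    rules = rules or SelectionRules()
    donors = sorted(d for d in screen["donor"].unique() if d != "pooled")
    if len(donors) < 2:
        raise ValueError("need screens from at least 2 donors")
    assessed = screen[screen["day"] >= rules.onset_day]
    if assessed.empty:
        raise ValueError("no assessed days at or after onset_day")
    selected = []
    for met, sub in assessed.groupby("metabolite", sort=True):
        per_donor = sub[sub["donor"] != "pooled"]
        pooled = sub[sub["donor"] == "pooled"]
        ok = True
        use_pooled_p = False
        for d in donors:
            dsub = per_donor[per_donor["donor"] == d]
            vals = dsub["pct_variation"].dropna()
            if vals.empty:
                raise ValueError(f"donor {d} has no assessable days for {met}")
            signs = np.sign(vals.to_numpy())
            if signs.size == 0 or np.any(signs == 0) or len(set(signs)) > 1:
                ok = False
                break
            if (dsub[["n_ref", "n_alt"]].min(axis=1)
                    < rules.min_n_per_group).any():
                use_pooled_p = True
        if not ok:
            continue
        # direction must also agree between donors
        first_signs = [np.sign(per_donor[per_donor["donor"] == d]
                               ["pct_variation"].dropna().iloc[-1])
                       for d in donors]
        if len(set(first_signs)) > 1:
            continue
        if use_pooled_p:
            n_sig = int(pooled["significant"].sum())
        else:
            n_sig = int(per_donor.groupby("donor")["significant"].sum().min())
        if n_sig < rules.min_sig_days:
            continue
        final_day = pooled["day"].max()
        final_pct = pooled.loc[pooled["day"] == final_day,
                               "pct_variation"]
        if final_pct.empty or not np.isfinite(final_pct.iloc[0]):
            continue
        if abs(final_pct.iloc[0]) < rules.magnitude_floor:
            continue
        selected.append(met)
    return selected


# ---------------------------------------------------------------------------
# Spearman maps

@lru_cache(maxsize=8)
def _exact_rho_null(n: int) -> np.ndarray:
    """Null distribution of Spearman rho for untied samples of size n."""
    base = np.arange(1, n + 1, dtype=float)
    denom = n * (n ** 2 - 1)
    rhos = []
    for perm in permutations(range(n)):
        d2 = float(np.sum((base - base[list(perm)]) ** 2))
        rhos.append(1.0 - 6.0 * d2 / denom)
    return np.sort(np.asarray(rhos))


def spearman_rho_p(x, y, exact_limit: int = 9) -> tuple[float, float]:
    """Mid-rank Spearman rho with a two-sided p.

    Exact permutation p for untied data with n <= exact_limit, otherwise the
    t approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples of length >= 3")
    rho = float(stats.spearmanr(x, y).statistic)
    n = x.size
    has_ties = (np.unique(x).size < n) or (np.unique(y).size < n)
    if not has_ties and n <= exact_limit:
        null = _exact_rho_null(n)
        p = float(np.mean(np.abs(null) >= abs(rho) - 1e-12))
        return rho, p
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    return rho, float(2.0 * stats.t.sf(abs(t), df=n - 2))


def pair_group_means(table: pd.DataFrame, variables: list[str],
                     by=("donor", "day")) -> pd.DataFrame:
    """Group means used to pair compartments whose replicates do not match
    one-to-one (trajectory-level correlation)."""
    return table.groupby(list(by))[variables].mean()


def spearman_map(A: pd.DataFrame, B: pd.DataFrame | None = None,
                 rho_min: float = 0.8, p_max: float = 0.001) -> pd.DataFrame:
    """Thresholded Spearman correlation pairs.

    A (and B, if given) are aligned tables (rows = paired observations,
    columns = variables).  Without B, all within-A pairs are tested; with B,
    all A-to-B pairs (rows must align, e.g. via `pair_group_means` on a
    shared (donor, day) index).  Only pairs with |rho| > rho_min and
    p < p_max are retained.
    """
    if B is not None:
        common = A.index.intersection(B.index)
        if len(common) < 3:
            raise ValueError("fewer than 3 aligned observations")
        A = A.loc[common]
        B = B.loc[common]
        pairs = [(a, b) for a in A.columns for b in B.columns]
        get = lambda a, b: (A[a].to_numpy(), B[b].to_numpy())
    else:
        cols = list(A.columns)
        pairs = [(a, b) for i, a in enumerate(cols) for b in cols[i + 1:]]
        get = lambda a, b: (A[a].to_numpy(), A[b].to_numpy())
    rows = []
    for a, b in pairs:
        x, y = get(a, b)
        okmask = np.isfinite(x) & np.isfinite(y)
        if okmask.sum() < 3:
            continue
        rho, p = spearman_rho_p(x[okmask], y[okmask])
        if abs(rho) > rho_min and p < p_max:
            rows.append({"variable_a": a, "variable_b": b,
                         "rho": rho, "p_value": p})
    return pd.DataFrame(rows, columns=["variable_a", "variable_b",
                                       "rho", "p_value"])
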