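"""Normalization ladder, group comparisons and density-stability
correlation profiles.

The ladder applied to every cell n of construct i in condition j:

* ``tau_n``   = eGFP lifetime / CayRFP lifetime of the same cell
  (and ``k_n`` for the initial expression rates);
* ``fc_tau``  = tau_n / median tau_n of the unmutated reference construct
  in the same condition j;
* ``norm_fc_tau`` = fc_tau(siRNA j) / median fc_tau(siCtrl) of the same
  construct — the RNAi effect in isolation.

Group differences use the two-sided Mann-Whitney U test (exact null
enumeration for small tie-free samples, normal approximation with tie and
continuity correction otherwise) with the conventional star mapping.
Density-stability correlation profiles are per-codon Pearson coefficients
across constructs between simulated ribosome occupancy and a per-construct
central stability measure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .tasep import DensityProfile

__all__ = [
    "normalize_per_cell",
    "fold_change",
    "rnai_relative_fc",
    "mannwhitney_u",
    "significance_stars",
    "CorrelationProfile",
    "correlation_profile",
    "summarize",
    "bootstrap_median_ci",
]

CONDITION_COLS = ["construct", "sirna", "cell_line", "experiment"]


# ---------------------------------------------------------------------------
# Normalization ladder

def normalize_per_cell(fits: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Per-cell eGFP/CayRFP ratios from a fit table.

    ``fits`` is the tidy fit-table dialect (one row per cell x channel with
    ``delta_hat``, ``m0ktl_hat``, ``converged``, ``non_expressing`` plus
    condition columns).  Cells failing either channel (unconverged,
    non-expressing, or non-positive rates) are dropped; the counts are
    returned alongside the per-cell table.
    """
    dropped = {"missing_channel": 0, "failed_fit": 0, "invalid_ratio": 0}
    rows = []
    for cell_id, g in fits.groupby("cell_id", sort=False):
        by_ch = {r["channel"]: r for _, r in g.iterrows()}
        if not {"eGFP", "CayRFP"} <= set(by_ch):
            dropped["missing_channel"] += 1
            continue
        gfp, rfp = by_ch["eGFP"], by_ch["CayRFP"]
        ok = all(
            bool(r["converged"]) and not bool(r["non_expressing"])
            for r in (gfp, rfp)
        )
        if not ok:
            dropped["failed_fit"] += 1
            continue
        if not (gfp["delta_hat"] > 0 and rfp["delta_hat"] > 0
                and gfp["m0ktl_hat"] > 0 and rfp["m0ktl_hat"] > 0):
            dropped["invalid_ratio"] += 1
            continue
        row = {c: gfp[c] for c in CONDITION_COLS if c in gfp.index}
        row.update(
            cell_id=cell_id,
            tau_n=float(rfp["delta_hat"] / gfp["delta_hat"]),
            k_n=float(gfp["m0ktl_hat"] / rfp["m0ktl_hat"]),
        )
        rows.append(row)
    return pd.DataFrame(rows), dropped


def fold_change(
    cells: pd.DataFrame,
    reference_construct: str = "eGFP",
    condition_keys: tuple[str, ...] = ("sirna", "cell_line"),
) -> pd.DataFrame:
    """Per-cell fold change vs the unmutated-reference median in the same
    condition; the reference construct's median fc is 1 by construction."""
    keys = [k for k in condition_keys if k in cells.columns]
    out = cells.reset_index(drop=True).copy()
    out["fc_tau"] = np.nan
    out["fc_k"] = np.nan
    grouped = out.groupby(keys) if keys else [((), out)]
    for key, g in grouped:
        ref = g[g["construct"] == reference_construct]
        if ref.empty:
            raise ValueError(
                f"reference construct {reference_construct!r} missing in "
                f"condition {key!r}"
            )
        med_tau = float(ref["tau_n"].median())
        med_k = float(ref["k_n"].median())
        if not med_tau > 0:
            raise ValueError(f"non-positive reference median in condition {key!r}")
        out.loc[g.index, "fc_tau"] = g["tau_n"] / med_tau
        if med_k > 0:
            out.loc[g.index, "fc_k"] = g["k_n"] / med_k
    return out


def rnai_relative_fc(
    cells: pd.DataFrame,
    sictrl_label: str = "siCtrl",
    condition_keys: tuple[str, ...] = ("cell_line",),
) -> pd.DataFrame:
    """Fold change relative to the same construct's siCtrl median
    (``norm_fc_tau``); computed for every row, so siCtrl rows themselves
    have median 1 per construct."""
    keys = ["construct"] + [k for k in condition_keys if k in cells.columns]
    out = cells.reset_index(drop=True).copy()
    out["norm_fc_tau"] = np.nan
    ctrl = out[out["sirna"] == sictrl_label]
    if ctrl.empty:
        raise ValueError(f"no rows with sirna == {sictrl_label!r}")
    ctrl_median = ctrl.groupby(keys)["fc_tau"].median()
    for key, g in out.groupby(keys):
        if key not in ctrl_median.index:
            raise ValueError(f"missing siCtrl reference for {key!r}")
        ref = float(ctrl_median.loc[key])
        if not ref > 0:
            raise ValueError(f"non-positive siCtrl median for {key!r}")
        out.loc[g.index, "norm_fc_tau"] = g["fc_tau"] / ref
    return out


# ---------------------------------------------------------------------------
# Mann-Whitney U

def _exact_u_counts(n1: int, n2: int) -> np.ndarray:
    """Number of labelings with each U value, via the Mann-Whitney
    recurrence  N(u; n1, n2) = N(u - n2; n1 - 1, n2) + N(u; n1, n2 - 1)."""
    table: dict[tuple[int, int], np.ndarray] = {}

    def rec(a: int, b: int) -> np.ndarray:
        if (a, b) in table:
            return table[(a, b)]
        if a == 0 or b == 0:
            out = np.array([1.0])
        else:
            left = rec(a - 1, b)   # U contributions shifted by b
            right = rec(a, b - 1)
            out = np.zeros(a * b + 1)
            out[b : b + left.size] += left
            out[: right.size] += right
        table[(a, b)] = out
        return out

    return rec(n1, n2)


def mannwhitney_u(
    group_a: np.ndarray, group_b: np.ndarray, exact_max_n: int = 16
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U_a, p).

    Exact null enumeration when the pooled sample is tie-free with
    ``n_a + n_b <= exact_max_n``, otherwise the normal approximation with
    tie and continuity correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    u_a = float(sum((x > b).sum() + 0.5 * (x == b).sum() for x in a))
    pooled = np.concatenate([a, b])
    ties = np.unique(pooled).size < pooled.size
    n1, n2 = a.size, b.size
    if not ties and n1 + n2 <= exact_max_n:
        counts = _exact_u_counts(n1, n2)
        total = counts.sum()
        u = int(round(u_a))
        p_low = counts[: u + 1].sum() / total
        p_high = counts[u:].sum() / total
        p = min(1.0, 2.0 * min(p_low, p_high))
        return u_a, float(p)
    # normal approximation
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    n = n1 + n2
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return u_a, 1.0
    z = (abs(u_a - mu) - 0.5) / math.sqrt(sigma2)
    z = max(z, 0.0)
    p = 2.0 * sps.norm.sf(z)
    return u_a, float(min(p, 1.0))


def significance_stars(p: float) -> str:
    """Star label for a p-value; boundary values fall in the less
    significant class (p = 0.05 -> 'ns')."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value {p} outside [0, 1]")
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 5e-2:
        return "*"
    return "ns"


# ---------------------------------------------------------------------------
# Correlation profiles

@dataclass
class CorrelationProfile:
    r: np.ndarray                # per-codon Pearson r (NaN where undefined)
    defined: np.ndarray          # bool mask: density variance > 0
    n_constructs: int
    p: np.ndarray | None = None
    constructs: list[str] = field(default_factory=list)


def correlation_profile(
    construct_stats: dict[str, float],
    profiles: dict[str, DensityProfile | np.ndarray],
    compute_p: bool = False,
) -> CorrelationProfile:
    """Per-codon Pearson r across constructs between simulated density and
    a per-construct stability measure.

    Positions where the density has zero variance across constructs are
    flagged undefined (r = NaN); a constant stability vector makes every
    position undefined.
    """
    names = sorted(construct_stats)
    if len(names) < 3:
        raise ValueError("need >= 3 constructs for a correlation profile")
    if set(names) - set(profiles):
        raise ValueError(f"missing profiles for {sorted(set(names) - set(profiles))}")
    dens = []
    for nm in names:
        p = profiles[nm]
        dens.append(p.rho if isinstance(p, DensityProfile) else np.asarray(p, float))
    lengths = {d.shape[0] for d in dens}
    if len(lengths) != 1:
        raise ValueError(f"profiles on mismatched codon grids: {sorted(lengths)}")
    D = np.vstack(dens)                      # constructs x codons
    y = np.array([construct_stats[nm] for nm in names], dtype=float)

    Dc = D - D.mean(axis=0)
    yc = y - y.mean()
    sd_d = np.sqrt((Dc**2).sum(axis=0))
    sd_y = math.sqrt(float((yc**2).sum()))
    defined = (sd_d > 0) & (sd_y > 0)
    r = np.full(D.shape[1], np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        r[defined] = (Dc[:, defined] * yc[:, None]).sum(axis=0) / (
            sd_d[defined] * sd_y
        )
    r = np.clip(r, -1.0, 1.0)
    pvals = None
    if compute_p:
        n = len(names)
        pvals = np.full_like(r, np.nan)
        ok = defined & (np.abs(r) < 1.0)
        tstat = r[ok] * np.sqrt((n - 2) / (1 - r[ok] ** 2))
        pvals[ok] = 2 * sps.t.sf(np.abs(tstat), df=n - 2)
        pvals[defined & (np.abs(r) >= 1.0)] = 0.0
    return CorrelationProfile(
        r=r, defined=defined, n_constructs=len(names), p=pvals, constructs=names
    )


# ---------------------------------------------------------------------------
# Summaries

def summarize(
    cells: pd.DataFrame,
    value: str = "tau_n",
    by: tuple[str, ...] = ("construct", "sirna", "cell_line"),
    experiment_col: str = "experiment",
) -> pd.DataFrame:
    """Median and (unscaled) MAD per condition, plus per-experiment medians
    as separate rows (``experiment == '<pooled>'`` marks the pooled rows)."""
    keys = [k for k in by if k in cells.columns]
    rows = []

    def mad(x: pd.Series) -> float:
        return float((x - x.median()).abs().median())

    for key, g in cells.groupby(keys) if keys else [((), cells)]:
        base = dict(zip(keys, key if isinstance(key, tuple) else (key,)))
        rows.append(
            {**base, experiment_col: "<pooled>", "n_cells": len(g),
             "median": float(g[value].median()), "mad": mad(g[value])}
        )
        if experiment_col in g.columns:
            for exp, ge in g.groupby(experiment_col):
                rows.append(
                    {**base, experiment_col: exp, "n_cells": len(ge),
                     "median": float(ge[value].median()), "mad": mad(ge[value])}
                )
    return pd.DataFrame(rows)


def bootstrap_median_ci(
    values: np.ndarray,
    n_boot: int = 1000,
    level: float = 0.95,
    rng_seed: int = 0,
) -> tuple[float, float, float]:
    """Percentile bootstrap CI for the median: (median, lo, hi)."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    rng = np.random.default_rng(rng_seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    meds = np.median(x[idx], axis=1)
    alpha = (1.0 - level) / 2.0
    return (
        float(np.median(x)),
        float(np.quantile(meds, alpha)),
        float(np.quantile(meds, 1.0 - alpha)),
    )
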