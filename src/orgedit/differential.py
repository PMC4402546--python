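"""Differential editing: finding sites with reduced extent after silencing.

The procedure follows the dual-control design of a VIGS silencing experiment.
Replicates of each condition are pooled (C and T read counts summed), then
each site is tested with a Pearson chi-square on the 2x2 table of pooled
(nC, nT) — treatment versus each control — with one degree of freedom and no
continuity correction. Per organelle, the per-test threshold is the familywise
rate Bonferroni-divided by that organelle's edited-site universe size. A site
must additionally show an absolute extent reduction of at least ``min_delta``
(default 0.1, i.e. 10 percentage points).

Because virus inoculation alone can depress editing, sites that are already
significantly reduced in the GFP-silenced control relative to uninoculated
plants are flagged as control-affected and excluded before treatment testing.
A site is declared significantly reduced only when it passes the chi-square
and delta gates against BOTH controls.
"""

from __future__ import annotations

from math import floor
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigError, InputError
from .io import CONDITIONS
from .sites import SITE_COLUMNS, SITE_KEY

DIFF_COLUMNS = SITE_COLUMNS + [
    "extent_uninoc",
    "extent_gfp",
    "extent_treat",
    "delta_vs_uninoc",
    "delta_vs_gfp",
    "chi2_vs_uninoc",
    "chi2_vs_gfp",
    "p_vs_uninoc",
    "p_vs_gfp",
    "threshold",
    "excluded_control_affected",
    "significant",
]


def pool_replicates(counts: pd.DataFrame) -> pd.DataFrame:
    """Sum nC, nT, nOther over the libraries of one condition, per site."""
    pooled = (
        counts.groupby(SITE_COLUMNS, sort=True, as_index=False)[["nC", "nT", "nOther"]]
        .sum()
    )
    return pooled


def bonferroni_threshold(alpha_family: float, n_sites: int) -> float:
    """Per-test error rate achieving the familywise rate over ``n_sites`` tests."""
    if n_sites < 1:
        raise ConfigError("Bonferroni correction needs at least one test")
    if not (0 < alpha_family < 1):
        raise ConfigError("alpha_family must be in (0, 1)")
    return alpha_family / n_sites


def chi2_2x2(
    a: tuple[int, int], b: tuple[int, int], continuity: bool = False
) -> tuple[float, float]:
    """Pearson chi-square (1 df) comparing C/T proportions of two groups.

    ``a`` and ``b`` are (nC, nT) pairs, e.g. pooled control vs treatment. No
    continuity correction by default. A zero column margin (no C anywhere, or
    no T anywhere) leaves the test undefined: returns (nan, nan).
    """
    table = np.array([[a[0], a[1]], [b[0], b[1]]], dtype=float)
    if (table.sum(axis=1) == 0).any():
        raise InputError("chi-square needs C+T coverage in both groups")
    if (table.sum(axis=0) == 0).any():
        return float("nan"), float("nan")
    res = stats.chi2_contingency(table, correction=continuity)
    return float(res.statistic), float(res.pvalue)


def _chi2_arrays(c1, t1, c2, t2):
    """Vectorised closed-form 2x2 Pearson chi-square: n*(ad-bc)^2/(r1*r2*c1*c2)."""
    c1, t1, c2, t2 = (np.asarray(x, dtype=float) for x in (c1, t1, c2, t2))
    n = c1 + t1 + c2 + t2
    r1, r2 = c1 + t1, c2 + t2
    k1, k2 = c1 + c2, t1 + t2
    denom = r1 * r2 * k1 * k2
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = n * (c1 * t2 - t1 * c2) ** 2 / denom
    stat = np.where(denom > 0, stat, np.nan)
    p = np.where(np.isnan(stat), np.nan, stats.chi2.sf(stat, df=1))
    return stat, p


def compare_site_sets(a: Sequence, b: Sequence) -> tuple[int, int, int]:
    """Overlap of two site sets: (intersection size, %A shared, %B shared).

    Percentages are rounded half-up to whole percent; an empty set shares 0%.
    """
    sa, sb = set(a), set(b)
    inter = len(sa & sb)
    pct = lambda n, d: int(floor(100.0 * n / d + 0.5)) if d else 0
    return inter, pct(inter, len(sa)), pct(inter, len(sb))


def _pooled_by_condition(
    counts: pd.DataFrame, design: Mapping[str, str]
) -> dict[str, pd.DataFrame]:
    missing = set(counts["library_id"]) - set(design)
    if missing:
        raise InputError(f"libraries absent from design: {sorted(missing)}")
    cond = counts["library_id"].map(dict(design))
    pooled = {}
    for c in CONDITIONS:
        sub = counts.loc[cond == c]
        if sub.empty:
            raise InputError(f"design error: no libraries for condition {c!r}")
        pooled[c] = pool_replicates(sub).set_index(SITE_KEY)
    return pooled


def exclude_control_affected(
    counts: pd.DataFrame,
    design: Mapping[str, str],
    threshold: float | Mapping[str, float],
    min_delta: float = 0.1,
) -> pd.DataFrame:
    """Flag sites already reduced in the GFP-silenced control vs uninoculated.

    ``threshold`` is the per-test p-value cutoff (a single value or a map from
    organelle to value). Returns the site table with a boolean
    ``control_affected`` column; flagged sites are removed from treatment
    testing downstream.
    """
    cond = counts["library_id"].map(dict(design))
    pooled = {}
    for c in ("uninoculated", "gfp_silenced"):
        sub = counts.loc[cond == c]
        if sub.empty:
            raise InputError(f"design error: no libraries for condition {c!r}")
        pooled[c] = pool_replicates(sub).set_index(SITE_KEY)
    base = pooled["uninoculated"].reset_index()[SITE_COLUMNS]
    idx = pd.MultiIndex.from_frame(base[SITE_KEY])
    uC = pooled["uninoculated"]["nC"].reindex(idx).to_numpy(dtype=float)
    uT = pooled["uninoculated"]["nT"].reindex(idx).to_numpy(dtype=float)
    gC = pooled["gfp_silenced"]["nC"].reindex(idx).to_numpy(dtype=float)
    gT = pooled["gfp_silenced"]["nT"].reindex(idx).to_numpy(dtype=float)
    if isinstance(threshold, Mapping):
        thr = base["organelle"].map(dict(threshold)).to_numpy(dtype=float)
    else:
        thr = np.full(len(base), float(threshold))
    with np.errstate(invalid="ignore", divide="ignore"):
        ext_u = np.where(uC + uT > 0, uT / (uC + uT), np.nan)
        ext_g = np.where(gC + gT > 0, gT / (gC + gT), np.nan)
    _, p = _chi2_arrays(uC, uT, gC, gT)
    delta = ext_u - ext_g
    flagged = (p < thr) & (delta >= min_delta)
    out = base.copy()
    out["control_affected"] = np.where(np.isnan(p) | np.isnan(delta), False, flagged)
    return out


def call_reduced_sites(
    counts: pd.DataFrame,
    design: Mapping[str, str],
    alpha_family: float = 1e-3,
    min_delta: float = 0.1,
    mode: str = "pooled",
) -> pd.DataFrame:
    """Run the full dual-control differential-editing procedure.

    Per organelle, the Bonferroni divisor is the number of sites of that
    organelle present in ``counts`` (the edited-site universe), counted before
    the control-affected exclusion. ``mode='pooled'`` pools treatment
    replicates before testing; ``mode='per_replicate'`` tests each treatment
    replicate against the pooled controls and requires every replicate to pass
    (the reported statistic is then the least favourable replicate's).

    A site is ``significant`` iff it is not control-affected and shows
    p < threshold AND delta >= min_delta against BOTH controls.
    """
    if mode not in ("pooled", "per_replicate"):
        raise ConfigError(f"unknown mode {mode!r}")
    if not (0 <= min_delta <= 1):
        raise ConfigError("min_delta must be in [0, 1]")
    pooled = _pooled_by_condition(counts, design)
    base = pooled["uninoculated"].reset_index()[SITE_COLUMNS]

    # per-organelle Bonferroni threshold over the site universe in the table
    n_by_org = base.groupby("organelle")["genomic_pos_0based"].count()
    thr_by_org = {
        org: bonferroni_threshold(alpha_family, int(n)) for org, n in n_by_org.items()
    }
    thr = base["organelle"].map(thr_by_org).to_numpy(dtype=float)

    def aligned(cond: str, col: str) -> np.ndarray:
        idx = pd.MultiIndex.from_frame(base[SITE_KEY])
        return pooled[cond][col].reindex(idx).to_numpy(dtype=float)

    uC, uT = aligned("uninoculated", "nC"), aligned("uninoculated", "nT")
    gC, gT = aligned("gfp_silenced", "nC"), aligned("gfp_silenced", "nT")

    def extent(c, t):
        tot = c + t
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, t / tot, np.nan)

    ext_u, ext_g = extent(uC, uT), extent(gC, gT)

    # control-affected screen: GFP-silenced vs uninoculated
    chi_ctrl, p_ctrl = _chi2_arrays(uC, uT, gC, gT)
    delta_ctrl = ext_u - ext_g
    control_affected = (p_ctrl < thr) & (delta_ctrl >= min_delta)

    if mode == "pooled":
        treat_groups = [pooled["treatment"]]
    else:
        cond = counts["library_id"].map(dict(design))
        treat = counts.loc[cond == "treatment"]
        treat_groups = [
            pool_replicates(treat[treat["library_id"] == lib]).set_index(SITE_KEY)
            for lib in sorted(treat["library_id"].unique())
        ]

    idx = pd.MultiIndex.from_frame(base[SITE_KEY])

    def versus(ctrlC, ctrlT, ext_ctrl):
        """Worst-case (least significant) comparison over treatment groups."""
        stat_w = delta_w = ext_w = None
        p_w = None
        ok_all = np.ones(len(base), dtype=bool)
        for grp in treat_groups:
            tC = grp["nC"].reindex(idx).to_numpy(dtype=float)
            tT = grp["nT"].reindex(idx).to_numpy(dtype=float)
            stat, p = _chi2_arrays(ctrlC, ctrlT, tC, tT)
            ext_t = extent(tC, tT)
            delta = ext_ctrl - ext_t
            ok = (p < thr) & (delta >= min_delta)
            ok = np.where(np.isnan(p) | np.isnan(delta), False, ok)
            ok_all &= ok
            if p_w is None:
                stat_w, p_w, delta_w, ext_w = stat, p, delta, ext_t
            else:
                take = np.isnan(p_w) | (p > p_w)
                stat_w = np.where(take, stat, stat_w)
                delta_w = np.where(take, delta, delta_w)
                ext_w = np.where(take, ext_t, ext_w)
                p_w = np.where(take, p, p_w)
        return stat_w, p_w, delta_w, ext_w, ok_all

    chi_u, p_u, d_u, ext_t, ok_u = versus(uC, uT, ext_u)
    chi_g, p_g, d_g, _, ok_g = versus(gC, gT, ext_g)

    out = base.copy()
    out["extent_uninoc"] = ext_u
    out["extent_gfp"] = ext_g
    out["extent_treat"] = ext_t
    out["delta_vs_uninoc"] = d_u
    out["delta_vs_gfp"] = d_g
    out["chi2_vs_uninoc"] = chi_u
    out["chi2_vs_gfp"] = chi_g
    out["p_vs_uninoc"] = p_u
    out["p_vs_gfp"] = p_g
    out["threshold"] = thr
    out["excluded_control_affected"] = control_affected
    out["significant"] = ~control_affected & ok_u & ok_g
    return out[DIFF_COLUMNS]
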