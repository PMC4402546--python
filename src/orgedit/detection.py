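"""Calling C-to-U editing sites with an error-calibrated likelihood ratio test.

At a candidate site, condition on the reads showing C or T (other bases carry
no editing signal) and model each such read as showing T with probability
theta. Under the null of no editing, theta equals the library's empirical
C-to-T sequencing error rate eps; under the alternative the site is edited
with extent p, giving

    theta = p + (1 - p) * eps,   theta in [eps, 1].

The likelihood-ratio statistic is lambda = 2 * (l(theta_hat) - l(eps)) with
l(theta) = nT*log(theta) + nC*log(1 - theta) and theta_hat = max(eps,
nT/(nC+nT)). Because the alternative is one-sided with the null on the
boundary of the parameter space, lambda's null distribution is the chi-bar-
square mixture 0.5*chi2_0 + 0.5*chi2_1 rather than a plain chi2_1; using the
mixture keeps the test exact-to-conservative, never anti-conservative.
The editing-extent MLE is recovered as p_hat = (theta_hat - eps) / (1 - eps).

Error rates are estimated per library from genome-wide mismatch tallies with
a pseudocount, excluding candidate/edited C positions from the C-to-T class
so genuine editing cannot inflate the error model; a two-pass driver first
calls provisional edits under a prior error rate, then re-estimates and
re-calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy.special import xlogy
from scipy.stats import chi2

from .exceptions import ConfigError, InputError
from .sites import SITE_KEY

DEFAULT_PRIOR_EPSILON = 1e-3


class LRTResult(NamedTuple):
    extent_mle: float
    lrt_stat: float
    p_value: float


@dataclass
class LibraryErrorProfile:
    """Empirical per-substitution mismatch rates for one library."""

    library_id: str
    rate: dict[str, float] = field(default_factory=dict)
    bases_observed: dict[str, int] = field(default_factory=dict)

    def epsilon(self) -> float:
        """The C-to-T error rate used by the editing test."""
        if "C>T" not in self.rate:
            raise InputError(f"library {self.library_id}: C>T rate undefined (no C coverage)")
        return self.rate["C>T"]


def estimate_error_rates(
    tallies: pd.DataFrame,
    library_id: str,
    exclude_c_positions: Iterable[tuple[str, int]] = (),
    pseudocount: float = 0.5,
) -> LibraryErrorProfile:
    """Estimate per-substitution error rates from genome-wide base tallies.

    rate(X>Y) = (mismatches + pseudocount) / (bases at X positions + 2*pseudocount).

    Positions listed in ``exclude_c_positions`` (candidate or provisionally
    edited C sites, keyed by (organelle, 0-based position)) are dropped from
    the C reference class entirely, so editing-derived T reads never enter the
    C>T numerator or denominator. The pseudocount keeps every rate strictly
    positive; a reference base class with zero aligned bases yields no rate
    entries for that base and is flagged via ``bases_observed``.
    """
    if pseudocount < 0:
        raise ConfigError("pseudocount must be >= 0")
    excl = set(exclude_c_positions)
    if excl:
        is_c = tallies["sense_ref"] == "C"
        keys = list(zip(tallies["organelle"], tallies["pos_0based"]))
        drop = np.array([k in excl for k in keys]) & is_c.to_numpy()
        tallies = tallies.loc[~drop]
    profile = LibraryErrorProfile(library_id=library_id)
    for ref_base in "ACGT":
        sub = tallies[tallies["sense_ref"] == ref_base]
        aligned = int(sub[["nA", "nC", "nG", "nT", "nOther"]].to_numpy().sum())
        profile.bases_observed[ref_base] = aligned
        if aligned == 0 and pseudocount == 0:
            continue  # rate undefined for this class
        for obs in "ACGT":
            if obs == ref_base:
                continue
            mism = int(sub[f"n{obs}"].sum())
            profile.rate[f"{ref_base}>{obs}"] = (mism + pseudocount) / (
                aligned + 2 * pseudocount
            )
    return profile


# ---------------------------------------------------------------------------
# likelihood ratio test
# ---------------------------------------------------------------------------

def _lrt_arrays(nC, nT, epsilon):
    """Vectorised LRT; returns (extent_mle, lambda, p_value) arrays."""
    nC = np.asarray(nC, dtype=float)
    nT = np.asarray(nT, dtype=float)
    epsilon = np.asarray(epsilon, dtype=float)
    total = nC + nT
    with np.errstate(divide="ignore", invalid="ignore"):
        theta_hat = np.maximum(epsilon, nT / total)
        loglik = lambda th: xlogy(nT, th) + xlogy(nC, 1.0 - th)
        lam = 2.0 * (loglik(theta_hat) - loglik(epsilon))
    lam = np.where(theta_hat <= epsilon, 0.0, lam)  # observed T fraction <= eps
    lam = np.maximum(lam, 0.0)  # guard against rounding just below zero
    p = np.where(lam > 0, 0.5 * chi2.sf(lam, df=1), 1.0)
    p_hat = (theta_hat - epsilon) / (1.0 - epsilon)
    return p_hat, lam, p


def lrt_edit_test(nC: int, nT: int, epsilon: float) -> LRTResult:
    """Test one site in one library for editing.

    Parameters
    ----------
    nC, nT : reads showing C and T at the site (sense orientation)
    epsilon : the library's empirical C>T error rate, 0 <= eps < 1

    Returns ``(extent_mle, lrt_stat, p_value)``. When nT = 0 (or the T
    fraction does not exceed eps) the MLE sits on the null boundary:
    lambda = 0 and p = 1. With eps = 0 and nT > 0 the null likelihood is
    zero, so lambda is infinite and p = 0.
    """
    if nC < 0 or nT < 0:
        raise InputError("counts must be non-negative")
    if nC + nT == 0:
        raise InputError("no C/T coverage at site: LRT undefined")
    if not (0 <= epsilon < 1):
        raise ConfigError(f"epsilon = {epsilon} outside [0, 1)")
    p_hat, lam, p = _lrt_arrays(nC, nT, epsilon)
    return LRTResult(float(p_hat), float(lam), float(p))


def call_editing_sites(
    counts: pd.DataFrame,
    epsilon: Mapping[str, float] | Mapping[str, LibraryErrorProfile] | float,
    alpha_family: float = 1e-3,
    n_scanned: int | None = None,
    min_libraries: int = 2,
) -> pd.DataFrame:
    """Apply the LRT per site and library and call the edited-site universe.

    The per-test detection threshold is ``alpha_family`` Bonferroni-divided by
    the number of scanned candidate sites (``n_scanned``, default: distinct
    sites in the table). A site enters the edited universe when it is
    individually significant in at least ``min_libraries`` libraries.

    Returns the counts table augmented with ``extent_mle``, ``lrt_stat``,
    ``p_value``, ``is_edited`` (library-level call) and ``site_edited``
    (site-level verdict shared by all rows of a site). Rows without C/T
    coverage get NaN statistics and are never significant.
    """
    if not (0 < alpha_family < 1):
        raise ConfigError("alpha_family must be in (0, 1)")
    if counts.empty:
        out = counts.copy()
        for col in ("extent_mle", "lrt_stat", "p_value"):
            out[col] = pd.Series(dtype=float)
        out["is_edited"] = pd.Series(dtype=bool)
        out["site_edited"] = pd.Series(dtype=bool)
        return out
    if n_scanned is None:
        n_scanned = len(counts.drop_duplicates(subset=SITE_KEY))
    threshold = alpha_family / n_scanned

    if isinstance(epsilon, (int, float)):
        eps = np.full(len(counts), float(epsilon))
    else:
        def _eps_of(lib: str) -> float:
            val = epsilon[lib]
            return val.epsilon() if isinstance(val, LibraryErrorProfile) else float(val)

        eps = counts["library_id"].map({k: _eps_of(k) for k in set(counts["library_id"])})
        eps = eps.to_numpy(dtype=float)

    nC = counts["nC"].to_numpy()
    nT = counts["nT"].to_numpy()
    covered = (nC + nT) > 0
    p_hat = np.full(len(counts), np.nan)
    lam = np.full(len(counts), np.nan)
    pval = np.full(len(counts), np.nan)
    p_hat[covered], lam[covered], pval[covered] = _lrt_arrays(
        nC[covered], nT[covered], eps[covered]
    )

    out = counts.copy()
    out["extent_mle"] = p_hat
    out["lrt_stat"] = lam
    out["p_value"] = pval
    out["is_edited"] = covered & (pval < threshold)
    n_sig = out.groupby(SITE_KEY)["is_edited"].transform("sum")
    out["site_edited"] = n_sig >= min_libraries
    return out


def two_pass_error_profiles(
    tallies_by_library: Mapping[str, pd.DataFrame],
    counts: pd.DataFrame,
    prior_epsilon: float = DEFAULT_PRIOR_EPSILON,
    alpha_family: float = 1e-3,
    n_scanned: int | None = None,
    pseudocount: float = 0.5,
) -> dict[str, LibraryErrorProfile]:
    """Estimate error profiles without letting true edits inflate them.

    Pass 1 calls provisional edits under a fixed prior C>T error rate; pass 2
    re-estimates each library's rates from the genome-wide tallies with the
    provisionally edited positions excluded from the C class.
    """
    provisional = call_editing_sites(
        counts, prior_epsilon, alpha_family=alpha_family, n_scanned=n_scanned, min_libraries=1
    )
    edited = provisional.loc[provisional["site_edited"], SITE_KEY].drop_duplicates()
    exclude = set(zip(edited["organelle"], edited["genomic_pos_0based"]))
    return {
        lib: estimate_error_rates(tal, lib, exclude_c_positions=exclude, pseudocount=pseudocount)
        for lib, tal in tallies_by_library.items()
    }
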