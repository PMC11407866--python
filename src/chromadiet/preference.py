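"""Preference-ranking analysis: simulated ranking sessions, mean ranks, a
permutation null band for random responding, rank correlations between
preference and environment curves, and Zou's confidence interval for the
difference between two dependent overlapping correlations.

Rank polarity: rank 1 = chosen first = most preferred.  When correlating
preferences with environment saturation curves, mean ranks are negated so
that larger = more preferred, matching how preferences are plotted against
saturations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "N_STIMULI",
    "simulate_ranking_session",
    "mean_ranks",
    "permutation_null_band",
    "NullBand",
    "spearman_rho",
    "zou_ci_difference",
    "preference_environment_correlation",
    "ranks_to_long",
    "long_to_ranks",
]

N_STIMULI = 8


def simulate_ranking_session(
    strengths: np.ndarray, noise_sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Simulate one iterated best-choice ranking session.

    At each step the remaining stimulus with the highest (strength + fresh
    Gaussian noise) is chosen, removed and assigned the next rank; the last
    remaining stimulus is least preferred.  Returns the rank (1..n) of each
    stimulus.  ``noise_sd = 0`` gives the deterministic strength order;
    ``noise_sd = inf`` gives a uniform random permutation.
    """
    s = np.asarray(strengths, dtype=float)
    n = s.size
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    ranks = np.empty(n, dtype=int)
    remaining = list(range(n))
    for pos in range(1, n + 1):
        if np.isinf(noise_sd):
            util = rng.random(len(remaining))
        else:
            util = s[remaining] + noise_sd * rng.standard_normal(len(remaining))
        pick = remaining[int(np.argmax(util))]
        ranks[pick] = pos
        remaining.remove(pick)
    return ranks


def mean_ranks(ranks: np.ndarray) -> np.ndarray:
    """Mean rank per stimulus over all leading axes (participants, trials).

    Because every trial is a permutation of 1..n, the grand mean of the n
    stimulus means is exactly (n+1)/2.
    """
    r = np.asarray(ranks, dtype=float)
    if r.shape[-1] < 1 or r.size == 0:
        raise ValueError("need at least one trial")
    return r.reshape(-1, r.shape[-1]).mean(axis=0)


@dataclass(frozen=True)
class NullBand:
    lo: np.ndarray  # (n_stimuli,) lower percentile of null mean ranks
    hi: np.ndarray
    centre: float  # mean of band midpoints across stimuli

    def contains(self, means: np.ndarray) -> np.ndarray:
        m = np.asarray(means, dtype=float)
        return (m >= self.lo) & (m <= self.hi)


def permutation_null_band(
    n_participants: int,
    n_trials: int,
    n_perm: int = 10000,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
    n_stimuli: int = N_STIMULI,
    chunk: int = 2000,
) -> NullBand:
    """Null band of per-stimulus mean ranks under fully random responding.

    Each permutation replaces every trial of every participant with an
    independent uniform random permutation of 1..n_stimuli and records the
    per-stimulus mean rank; the band is the alpha/2 and 1 - alpha/2
    percentiles over permutations.
    """
    if n_perm < 1 or n_participants < 1 or n_trials < 1:
        raise ValueError("counts must be positive")
    rng = np.random.default_rng() if rng is None else rng
    n_obs = n_participants * n_trials
    base = np.arange(1, n_stimuli + 1)
    out = np.empty((n_perm, n_stimuli))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        block = np.tile(base, (m * n_obs, 1))
        block = rng.permuted(block, axis=1).reshape(m, n_obs, n_stimuli)
        out[done : done + m] = block.mean(axis=1)
        done += m
    lo = np.percentile(out, 100 * alpha / 2, axis=0)
    hi = np.percentile(out, 100 * (1 - alpha / 2), axis=0)
    return NullBand(lo=lo, hi=hi, centre=float((lo + hi).mean() / 2))


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman's rank correlation (ties mid-ranked).

    Returns NaN with a warning when either input has zero rank variance
    (the coefficient is undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("x and y must be equal-length 1-D arrays, n >= 2")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        warnings.warn("zero rank variance: Spearman's rho undefined")
        return float("nan")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def zou_ci_difference(
    r12: float, r13: float, r23: float, n: int, alpha: float = 0.05
) -> tuple[float, float]:
    """Zou's CI for the difference r12 - r13 of two dependent overlapping
    correlations (sharing variable 1), with r23 the correlation between the
    two non-shared variables.

    Combines the individual Fisher-z confidence limits of r12 and r13,
    accounting for their sampling correlation.  The interval contains 0 iff
    the difference is not significant at level alpha.
    """
    for r in (r12, r13, r23):
        if not -1.0 < r < 1.0:
            raise ValueError("correlations must lie strictly inside (-1, 1)")
    if n < 4:
        raise ValueError("need n >= 4")
    z = stats.norm.ppf(1 - alpha / 2)
    se = 1.0 / np.sqrt(n - 3)

    def fisher_limits(r: float) -> tuple[float, float]:
        zr = np.arctanh(r)
        return float(np.tanh(zr - z * se)), float(np.tanh(zr + z * se))

    l1, u1 = fisher_limits(r12)
    l2, u2 = fisher_limits(r13)
    # sampling correlation between the two correlation estimates
    num = (r23 - 0.5 * r12 * r13) * (1 - r12**2 - r13**2 - r23**2) + r23**3
    den = (1 - r12**2) * (1 - r13**2)
    c = num / den
    d = r12 - r13
    lo = d - np.sqrt((r12 - l1) ** 2 + (u2 - r13) ** 2 - 2 * c * (r12 - l1) * (u2 - r13))
    hi = d + np.sqrt((u1 - r12) ** 2 + (r13 - l2) ** 2 - 2 * c * (u1 - r12) * (r13 - l2))
    return float(lo), float(hi)


def preference_environment_correlation(
    mean_prefs: dict[str, np.ndarray],
    env_curves: dict[str, np.ndarray],
    ranking: bool = True,
) -> pd.DataFrame:
    """All pairwise Spearman correlations between group preference curves and
    per-location environment saturation curves.

    Rows are participant groups, columns environment locations.  For
    ranking-task input (``ranking=True``) mean ranks are negated first so
    larger = more preferred.
    """
    rows = {}
    for g, pref in mean_prefs.items():
        p = -np.asarray(pref, dtype=float) if ranking else np.asarray(pref, dtype=float)
        rows[g] = {
            loc: spearman_rho(p, np.asarray(env, dtype=float))
            for loc, env in env_curves.items()
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def ranks_to_long(ranks: np.ndarray) -> pd.DataFrame:
    """(participants, trials, stimuli) rank array -> long-format table."""
    r = np.asarray(ranks)
    if r.ndim != 3:
        raise ValueError("expected (participants, trials, stimuli)")
    P, T, S = r.shape
    idx = np.indices((P, T, S))
    return pd.DataFrame(
        {
            "participant": idx[0].ravel(),
            "trial": idx[1].ravel(),
            "stimulus": idx[2].ravel() + 1,
            "rank": r.ravel(),
        }
    )


def long_to_ranks(df: pd.DataFrame) -> np.ndarray:
    """Inverse of :func:`ranks_to_long`."""
    P = df["participant"].nunique()
    T = df["trial"].nunique()
    S = df["stimulus"].nunique()
    out = np.empty((P, T, S), dtype=int)
    pi = {p: i for i, p in enumerate(sorted(df["participant"].unique()))}
    ti = {t: i for i, t in enumerate(sorted(df["trial"].unique()))}
    si = {s: i for i, s in enumerate(sorted(df["stimulus"].unique()))}
    for row in df.itertuples(index=False):
        out[pi[row.participant], ti[row.trial], si[row.stimulus]] = row.rank
    return out
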