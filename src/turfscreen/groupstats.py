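"""Nonparametric germplasm ranking: Kruskal–Wallis, Dunn post hoc with
Benjamini–Hochberg adjustment, compact letter display, and Pearson correlation.

Replicate observations (the per-ROI values) rarely satisfy normality, so group
comparison is rank-based throughout.  Per session and metric: a tie-corrected
Kruskal–Wallis omnibus test over all germplasm, then Dunn's pairwise rank test
with BH false-discovery-rate adjustment across all k(k−1)/2 pairs (one family
per session × metric), rendered as a compact letter display — groups share a
letter exactly when their adjusted p is at or above the significance level.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, UndefinedStatisticError


@dataclass
class GroupSample:
    """One germplasm's replicate observations of a single metric."""

    group: str
    values: np.ndarray

    def __init__(self, group: str, values: Sequence[float]):
        self.group = group
        arr = np.asarray(values, dtype=float)
        arr = arr[np.isfinite(arr)]
        if arr.size < 2:
            raise ConfigError(
                f"group {group!r} needs >= 2 finite observations, has {arr.size}"
            )
        self.values = arr


@dataclass(frozen=True)
class OmnibusResult:
    statistic: float  # tie-corrected H
    df: int
    p_value: float


@dataclass
class PairwiseTable:
    """All-pairs Dunn results; one BH family per table."""

    groups: tuple[str, ...]
    table: pd.DataFrame  # columns: group1, group2, z, p_raw, p_adj

    def adjusted_p(self, g1: str, g2: str) -> float:
        t = self.table
        row = t[((t.group1 == g1) & (t.group2 == g2))
                | ((t.group1 == g2) & (t.group2 == g1))]
        if row.empty:
            raise ConfigError(f"pair ({g1}, {g2}) missing from pairwise table")
        return float(row.p_adj.iloc[0])


@dataclass
class LetterDisplay:
    letters: dict[str, str]  # group -> letter string
    alpha: float


def kruskal_wallis(groups: Sequence[GroupSample], method: str = "chi-square",
                   n_permutations: int = 999, seed: int = 0) -> OmnibusResult:
    """Tie-corrected Kruskal–Wallis H, df = k−1.

    The default p value comes from the chi-square upper tail, the standard
    reporting convention even at 4 observations per group; at such sample
    sizes the approximation is conservative, so an exact Monte Carlo
    permutation p (``method="permutation"``: group labels reshuffled on the
    pooled midranks) is available for small-sample calibration checks.  The H
    statistic is identical under both methods.
    """
    if len(groups) < 2:
        raise ConfigError("need at least 2 groups")
    samples = [g.values for g in groups]
    pooled = np.concatenate(samples)
    if pooled.size < 3:
        raise ConfigError("need total N >= 3")
    df = len(groups) - 1
    if np.ptp(pooled) == 0:
        warnings.warn("all pooled observations identical; H = 0, p = 1")
        return OmnibusResult(0.0, df, 1.0)
    h, p = stats.kruskal(*samples)
    if method == "chi-square":
        return OmnibusResult(float(h), df, float(p))
    if method != "permutation":
        raise ConfigError(f"unknown method {method!r}")

    # permutation null: reshuffle ranks over group labels; the tie pattern —
    # hence the tie correction — is invariant, so raw rank sums compare 1:1
    rng = np.random.default_rng(seed)
    ranks = stats.rankdata(pooled)
    sizes = np.array([s.size for s in samples])
    offsets = np.concatenate([[0], np.cumsum(sizes)[:-1]])

    def h_uncorrected(rank_rows: np.ndarray) -> np.ndarray:
        group_sums = np.add.reduceat(rank_rows, offsets, axis=1)
        n = pooled.size
        return (12.0 / (n * (n + 1))) * (
            (group_sums**2 / sizes).sum(axis=1)
        ) - 3.0 * (n + 1)

    h_obs = h_uncorrected(ranks[None, :])[0]
    perm = rng.permuted(np.tile(ranks, (n_permutations, 1)), axis=1)
    h_perm = h_uncorrected(perm)
    p_perm = (1.0 + (h_perm >= h_obs - 1e-12).sum()) / (n_permutations + 1.0)
    return OmnibusResult(float(h), df, float(p_perm))


def dunn_test(groups: Sequence[GroupSample]) -> PairwiseTable:
    """Dunn's rank-based multiple comparison with BH adjustment.

    For pair (i, j): z = (R̄ᵢ − R̄ⱼ) / sqrt((N(N+1)/12 − Στ/(12(N−1))) ·
    (1/nᵢ + 1/nⱼ)) with Στ = Σ(t³ − t) over tied value groups; two-sided
    normal p, BH step-up over all pairs.
    """
    if len(groups) < 2:
        raise ConfigError("need at least 2 groups")
    names = tuple(g.group for g in groups)
    if len(set(names)) != len(names):
        raise ConfigError("duplicate group ids")
    samples = [g.values for g in groups]
    pooled = np.concatenate(samples)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks = {}
    start = 0
    for g, v in zip(groups, samples):
        mean_ranks[g.group] = ranks[start:start + v.size].mean()
        start += v.size
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(counts**3 - counts))
    var_term = n_total * (n_total + 1) / 12.0 - tie_sum / (12.0 * (n_total - 1))

    rows = []
    sizes = {g.group: g.values.size for g in groups}
    for g1, g2 in itertools.combinations(names, 2):
        se = np.sqrt(var_term * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
        if se == 0:
            z = 0.0
        else:
            z = (mean_ranks[g1] - mean_ranks[g2]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group1": g1, "group2": g2, "z": z, "p_raw": min(p, 1.0)})
    table = pd.DataFrame(rows)
    table["p_adj"] = bh_adjust(table["p_raw"].to_numpy())
    return PairwiseTable(groups=names, table=table)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ConfigError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def letter_display(pairwise: PairwiseTable, alpha: float,
                   group_means: dict[str, float] | None = None) -> LetterDisplay:
    """Compact letter display by insert-and-absorb.

    Groups are ordered by descending mean (raw, untransformed values — the
    rank tables print untransformed means).  Starting from one letter covering
    every group, each significant pair splits every letter containing both
    members; letters whose group set is contained in another's are absorbed.
    Two groups share a letter iff their adjusted p ≥ alpha.
    """
    names = list(pairwise.groups)
    if group_means is not None:
        names.sort(key=lambda g: -group_means[g])
    order = {g: i for i, g in enumerate(names)}

    letters: list[set[str]] = [set(names)]
    for g1, g2 in itertools.combinations(names, 2):
        if pairwise.adjusted_p(g1, g2) >= alpha:
            continue
        new: list[set[str]] = []
        for letter in letters:
            if g1 in letter and g2 in letter:
                new.append(letter - {g1})
                new.append(letter - {g2})
            else:
                new.append(letter)
        # absorb: drop empties and duplicates, then proper subsets
        unique: list[set[str]] = []
        for letter in new:
            if letter and letter not in unique:
                unique.append(letter)
        letters = [s for s in unique if not any(s < other for other in unique)]

    letters.sort(key=lambda s: min(order[g] for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    if len(letters) > len(alphabet):
        raise UndefinedStatisticError("more letter classes than letters available")
    out = {g: "" for g in names}
    for ch, letter in zip(alphabet, letters):
        for g in letter:
            out[g] += ch
    return LetterDisplay(letters=out, alpha=alpha)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Sample Pearson correlation: (r, r², two-sided p from t with n−2 df)."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size:
        raise ConfigError("x and y must have equal length")
    if xa.size < 3:
        raise ConfigError("need at least 3 paired observations")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise UndefinedStatisticError("correlation undefined under zero variance")
    res = stats.pearsonr(xa, ya)
    r = float(res.statistic)
    return r, r * r, float(res.pvalue)


def rank_letter_table(groups: Sequence[GroupSample], alpha: float = 0.05
                      ) -> pd.DataFrame:
    """Ranked mean ± sd table with compact letters (one session × metric)."""
    means = {g.group: float(g.values.mean()) for g in groups}
    sds = {g.group: float(g.values.std(ddof=1)) for g in groups}
    pairwise = dunn_test(groups)
    display = letter_display(pairwise, alpha=alpha, group_means=means)
    rows = sorted(means, key=lambda g: -means[g])
    return pd.DataFrame(
        {
            "germplasm": rows,
            "mean": [means[g] for g in rows],
            "sd": [sds[g] for g in rows],
            "letters": [display.letters[g] for g in rows],
        }
    )
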