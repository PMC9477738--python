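"""Binding-strength stratification and differential peak occupancy.

Two analyses live here.  The first stratifies peak scores by per-peak motif
count and asks whether binding strength varies with motif content: a
Kruskal-Wallis test across groups, pairwise two-sided Wilcoxon rank-sum tests
with Benjamini-Hochberg adjustment, and a compact letter display in which
groups sharing a letter are not significantly different.

The second computes per-peak differential occupancy between two genotypes
from replicated count matrices: median-of-ratios normalization, a moderated
t-statistic on log2(normalized count + 0.5), and BH FDR across peaks with a
0.05 default threshold.  Variance moderation squeezes per-peak pooled
variances toward a common prior fitted by moments across peaks; with only a
handful of replicates per condition this borrowing of strength is what makes
per-peak testing usable.  Set ``moderate_variance=False`` for a plain Welch t.

The rank statistics are computed from first principles (ranks, tie
corrections, chi-square / normal reference distributions) so they can be
validated against independent implementations rather than delegating to one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import polygamma
from statsmodels.stats.multitest import multipletests

from .io_formats import CountMatrix, Peak

__all__ = [
    "StrataResult",
    "stratify_by_motif_count",
    "kruskal_wallis",
    "wilcoxon_rank_sum",
    "pairwise_letters",
    "normalize_counts",
    "differential_binding",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# stratification and rank tests


def stratify_by_motif_count(
    peaks: Sequence[Peak],
    counts_per_peak: Mapping[str, int],
    max_group: int = 3,
) -> dict[str, list[float]]:
    """Group peak scores by motif count, pooling counts >= max_group.

    Keys are "0", "1", ..., ">=<max_group>"; empty groups are dropped with a
    warning.  Peaks absent from ``counts_per_peak`` count as zero motifs.
    """
    groups: dict[str, list[float]] = {}
    labels = [str(k) for k in range(max_group)] + [f">={max_group}"]
    for lab in labels:
        groups[lab] = []
    for p in peaks:
        k = counts_per_peak.get(p.id, 0)
        lab = str(k) if k < max_group else f">={max_group}"
        groups[lab].append(p.score)
    empty = [lab for lab, v in groups.items() if not v]
    if empty:
        logger.warning("dropping empty motif-count groups: %s", empty)
    return {lab: v for lab, v in groups.items() if v}


def kruskal_wallis(groups: Mapping[str, Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction; p from chi-square, df = g - 1."""
    vals = [np.asarray(v, dtype=float) for v in groups.values()]
    if len(vals) < 2:
        raise ValueError("need at least 2 groups")
    pooled = np.concatenate(vals)
    n = len(pooled)
    if n < 3:
        raise ValueError("need at least 3 observations in total")
    ranks = stats.rankdata(pooled)
    h = 0.0
    i = 0
    for v in vals:
        r = ranks[i : i + len(v)]
        h += r.sum() ** 2 / len(v)
        i += len(v)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, tie_counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - (tie_counts**3 - tie_counts).sum() / (n**3 - n)
    if correction == 0:  # every value identical
        return 0.0, 1.0
    h /= correction
    p = float(stats.chi2.sf(h, df=len(vals) - 1))
    return float(h), p


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum via the normal approximation with tie
    correction (no continuity correction); returns (z, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    n = n1 + n2
    ranks = stats.rankdata(pooled)
    r1 = ranks[:n1].sum()
    mu = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / ((n) * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var == 0:
        return 0.0, 1.0
    z = (r1 - mu) / np.sqrt(var)
    p = float(2 * stats.norm.sf(abs(z)))
    return float(z), min(p, 1.0)


@dataclass
class StrataResult:
    """Stratified scores with omnibus and pairwise tests and a letter display."""

    groups: dict[str, list[float]]
    kw_H: float
    kw_p: float
    pairwise: dict[tuple[str, str], float]  # BH-adjusted Wilcoxon p per pair
    letters: dict[str, str]
    alpha: float = 0.05


def _letters_insert_absorb(
    labels: Sequence[str],
    significant: Mapping[tuple[str, str], bool],
) -> dict[str, str]:
    """Compact letter display by insert-and-absorb.

    Start from one column holding every group; for each significant pair split
    every column containing both members; absorb columns that became subsets
    of others.  By construction two groups share a letter iff no significant
    difference separates them.
    """
    columns: list[set[str]] = [set(labels)]
    for (a, b), sig in significant.items():
        if not sig:
            continue
        new_columns: list[set[str]] = []
        for col in columns:
            if a in col and b in col:
                new_columns.extend([col - {a}, col - {b}])
            else:
                new_columns.append(col)
        # absorb: drop empties, duplicates, and columns contained in another
        uniq: list[set[str]] = []
        for c in new_columns:
            if c and c not in uniq:
                uniq.append(c)
        columns = [c for c in uniq if not any(c < other for other in uniq)]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {lab: "" for lab in labels}
    for i, col in enumerate(columns):
        ch = alphabet[i % len(alphabet)] * (1 + i // len(alphabet))
        for lab in labels:
            if lab in col:
                letters[lab] += ch
    return letters


def pairwise_letters(
    groups: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
) -> StrataResult:
    """All-pairs Wilcoxon rank-sum with BH adjustment, plus letters.

    The letter invariant holds exactly: two groups share at least one letter
    iff their BH-adjusted pairwise p is >= alpha.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    for lab in labels:
        if len(groups[lab]) == 0:
            raise ValueError(f"group {lab!r} is empty")
    kw_h, kw_p = kruskal_wallis(groups)
    pairs = list(combinations(labels, 2))
    raw = [wilcoxon_rank_sum(groups[a], groups[b])[1] for a, b in pairs]
    adj = multipletests(raw, method="fdr_bh")[1] if pairs else []
    pairwise = {pair: float(p) for pair, p in zip(pairs, adj)}
    significant = {pair: p < alpha for pair, p in pairwise.items()}
    letters = _letters_insert_absorb(labels, significant)
    return StrataResult(
        groups={k: list(v) for k, v in groups.items()},
        kw_H=kw_h,
        kw_p=kw_p,
        pairwise=pairwise,
        letters=letters,
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# differential occupancy


def normalize_counts(cm: CountMatrix) -> tuple[pd.Series, pd.DataFrame]:
    """Median-of-ratios size factors and the normalized matrix.

    The reference is the per-row geometric mean over rows positive in every
    sample; a sample's size factor is the median ratio of its counts to the
    reference.  When no row is positive everywhere the size factors fall back
    to library-size ratios (with a warning).
    """
    counts = cm.counts
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    arr = counts.to_numpy(dtype=float)
    if (arr.sum(axis=0) == 0).any():
        raise ValueError("all-zero sample")
    positive = (arr > 0).all(axis=1)
    if positive.any():
        logref = np.log(arr[positive]).mean(axis=1, keepdims=True)
        ratios = np.log(arr[positive]) - logref
        sf = np.exp(np.median(ratios, axis=0))
    else:
        logger.warning(
            "no row positive in all samples; falling back to library-size factors"
        )
        lib = arr.sum(axis=0)
        sf = lib / np.exp(np.mean(np.log(lib)))
    size_factors = pd.Series(sf, index=counts.columns, name="size_factor")
    normalized = counts / sf
    return size_factors, normalized


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (standard moment-method step)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = polygamma(1, y)
        dif = tri * (1 - tri / x) / polygamma(2, y)
        y += dif
        if abs(dif) < 1e-8 * y:
            break
    return float(y)


def _squeeze_variances(s2: np.ndarray, df: float) -> tuple[float, float, np.ndarray]:
    """Empirical-Bayes squeeze of per-row variances toward a common prior.

    Fits a scaled inverse chi-square prior (d0, s0^2) to the observed sample
    variances by matching moments of log s^2, then returns posterior
    variances (d0*s0^2 + df*s2) / (d0 + df).  d0 = inf collapses every row to
    s0^2.
    """
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.mean(s2[ok])) if ok.any() else 1e-8, np.full_like(
            s2, np.mean(s2[ok]) if ok.any() else 1e-8
        )
    z = np.log(s2[ok])
    e = z - polygamma(0, df / 2) + np.log(df / 2)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(polygamma(1, df / 2))
    if e_var > 0:
        d0 = 2 * _trigamma_inverse(e_var)
        s0_2 = float(np.exp(e_mean + polygamma(0, d0 / 2) - np.log(d0 / 2)))
        post = (d0 * s0_2 + df * s2) / (d0 + df)
    else:
        d0 = np.inf
        s0_2 = float(np.exp(e_mean))
        post = np.full_like(s2, s0_2)
    return d0, s0_2, post


def differential_binding(
    cm: CountMatrix,
    condition_order: Sequence[str] | None = None,
    fdr_threshold: float = 0.05,
    moderate_variance: bool = True,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-peak differential occupancy between two conditions.

    Counts are normalized (median of ratios), log2(x + pseudocount)
    transformed, and tested per peak with a two-sided t on the difference of
    condition means; log2fc is condition2 minus condition1 on the log2 scale.
    With ``moderate_variance`` (default) the pooled within-condition variances
    are squeezed toward an empirical prior and the t reference gains the
    prior degrees of freedom; otherwise a plain Welch t is used.  P values
    are BH-adjusted across peaks and ``significant`` marks fdr <= threshold.
    """
    conditions = list(condition_order) if condition_order else cm.conditions
    if len(conditions) != 2:
        raise ValueError(f"need exactly 2 conditions, got {conditions}")
    s1 = cm.samples_of(conditions[0])
    s2 = cm.samples_of(conditions[1])
    if len(s1) < 2 or len(s2) < 2:
        raise ValueError("need at least 2 replicates per condition")
    _, norm = normalize_counts(cm)
    y = np.log2(norm.to_numpy(dtype=float) + pseudocount)
    i1 = [cm.col_ids.index(s) for s in s1]
    i2 = [cm.col_ids.index(s) for s in s2]
    y1, y2 = y[:, i1], y[:, i2]
    n1, n2 = len(i1), len(i2)
    m1, m2 = y1.mean(axis=1), y2.mean(axis=1)
    v1 = y1.var(axis=1, ddof=1)
    v2 = y2.var(axis=1, ddof=1)
    log2fc = m2 - m1

    if moderate_variance:
        df_resid = n1 + n2 - 2
        s2_pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / df_resid
        d0, _, s2_post = _squeeze_variances(s2_pooled, df_resid)
        se = np.sqrt(s2_post * (1 / n1 + 1 / n2))
        df_total = df_resid + (d0 if np.isfinite(d0) else 1e6)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, log2fc / np.where(se > 0, se, 1.0), 0.0)
        p = 2 * stats.t.sf(np.abs(t), df=df_total)
    else:
        se2 = v1 / n1 + v2 / n2
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se2 > 0, log2fc / np.sqrt(np.where(se2 > 0, se2, 1.0)), 0.0)
            df_w = np.where(
                se2 > 0,
                se2**2
                / np.maximum(
                    (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1), 1e-300
                ),
                1.0,
            )
        p = 2 * stats.t.sf(np.abs(t), df=df_w)
    p = np.clip(p, 0.0, 1.0)
    fdr = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "peak_id": cm.row_ids,
            f"mean_{conditions[0]}": norm.iloc[:, i1].mean(axis=1).to_numpy(),
            f"mean_{conditions[1]}": norm.iloc[:, i2].mean(axis=1).to_numpy(),
            "log2fc": log2fc,
            "p": p,
            "fdr": fdr,
            "significant": fdr <= fdr_threshold,
        }
    )
    return out
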