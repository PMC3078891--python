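"""Differential expression: one-way ANOVA, fold-change gates, permutation FDR.

Genes are tested with a one-way ANOVA on log2 normalized values (for two
groups F is exactly the squared pooled-variance t statistic), while the
fold change is the ratio of untransformed group means — log2FC =
log2(mean_hibernating / mean_summer).  A gene is selected when p < p_cut
and |log2FC| > fc_cut (defaults 0.01 and 0.5).

The experiment-level false discovery rate is estimated by phenotype
permutation: rerun the whole selection under every distinct relabelling of
the samples (all C(11, 5) = 462 for the 6-vs-5 design, seeded sampling
above 10,000) and divide the mean permuted selection count by the observed
count.  The reciprocal ("literal") orientation is available behind a flag.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import ExpressionMatrix

__all__ = [
    "log2_fold_change",
    "fc_from_log2",
    "oneway_anova",
    "de_table",
    "select_de",
    "de_summary",
    "permutation_fdr",
    "PermutationFdr",
]


def log2_fold_change(values_hib, values_sum) -> float:
    """log2 of the ratio of group means (hibernating over summer).

    NaNs are ignored.  Non-positive or empty group means make the fold
    change undefined (NaN) — such genes are excluded from selection.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mh = np.nanmean(np.asarray(values_hib, dtype=float))
        ms = np.nanmean(np.asarray(values_sum, dtype=float))
    if not (np.isfinite(mh) and np.isfinite(ms)) or mh <= 0 or ms <= 0:
        return float("nan")
    return float(np.log2(mh / ms))


def fc_from_log2(log2fc: float) -> float:
    """Linear fold change 2**log2fc (report 2**|log2fc|-fold down if negative)."""
    return float(2.0 ** log2fc)


def oneway_anova(values, labels) -> tuple[float, float]:
    """One-way fixed-effects ANOVA (F, p) by explicit sums of squares.

    ``labels`` assigns each observation to a group; NaN observations are
    dropped.  With two groups F equals the squared pooled-variance t.  If
    every group has zero within variance the statistic is undefined and
    (nan, nan) is returned.
    """
    v = np.asarray(values, dtype=float)
    lab = np.asarray(labels)
    keep = np.isfinite(v)
    v, lab = v[keep], lab[keep]
    groups = [v[lab == g] for g in pd.unique(lab)]
    groups = [g for g in groups if len(g) > 0]
    k, n = len(groups), len(v)
    if k < 2 or n - k < 1:
        return float("nan"), float("nan")
    grand = v.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if ssw <= 0:
        return float("nan"), float("nan")
    f = (ssb / (k - 1)) / (ssw / (n - k))
    p = float(stats.f.sf(f, k - 1, n - k))
    return float(f), p


def _matrix_stats(raw: np.ndarray, log2v: np.ndarray, mask1: np.ndarray, mask2: np.ndarray):
    """Vectorised per-row two-group ANOVA on log2 values + raw-mean log2FC.

    ``raw``/``log2v`` are genes × samples with NaN for missing entries;
    ``mask1``/``mask2`` are boolean sample selectors (hibernating, summer).
    Returns (F, p, log2fc, mean1, mean2).
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        x1, x2 = log2v[:, mask1], log2v[:, mask2]
        n1 = np.isfinite(x1).sum(axis=1)
        n2 = np.isfinite(x2).sum(axis=1)
        m1 = np.nanmean(x1, axis=1)
        m2 = np.nanmean(x2, axis=1)
        ss1 = np.nansum((x1 - m1[:, None]) ** 2, axis=1)
        ss2 = np.nansum((x2 - m2[:, None]) ** 2, axis=1)
        n = n1 + n2
        grand = (n1 * m1 + n2 * m2) / n
        ssb = n1 * (m1 - grand) ** 2 + n2 * (m2 - grand) ** 2
        ssw = ss1 + ss2
        ok = (n1 >= 2) & (n2 >= 2) & (ssw > 0)
        f = np.full(raw.shape[0], np.nan)
        p = np.full(raw.shape[0], np.nan)
        df2 = n - 2
        f[ok] = (ssb[ok] / 1.0) / (ssw[ok] / df2[ok])
        p[ok] = stats.f.sf(f[ok], 1, df2[ok])
        r1 = np.nanmean(raw[:, mask1], axis=1)
        r2 = np.nanmean(raw[:, mask2], axis=1)
        lfc = np.full(raw.shape[0], np.nan)
        pos = np.isfinite(r1) & np.isfinite(r2) & (r1 > 0) & (r2 > 0)
        lfc[pos] = np.log2(r1[pos] / r2[pos])
    return f, p, lfc, r1, r2


def _group_masks(groups: pd.Series, columns) -> tuple[np.ndarray, np.ndarray]:
    g = groups.reindex(columns)
    labels = pd.unique(g)
    if len(labels) != 2:
        raise ValueError("exactly two phenotype groups required")
    if "hibernating" in set(labels):
        first = "hibernating"
    else:
        first = labels[0]
    return (g == first).to_numpy(), (g != first).to_numpy()


def de_table(matrix: ExpressionMatrix | pd.DataFrame, groups: pd.Series | None = None) -> pd.DataFrame:
    """Per-row DE statistics: group means, log2FC, F, p.

    Accepts an :class:`ExpressionMatrix` or a plain genes × samples frame
    plus a ``groups`` Series.  ANOVA runs on log2 values, fold change on
    raw means.
    """
    if isinstance(matrix, ExpressionMatrix):
        values, groups = matrix.values, matrix.groups
    else:
        values = matrix
        if groups is None:
            raise ValueError("groups required with a plain DataFrame")
    raw = values.to_numpy(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        logv = np.where(raw > 0, np.log2(np.where(raw > 0, raw, 1.0)), np.nan)
    m1, m2 = _group_masks(groups, values.columns)
    f, p, lfc, r1, r2 = _matrix_stats(raw, logv, m1, m2)
    out = pd.DataFrame(
        {
            "mean_hibernating": r1,
            "mean_summer": r2,
            "log2fc": lfc,
            "f_statistic": f,
            "p_value": p,
        },
        index=values.index,
    )
    out.index.name = values.index.name or "probe_id"
    return out.reset_index()


def select_de(table: pd.DataFrame, p_cut: float = 0.01, fc_cut: float = 0.5) -> pd.DataFrame:
    """Flag rows passing both gates; attach direction for selected rows."""
    out = table.copy()
    out["selected"] = (out["p_value"] < p_cut) & (out["log2fc"].abs() > fc_cut)
    out["selected"] = out["selected"].fillna(False)
    out["direction"] = np.where(
        out["selected"], np.where(out["log2fc"] > 0, "up", "down"), ""
    )
    return out


def de_summary(selected: pd.DataFrame, n_background: int | None = None) -> dict:
    """Headline counts: selected, up/down splits and their percentages."""
    sel = selected[selected["selected"]]
    n_sel = int(len(sel))
    n_up = int((sel["direction"] == "up").sum())
    n_down = n_sel - n_up
    out = {
        "n_tested": int(len(selected)),
        "n_selected": n_sel,
        "n_up": n_up,
        "n_down": n_down,
        "pct_up": 100.0 * n_up / n_sel if n_sel else float("nan"),
        "pct_down": 100.0 * n_down / n_sel if n_sel else float("nan"),
    }
    if n_background:
        out["n_background"] = int(n_background)
        out["pct_selected"] = 100.0 * n_sel / n_background
    return out


@dataclass
class PermutationFdr:
    """Experiment-level FDR from phenotype permutations."""

    fdr: float
    observed_count: int
    perm_counts: np.ndarray
    exhaustive: bool

    @property
    def mean_perm_count(self) -> float:
        return float(np.mean(self.perm_counts))


def distinct_relabelings(n_total: int, n_group1: int):
    """All distinct assignments of ``n_group1`` of ``n_total`` samples to group 1."""
    return itertools.combinations(range(n_total), n_group1)


def permutation_fdr(
    matrix: ExpressionMatrix | pd.DataFrame,
    groups: pd.Series | None = None,
    p_cut: float = 0.01,
    fc_cut: float = 0.5,
    max_exhaustive: int = 10_000,
    n_sample: int = 1_000,
    seed: int | None = 0,
    literal: bool = False,
) -> PermutationFdr:
    """Experiment FDR = mean permuted selection count / observed count.

    Every distinct relabelling is enumerated when there are at most
    ``max_exhaustive`` of them (462 for 6-vs-5, so the default design is
    exhaustive and Monte-Carlo free); otherwise ``n_sample`` relabellings
    are drawn with ``seed``.  The ratio is truncated to [0, 1].  With zero
    observed selections the FDR is undefined (NaN).  ``literal=True``
    returns observed / mean(permuted) instead.
    """
    if isinstance(matrix, ExpressionMatrix):
        values, groups = matrix.values, matrix.groups
    else:
        values = matrix
        if groups is None:
            raise ValueError("groups required with a plain DataFrame")
    raw = values.to_numpy(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        logv = np.where(raw > 0, np.log2(np.where(raw > 0, raw, 1.0)), np.nan)
    m1, m2 = _group_masks(groups, values.columns)
    n_total, n_g1 = len(values.columns), int(m1.sum())

    def count_selected(mask1: np.ndarray) -> int:
        mask2 = ~mask1
        _, p, lfc, _, _ = _matrix_stats(raw, logv, mask1, mask2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            sel = (p < p_cut) & (np.abs(lfc) > fc_cut)
        return int(np.nansum(sel))

    observed = count_selected(m1)

    from math import comb

    n_distinct = comb(n_total, n_g1)
    exhaustive = n_distinct <= max_exhaustive
    counts = []
    if exhaustive:
        for combo in distinct_relabelings(n_total, n_g1):
            mask = np.zeros(n_total, dtype=bool)
            mask[list(combo)] = True
            counts.append(count_selected(mask))
    else:
        rng = np.random.default_rng(seed)
        for _ in range(n_sample):
            mask = np.zeros(n_total, dtype=bool)
            mask[rng.choice(n_total, size=n_g1, replace=False)] = True
            counts.append(count_selected(mask))
    counts = np.asarray(counts)

    if observed == 0:
        fdr = float("nan")
    elif literal:
        mean_perm = float(np.mean(counts))
        fdr = float("inf") if mean_perm == 0 else observed / mean_perm
    else:
        fdr = min(1.0, float(np.mean(counts)) / observed)
    return PermutationFdr(
        fdr=fdr, observed_count=observed, perm_counts=counts, exhaustive=exhaustive
    )
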