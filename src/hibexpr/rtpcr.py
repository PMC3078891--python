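"""Quantitative real-time PCR: standard curves, relative quantification,
group testing and array-concordance verdicts.

Each primer set's amplification efficiency E is fitted from a 4-point
10-fold dilution series (Ct regressed on log10 input; E = 10^(−1/slope);
E = 2 is perfect doubling, slope −3.32 cycles per decade).  Per-sample
relative expression follows the efficiency-corrected ratio

    ratio_s = E_target^(Ct_cal − Ct_s, target) / E_ref^(Ct_cal − Ct_s, ref)

with the calibrator Ct taken as the summer-group mean so summer samples
average ~1.  Groups are compared by Student's t-test on log2 ratios, the
reported fold change is log2(mean_hib / mean_sum) of the ratios, and a
gene's array result counts as confirmed when the RT-PCR p is below 0.05
with the same fold-change sign.  Concordance across a panel is the
confirmation rate plus the Pearson correlation of (RT-PCR, array) log2
fold changes over the confirmed genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StandardCurve",
    "fit_standard_curve",
    "relative_expression",
    "group_test",
    "analyze_panel",
    "select_reference_gene",
    "concordance",
    "ConcordanceResult",
]


@dataclass(frozen=True)
class StandardCurve:
    """Dilution-series fit: slope/intercept of Ct vs log10 input, R², E."""

    slope: float
    intercept: float
    r_squared: float
    efficiency: float


def fit_standard_curve(dilutions, cts) -> StandardCurve:
    """Least-squares Ct ~ log10(input amount); E = 10^(−1/slope).

    Requires >= 4 points over >= 2 distinct dilutions; a non-negative
    slope marks an invalid series and raises.
    """
    d = np.asarray(dilutions, dtype=float)
    c = np.asarray(cts, dtype=float)
    if len(d) != len(c) or len(d) < 4:
        raise ValueError("a standard curve needs at least 4 (dilution, Ct) points")
    if np.unique(d).size < 2:
        raise ValueError("dilution series must span at least two concentrations")
    if np.any(d <= 0):
        raise ValueError("dilution factors must be positive")
    x = np.log10(d)
    res = stats.linregress(x, c)
    if res.slope >= 0:
        raise ValueError(f"invalid dilution series: non-negative slope {res.slope:.3f}")
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        efficiency=float(10.0 ** (-1.0 / res.slope)),
    )


def relative_expression(
    ct_target: pd.Series,
    ct_reference: pd.Series,
    e_target: float,
    e_reference: float,
    calibrator_samples,
) -> pd.Series:
    """Efficiency-corrected expression ratio per sample.

    ``ct_target``/``ct_reference`` are indexed by sample; samples missing a
    reference Ct are dropped.  The calibrator Ct is each gene's mean over
    ``calibrator_samples`` (the summer group), so adding any constant to
    all Ct values of a run cancels.
    """
    common = ct_target.index.intersection(ct_reference.index)
    tgt, ref = ct_target.loc[common], ct_reference.loc[common]
    cal = [s for s in calibrator_samples if s in common]
    if not cal:
        raise ValueError("no calibrator sample has both target and reference Ct")
    cal_t = float(tgt.loc[cal].mean())
    cal_r = float(ref.loc[cal].mean())
    ratio = e_target ** (cal_t - tgt) / e_reference ** (cal_r - ref)
    return ratio.rename("relative_expression")


def group_test(rel: pd.Series, groups: pd.Series) -> tuple[float, float]:
    """(log2FC, p): Student's t on log2 ratios; FC from raw ratio means."""
    g = groups.reindex(rel.index)
    hib = rel[g == "hibernating"].to_numpy(float)
    summ = rel[g == "summer"].to_numpy(float)
    if len(hib) < 2 or len(summ) < 2:
        raise ValueError("need at least two samples per group")
    log2fc = float(np.log2(hib.mean() / summ.mean()))
    t = stats.ttest_ind(np.log2(hib), np.log2(summ), equal_var=True)
    return log2fc, float(t.pvalue)


def select_reference_gene(expression: pd.DataFrame, candidates=None) -> str:
    """Most stable gene = lowest coefficient of variation across samples."""
    sub = expression if candidates is None else expression.loc[list(candidates)]
    cv = sub.std(axis=1, ddof=1) / sub.mean(axis=1)
    return str(cv.idxmin())


def analyze_panel(
    ct_table: pd.DataFrame,
    reference_gene: str,
    groups: pd.Series | None = None,
) -> pd.DataFrame:
    """Full panel analysis from a long Ct table.

    ``ct_table`` columns: sample, group, gene, ct, dilution (dilution rows
    carry the standard series; sample rows have NaN dilution).  Returns one
    row per non-reference gene: efficiency, slope, R², log2FC, p.
    """
    std = ct_table[ct_table["dilution"].notna()]
    samp = ct_table[ct_table["dilution"].isna()]
    if groups is None:
        groups = samp.drop_duplicates("sample").set_index("sample")["group"]
    curves = {}
    for gene, sub in std.groupby("gene"):
        curves[gene] = fit_standard_curve(sub["dilution"], sub["ct"])
    if reference_gene not in curves:
        raise KeyError(f"no standard curve for reference gene {reference_gene!r}")
    ct_by_gene = {
        gene: sub.set_index("sample")["ct"] for gene, sub in samp.groupby("gene")
    }
    cal = [s for s, g in groups.items() if g == "summer"]
    rows = []
    for gene, cts in ct_by_gene.items():
        if gene == reference_gene:
            continue
        curve = curves.get(gene)
        if curve is None:
            continue
        rel = relative_expression(
            cts, ct_by_gene[reference_gene], curve.efficiency,
            curves[reference_gene].efficiency, cal,
        )
        log2fc, p = group_test(rel, groups)
        rows.append(
            {
                "gene_symbol": gene,
                "efficiency": curve.efficiency,
                "slope": curve.slope,
                "r_squared": curve.r_squared,
                "rtpcr_log2fc": log2fc,
                "rtpcr_p": p,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ConcordanceResult:
    """Panel-level agreement between RT-PCR and array fold changes."""

    n_total: int
    n_confirmed: int
    confirmation_rate: float
    pearson_r: float
    pearson_p: float


def concordance(panel: pd.DataFrame) -> tuple[pd.DataFrame, ConcordanceResult]:
    """Verdicts and summary for a panel with paired array results.

    ``panel`` needs columns ``rtpcr_p, rtpcr_log2fc, array_log2fc``.  A
    gene is confirmed when rtpcr_p < 0.05 and the two fold changes share a
    sign (rows with missing RT-PCR fold change cannot be confirmed).  The
    Pearson correlation is computed on the log2 fold-change pairs of the
    confirmed genes (NaN when fewer than 3).
    """
    out = panel.copy()
    with np.errstate(invalid="ignore"):
        same_sign = np.sign(out["rtpcr_log2fc"]) == np.sign(out["array_log2fc"])
    out["confirmed"] = (
        (out["rtpcr_p"] < 0.05) & same_sign & out["rtpcr_log2fc"].notna()
    )
    out["verdict"] = np.where(out["confirmed"], "confirmed", "not_confirmed")
    conf = out[out["confirmed"]]
    n_total, n_conf = len(out), len(conf)
    if n_conf >= 3:
        r, rp = stats.pearsonr(conf["rtpcr_log2fc"], conf["array_log2fc"])
    else:
        r, rp = float("nan"), float("nan")
    res = ConcordanceResult(
        n_total=n_total,
        n_confirmed=n_conf,
        confirmation_rate=n_conf / n_total if n_total else float("nan"),
        pearson_r=float(r),
        pearson_p=float(rp),
    )
    return out, res
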