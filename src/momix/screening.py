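"""Per-feature statistical screening.

Features are screened in four steps: Shapiro-Wilk normality assessment per
class (motivating nonparametric testing), two-sided Wilcoxon signed-rank
tests on the within-patient paired subset and Mann-Whitney U tests on the
pooled unpaired sets, Benjamini-Hochberg adjustment at FDR level q within
each modality, and an iterative correlation-redundancy reduction that keeps,
of any pair with |Pearson r| above threshold, the feature with the smaller
preliminary paired p-value.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import ParameterError, feature_modality

logger = logging.getLogger("momix")

__all__ = [
    "ScreeningResult",
    "normality_fraction",
    "paired_unpaired_tests",
    "bh_adjust",
    "correlation_reduce",
    "screen_features",
]

_EXACT_MAX_N = 12


@dataclass
class ScreeningResult:
    """Per-feature screening report."""

    report: pd.DataFrame  # feature, modality, p_paired, p_unpaired, adjusted ps, flags
    retained: list = field(default_factory=list)
    removal_log: list = field(default_factory=list)  # (removed, kept, r, p_rm, p_keep)
    normal_fraction: float = float("nan")


def normality_fraction(table: pd.DataFrame, labels, classes=("normal", "cancer")):
    """Shapiro-Wilk normality flags per (feature, class) and overall fraction.

    A feature is flagged normal in a class when the Shapiro-Wilk p-value
    exceeds 0.05.  The overall fraction is the share of features flagged
    normal in *both* classes (among features where both flags are defined;
    constant or too-small groups leave the flag undefined).
    """
    labels = pd.Series(labels).reindex(table.index)
    flags = pd.DataFrame(index=table.columns, columns=list(classes), dtype=object)
    for cls in classes:
        block = table.loc[labels == cls]
        for feat in table.columns:
            vals = block[feat].dropna().to_numpy()
            if vals.size < 3 or np.ptp(vals) == 0:
                flags.loc[feat, cls] = None
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p = stats.shapiro(vals).pvalue
            flags.loc[feat, cls] = bool(p > 0.05)
    defined = flags.notna().all(axis=1)
    if defined.any():
        both = flags.loc[defined].all(axis=1)
        fraction = float(both.mean())
    else:
        fraction = float("nan")
    return flags, fraction


def _wilcoxon_paired(diffs: np.ndarray) -> float:
    diffs = diffs[np.isfinite(diffs)]
    if diffs.size < 2:
        return float("nan")
    if np.all(diffs == 0):
        warnings.warn("all paired differences zero; p = 1", stacklevel=3)
        return 1.0
    nz = diffs[diffs != 0]
    ties = np.unique(np.abs(nz)).size < nz.size
    method = "exact" if (nz.size <= 25 and not ties and (diffs != 0).all()) else "approx"
    res = stats.wilcoxon(diffs, alternative="two-sided", method=method, zero_method="wilcox")
    return float(res.pvalue)


def _mannwhitney(x: np.ndarray, y: np.ndarray) -> float:
    x, y = x[np.isfinite(x)], y[np.isfinite(y)]
    if x.size < 2 or y.size < 2:
        return float("nan")
    pooled = np.concatenate([x, y])
    ties = np.unique(pooled).size < pooled.size
    exact = not ties and min(x.size, y.size) <= _EXACT_MAX_N
    res = stats.mannwhitneyu(
        x,
        y,
        alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return float(res.pvalue)


def paired_unpaired_tests(
    table: pd.DataFrame, labels, patients, classes=("normal", "cancer")
) -> pd.DataFrame:
    """Two-sided nonparametric tests per feature for both study designs.

    Paired: Wilcoxon signed-rank on within-patient differences, restricted to
    patients contributing both classes (class means within patient when a
    patient has several specimens of one class).  Unpaired: Mann-Whitney U on
    the pooled class values.  Exact null distributions are used for small
    tie-free samples, the tie/continuity-corrected normal approximation
    otherwise.  Returns a DataFrame with columns ``p_paired``, ``p_unpaired``
    and ``n_pairs``.
    """
    labels = pd.Series(labels).reindex(table.index)
    patients = pd.Series(patients).reindex(table.index)
    a, b = classes
    rows = {}
    mask_a, mask_b = labels == a, labels == b
    paired_patients = sorted(
        set(patients[mask_a].dropna()) & set(patients[mask_b].dropna())
    )
    for feat in table.columns:
        col = table[feat]
        diffs = []
        for pat in paired_patients:
            va = col[mask_a & (patients == pat)].dropna()
            vb = col[mask_b & (patients == pat)].dropna()
            if len(va) and len(vb):
                diffs.append(va.mean() - vb.mean())
        diffs = np.asarray(diffs, dtype=float)
        p_paired = _wilcoxon_paired(diffs) if diffs.size >= 2 else float("nan")
        p_unpaired = _mannwhitney(
            col[mask_a].to_numpy(dtype=float), col[mask_b].to_numpy(dtype=float)
        )
        rows[feat] = {"p_paired": p_paired, "p_unpaired": p_unpaired, "n_pairs": diffs.size}
    return pd.DataFrame.from_dict(rows, orient="index")


def bh_adjust(p_values, q: float = 0.1):
    """Benjamini-Hochberg step-up adjustment and significance calls at q.

    Returns ``(adjusted, significant)`` arrays aligned with the input; NaN
    p-values pass through as NaN/False.
    """
    p = np.asarray(p_values, dtype=float)
    finite = np.isfinite(p)
    if finite.any() and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ParameterError("p-values must lie in [0, 1]")
    adjusted = np.full(p.shape, np.nan)
    significant = np.zeros(p.shape, dtype=bool)
    if finite.any():
        reject, p_adj, *_ = multipletests(p[finite], alpha=q, method="fdr_bh")
        adjusted[finite] = p_adj
        significant[finite] = p_adj <= q
    return adjusted, significant


def correlation_reduce(
    table: pd.DataFrame, ranking_p, threshold: float = 0.85, min_obs: int = 3
):
    """Iterative redundancy reduction by pairwise Pearson correlation.

    While any remaining pair of features has |r| > threshold (computed on
    pairwise-complete specimens), the pair with the largest |r| is processed
    (ties broken lexicographically) and its member with the larger ranking
    p-value removed; equal p retains the earlier column.  Features with fewer
    than ``min_obs`` complete observations are excluded from correlation and
    retained by default.  Returns ``(retained_names, removal_log)`` where the
    log rows are (removed, kept, r, p_removed, p_kept).
    """
    ranking_p = pd.Series(ranking_p).reindex(table.columns)
    counts = table.notna().sum(axis=0)
    excluded = list(table.columns[counts < min_obs])
    if excluded:
        logger.info(
            "%d feature(s) with < %d observations excluded from correlation "
            "and retained by default",
            len(excluded),
            min_obs,
        )
    candidates = [f for f in table.columns if f not in excluded]
    corr = table[candidates].corr(method="pearson", min_periods=min_obs).abs()
    np.fill_diagonal(corr.values, 0.0)
    corr = corr.fillna(0.0)

    alive = list(candidates)
    removal_log = []
    while True:
        sub = corr.loc[alive, alive]
        max_r = sub.to_numpy().max(initial=0.0)
        if max_r <= threshold:
            break
        pairs = []
        arr = sub.to_numpy()
        hits = np.argwhere(arr >= max_r - 1e-15)
        for i, j in hits:
            if i < j:
                pairs.append((alive[i], alive[j]))
        f1, f2 = min(pairs)  # lexicographic tie-break on the pair
        p1 = ranking_p.get(f1, np.nan)
        p2 = ranking_p.get(f2, np.nan)
        # larger p removed; NaN ranks worst; equal p keeps the earlier column
        if np.isnan(p1) and not np.isnan(p2):
            removed, kept = f1, f2
        elif np.isnan(p2) and not np.isnan(p1):
            removed, kept = f2, f1
        elif (p1 if not np.isnan(p1) else 1.0) > (p2 if not np.isnan(p2) else 1.0):
            removed, kept = f1, f2
        else:
            removed, kept = f2, f1
        removal_log.append(
            (removed, kept, float(sub.loc[f1, f2]), float(ranking_p.get(removed, np.nan)),
             float(ranking_p.get(kept, np.nan)))
        )
        alive.remove(removed)

    retained = [f for f in table.columns if f in set(alive) | set(excluded)]
    final = table[[f for f in retained if f not in excluded]].corr(min_periods=min_obs).abs()
    np.fill_diagonal(final.values, 0.0)
    assert np.nanmax(final.to_numpy(), initial=0.0) <= threshold + 1e-12
    return retained, removal_log


def screen_features(
    table: pd.DataFrame,
    labels,
    patients,
    classes=("normal", "cancer"),
    threshold: float = 0.85,
    q: float = 0.1,
) -> ScreeningResult:
    """Full screening pass, run per modality.

    The preliminary paired Wilcoxon p ranks features for the correlation
    reduction (falling back to the unpaired p where no paired coverage
    exists); BH adjustment is then applied to the retained features'
    paired and unpaired p-value families separately within each modality.
    """
    tests = paired_unpaired_tests(table, labels, patients, classes)
    ranking = tests["p_paired"].copy()
    fallback = ranking.isna() & tests["p_unpaired"].notna()
    if fallback.any():
        logger.info(
            "%d feature(s) lack paired coverage; ranking falls back to unpaired p",
            int(fallback.sum()),
        )
        ranking[fallback] = tests["p_unpaired"][fallback]

    _, normal_frac = normality_fraction(table, labels, classes)

    modality = pd.Series({f: feature_modality(f) for f in table.columns})
    retained_all: list[str] = []
    removal_all: list[tuple] = []
    for mod in sorted(modality.unique()):
        cols = list(modality.index[modality == mod])
        kept, log = correlation_reduce(table[cols], ranking[cols], threshold)
        retained_all.extend(kept)
        removal_all.extend(log)

    report = tests.copy()
    report["modality"] = modality
    report["retained"] = report.index.isin(retained_all)
    removal_cause = {rm: kept for rm, kept, *_ in removal_all}
    report["removal_cause"] = [
        f"correlated_with:{removal_cause[f]}" if f in removal_cause else "none"
        for f in report.index
    ]
    report["p_paired_adj"] = np.nan
    report["p_unpaired_adj"] = np.nan
    report["significant_paired"] = False
    report["significant_unpaired"] = False
    for mod in sorted(modality.unique()):
        sel = report.index[(report["modality"] == mod) & report["retained"]]
        for design in ("paired", "unpaired"):
            adj, sig = bh_adjust(report.loc[sel, f"p_{design}"], q)
            report.loc[sel, f"p_{design}_adj"] = adj
            report.loc[sel, f"significant_{design}"] = sig
    return ScreeningResult(
        report=report,
        retained=retained_all,
        removal_log=removal_all,
        normal_fraction=normal_frac,
    )
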