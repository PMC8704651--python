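"""Group statistics over electrode metric tables.

The analysis chain that localizes class-discriminative ("key") electrodes:

1. a MANOVA per (metric, band) with the electrodes' metric values as joint
   dependent variables and the four motor-imagery classes as factor
   (Pillai's trace, robust to covariance heterogeneity);
2. for metrics with a significant MANOVA, a per-electrode one-way ANOVA and,
   at significant electrodes, all pairwise class comparisons with the
   Games-Howell test (Welch standard errors and degrees of freedom,
   p-values from the studentized-range distribution) - robust to unequal
   variances across classes;
3. pooled one-way ANOVAs (all electrodes concatenated per class) and paired
   t-tests across class pairs with Benjamini-Hochberg FDR control for the
   multilayer distribution comparisons;
4. the key-electrode rule: an electrode is a key electrode when its post
   hoc chain is significant for at least two different metrics.

Metric tables are long-format pandas DataFrames with the columns
``recording_id, class_label, band, electrode, metric, value`` (one row per
electrode per network); build them with :func:`metrics_to_table`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.linalg import qr as _scipy_qr
from statsmodels.multivariate.manova import MANOVA
from statsmodels.stats.multitest import multipletests


def scipy_qr_pivot(a: np.ndarray):
    """Column-pivoted QR (thin) used to pick independent response columns."""
    return _scipy_qr(a, mode="economic", pivoting=True)

__all__ = [
    "StatReport",
    "metrics_to_table",
    "pooled_anova",
    "manova_electrodes",
    "electrode_posthoc",
    "games_howell",
    "paired_t_fdr",
    "bh_adjust",
    "key_electrodes",
]

TABLE_COLUMNS = ("recording_id", "class_label", "band", "electrode", "metric", "value")


@dataclass
class StatReport:
    """One test result of the statistics chain."""

    test: str  # anova | manova | games_howell | paired_t
    scope: dict  # metric, band, electrode (or "pooled")
    statistic: float
    df: tuple
    p: float
    significant: bool
    alpha: float = 0.05
    p_adjusted: float | None = None
    comparison: tuple | None = None  # (class A, class B) for pairwise tests
    note: str = ""


def metrics_to_table(metrics: Iterable) -> pd.DataFrame:
    """Stack NodeMetrics objects into a long-format metric table."""
    rows = []
    for m in metrics:
        labels = m.channel_labels or tuple(f"ch{i}" for i in range(len(m.values)))
        for name, val in zip(labels, m.values):
            rows.append(
                {
                    "recording_id": m.recording_id,
                    "class_label": m.class_label,
                    "band": m.band,
                    "electrode": name,
                    "metric": m.metric,
                    "value": float(val),
                }
            )
    return pd.DataFrame(rows, columns=list(TABLE_COLUMNS))


def _select(table: pd.DataFrame, metric: str, band: str | None) -> pd.DataFrame:
    sub = table[table["metric"] == metric]
    if band is not None:
        sub = sub[sub["band"] == band]
    if sub.empty:
        raise ValueError(f"no rows for metric={metric!r}, band={band!r}")
    return sub


def _class_groups(sub: pd.DataFrame) -> tuple[list[int], list[np.ndarray]]:
    classes = sorted(sub["class_label"].unique())
    groups = [sub.loc[sub["class_label"] == c, "value"].to_numpy() for c in classes]
    return classes, groups


def pooled_anova(
    table: pd.DataFrame, metric: str, band: str | None = None, alpha: float = 0.05
) -> StatReport:
    """One-way ANOVA across classes, pooling all electrodes and recordings."""
    sub = _select(table, metric, band)
    classes, groups = _class_groups(sub)
    if len(classes) < 2:
        raise ValueError("pooled ANOVA needs at least 2 classes")
    for c, g in zip(classes, groups):
        if g.size < 2:
            raise ValueError(f"class {c} has fewer than 2 observations")
    grand = np.concatenate(groups)
    ss_between = sum(g.size * (g.mean() - grand.mean()) ** 2 for g in groups)
    ss_total = float(((grand - grand.mean()) ** 2).sum())
    if ss_between <= 1e-12 * max(ss_total, 1e-300):
        # identical class distributions: F = 0, p = 1 (even when the residual
        # variance is also zero, where scipy would return NaN)
        f, p = 0.0, 1.0
    else:
        f, p = sps.f_oneway(*groups)
    df = (len(classes) - 1, grand.size - len(classes))
    return StatReport(
        test="anova",
        scope={"metric": metric, "band": band, "electrode": "pooled"},
        statistic=float(f),
        df=df,
        p=float(p),
        significant=bool(p < alpha),
        alpha=alpha,
    )


def _wide(sub: pd.DataFrame) -> pd.DataFrame:
    """Samples x electrodes matrix, one row per (recording, class)."""
    wide = sub.pivot_table(
        index=["recording_id", "class_label"],
        columns="electrode",
        values="value",
        sort=False,
    )
    if wide.isna().any().any():
        missing = wide.columns[wide.isna().any()].tolist()
        raise ValueError(f"missing electrode observations for {missing}")
    return wide


def shapiro_screen(sub: pd.DataFrame, alpha: float = 0.05) -> float:
    """Fraction of (electrode, class) groups rejecting Shapiro-Wilk normality.

    Degenerate (constant) groups count as rejections: they violate the
    normal-covariance assumption outright.
    """
    reject = 0
    total = 0
    for (_, _), grp in sub.groupby(["electrode", "class_label"]):
        v = grp["value"].to_numpy()
        if v.size < 3:
            continue
        total += 1
        if np.ptp(v) == 0:
            reject += 1
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if sps.shapiro(v).pvalue < alpha:
                reject += 1
    return reject / total if total else 0.0


def manova_electrodes(
    table: pd.DataFrame,
    metric: str,
    band: str | None = None,
    alpha: float = 0.05,
    screen_normality: bool = True,
) -> StatReport:
    """MANOVA with the electrodes as dependent variables and class as factor.

    Reports Pillai's trace with its F approximation.  When
    ``screen_normality`` is set, a Shapiro-Wilk screen over the (electrode,
    class) groups is run first and the rejection fraction is recorded in the
    report's note; metrics taking few integer values (degree, k-core on
    binarized networks) reject routinely at n = 18 per group, so the screen
    is advisory - Pillai's trace is robust to moderate non-normality - and a
    metric is only excluded when its statistic is genuinely incomputable
    (singular within-class covariance, the fate of near-constant metrics
    such as the k-core in practice).

    Raises
    ------
    ValueError
        If the pooled within-class covariance is singular (e.g. an electrode
        with zero variance in every class), where the statistic is undefined.
    """
    sub = _select(table, metric, band)
    scope = {"metric": metric, "band": band, "electrode": "all"}
    note = ""
    if screen_normality:
        frac = shapiro_screen(sub, alpha=alpha)
        if frac > 0.5:
            note = (
                f"normality assumption questionable "
                f"({frac:.0%} of groups reject Shapiro-Wilk)"
            )
    wide = _wide(sub)
    classes = wide.index.get_level_values("class_label").to_numpy()
    y = wide.to_numpy(dtype=float)
    n, p_full = y.shape
    uniq = np.unique(classes)
    resid = y - np.vstack([y[classes == c].mean(axis=0) for c in classes])
    # electrodes with no within-class variance at all cannot enter the
    # covariance; a metric that is mostly constant (the k-core fate) is
    # reported as incomputable rather than silently reduced
    degenerate = np.flatnonzero(resid.std(axis=0) == 0)
    if degenerate.size > p_full / 2:
        raise ValueError(
            "singular within-class covariance: most electrodes have no "
            "within-class variance; MANOVA is undefined for this metric"
        )
    keep = [i for i in range(p_full) if i not in set(degenerate)]
    if degenerate.size:
        dropped = [str(wide.columns[i]) for i in degenerate]
        note = (note + "; " if note else "") + (
            f"dropped constant electrode(s) {dropped}"
        )
    # exact linear dependencies among the remaining responses (e.g. a
    # metric normalized across electrodes, which sums to a constant) also
    # make the covariance singular; reduce to a maximal independent subset
    r_keep = resid[:, keep]
    rank = np.linalg.matrix_rank(r_keep)
    if rank < len(keep):
        _, _, piv = scipy_qr_pivot(r_keep)
        keep = sorted(np.asarray(keep)[piv[:rank]])
        note = (note + "; " if note else "") + (
            f"exact linear dependency among electrodes; reduced to "
            f"{rank} independent responses"
        )
    if rank == 0:
        raise ValueError(
            "singular within-class covariance (no within-class variance); "
            "MANOVA is undefined for this metric"
        )
    y = y[:, keep]
    p_dim = y.shape[1]
    if n - len(uniq) <= p_dim:
        raise ValueError(
            f"error degrees of freedom ({n - len(uniq)}) must exceed the number "
            f"of electrodes ({p_dim})"
        )
    data = pd.DataFrame(y, columns=[f"e{i}" for i in range(p_dim)])
    data["klass"] = classes.astype(str)
    formula = " + ".join(data.columns[:-1]) + " ~ C(klass)"
    try:
        res = MANOVA.from_formula(formula, data=data).mv_test()
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded above
        raise ValueError("singular within-class covariance") from exc
    tab = res.results["C(klass)"]["stat"]
    row = tab.loc["Pillai's trace"]
    p_val = float(row["Pr > F"])
    return StatReport(
        test="manova",
        scope=scope,
        statistic=float(row["Value"]),
        df=(float(row["Num DF"]), float(row["Den DF"])),
        p=p_val,
        significant=bool(p_val < alpha),
        alpha=alpha,
        note=note,
    )


def games_howell(
    groups: Sequence[np.ndarray],
    classes: Sequence[int] | None = None,
    on_degenerate: str = "raise",
) -> list[tuple[tuple[int, int], float, float, float, str]]:
    """Games-Howell pairwise comparisons between all groups.

    For groups a, b:  t = |m_a - m_b| / sqrt(s_a^2/n_a + s_b^2/n_b), with
    Welch-Satterthwaite degrees of freedom; the p-value evaluates the
    studentized-range distribution with k = number of groups at t * sqrt(2).

    When both groups of a pair have zero variance the statistic is
    undefined; with ``on_degenerate="raise"`` (default) a ValueError is
    raised, with ``"resolve"`` the pair is reported in the t -> limit sense
    (identical constant groups: p = 1; disjoint constant groups: p = 0) with
    an explanatory note.

    Returns a list of ((class_a, class_b), t, df, p, note).
    """
    k = len(groups)
    if classes is None:
        classes = list(range(1, k + 1))
    means = [np.mean(g) for g in groups]
    var_n = [np.var(g, ddof=1) / len(g) for g in groups]
    out = []
    for a, b in combinations(range(k), 2):
        se2 = var_n[a] + var_n[b]
        if se2 == 0:
            if on_degenerate == "raise":
                raise ValueError(
                    f"zero within-group variance in both groups {classes[a]} and "
                    f"{classes[b]}; the Games-Howell statistic is undefined"
                )
            if means[a] == means[b]:
                out.append(((classes[a], classes[b]), 0.0, float("nan"), 1.0,
                            "identical constant groups"))
            else:
                out.append(((classes[a], classes[b]), float("inf"), float("nan"),
                            0.0, "disjoint constant groups (zero variance)"))
            continue
        t = abs(means[a] - means[b]) / np.sqrt(se2)
        df = se2**2 / (
            var_n[a] ** 2 / (len(groups[a]) - 1) + var_n[b] ** 2 / (len(groups[b]) - 1)
        )
        p = float(sps.studentized_range.sf(t * np.sqrt(2.0), k, df))
        out.append(((classes[a], classes[b]), float(t), float(df), min(p, 1.0), ""))
    return out


def electrode_posthoc(
    table: pd.DataFrame,
    metric: str,
    band: str | None = None,
    alpha: float = 0.05,
    require_manova: bool = True,
    screen_normality: bool = True,
) -> list[StatReport]:
    """Per-electrode ANOVA + Games-Howell post hoc chain for one metric.

    A per-electrode one-way ANOVA across classes is run for every electrode;
    at electrodes significant at ``alpha``, all pairwise class comparisons
    are tested with Games-Howell.  When ``require_manova`` is set the chain
    only runs after a significant MANOVA over the joint electrode response
    (otherwise an empty list is returned); degenerate electrodes (constant
    values within every class) are skipped with a note.
    """
    if require_manova:
        try:
            gate = manova_electrodes(
                table, metric, band, alpha=alpha, screen_normality=screen_normality
            )
        except ValueError as exc:
            return [
                StatReport(
                    test="manova",
                    scope={"metric": metric, "band": band, "electrode": "all"},
                    statistic=float("nan"),
                    df=(),
                    p=float("nan"),
                    significant=False,
                    alpha=alpha,
                    note=str(exc),
                )
            ]
        if not gate.significant:
            return [gate]
        reports = [gate]
    else:
        reports = []
    sub = _select(table, metric, band)
    for electrode, grp in sub.groupby("electrode", sort=False):
        classes, groups = _class_groups(grp)
        scope = {"metric": metric, "band": band, "electrode": electrode}
        if all(np.ptp(g) == 0 for g in groups) and np.ptp(np.concatenate(groups)) == 0:
            reports.append(
                StatReport(
                    test="anova", scope=scope, statistic=0.0, df=(), p=1.0,
                    significant=False, alpha=alpha, note="constant metric",
                )
            )
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f, p = sps.f_oneway(*groups)
        if not np.isfinite(p):
            p = 0.0 if np.isinf(f) else 1.0
        anova_rep = StatReport(
            test="anova",
            scope=scope,
            statistic=float(f),
            df=(len(classes) - 1, sum(len(g) for g in groups) - len(classes)),
            p=float(p),
            significant=bool(p < alpha),
            alpha=alpha,
        )
        reports.append(anova_rep)
        if not anova_rep.significant:
            continue
        for (ca, cb), t, df, p_gh, note in games_howell(
            groups, classes, on_degenerate="resolve"
        ):
            reports.append(
                StatReport(
                    test="games_howell",
                    scope=scope,
                    statistic=t,
                    df=(df,),
                    p=p_gh,
                    significant=bool(p_gh < alpha),
                    alpha=alpha,
                    comparison=(ca, cb),
                    note=note,
                )
            )
    return reports


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]


def paired_t_fdr(
    table: pd.DataFrame,
    metric: str,
    band: str | None = None,
    alpha: float = 0.05,
) -> list[StatReport]:
    """Pairwise class comparisons by paired t-test with BH FDR correction.

    Observations are paired across classes by (recording, electrode).  Pairs
    with zero-variance differences are reported with p = 1 and a warning (the
    t statistic is undefined there).
    """
    sub = _select(table, metric, band)
    wide = sub.pivot_table(
        index=["recording_id", "electrode"], columns="class_label", values="value"
    )
    if wide.isna().any().any():
        missing = [
            (idx, int(col))
            for col in wide.columns
            for idx in wide.index[wide[col].isna()]
        ]
        raise ValueError(f"unpairable observations (missing class values): {missing[:10]}")
    classes = sorted(int(c) for c in wide.columns)
    raw = []
    meta = []
    for a, b in combinations(classes, 2):
        d = wide[a].to_numpy() - wide[b].to_numpy()
        if np.ptp(d) == 0:
            warnings.warn(
                f"paired t-test {a} vs {b}: zero-variance differences, "
                "t undefined; reporting p = 1"
            )
            t, p = 0.0, 1.0
        else:
            t, p = sps.ttest_rel(wide[a], wide[b])
        raw.append(float(p))
        meta.append(((a, b), float(t), d.size - 1))
    adj = bh_adjust(raw)
    reports = []
    for ((a, b), t, df), p, q in zip(meta, raw, adj):
        reports.append(
            StatReport(
                test="paired_t",
                scope={"metric": metric, "band": band, "electrode": "pooled"},
                statistic=t,
                df=(df,),
                p=p,
                p_adjusted=float(q),
                significant=bool(q < alpha),
                alpha=alpha,
                comparison=(a, b),
            )
        )
    return reports


def key_electrodes(
    reports: Iterable[StatReport], min_metrics: int = 2
) -> list[str]:
    """Electrodes whose post hoc chain is significant in >= ``min_metrics`` metrics.

    ``reports`` is a flat iterable of StatReports from one or more
    :func:`electrode_posthoc` chains; an electrode counts as significant for
    a metric when it has at least one significant Games-Howell comparison.
    """
    hits: dict[str, set[str]] = {}
    for r in reports:
        if r.test != "games_howell" or not r.significant:
            continue
        electrode = r.scope.get("electrode")
        metric = r.scope.get("metric")
        if electrode in (None, "all", "pooled"):
            continue
        hits.setdefault(electrode, set()).add(metric)
    return sorted(e for e, ms in hits.items() if len(ms) >= min_metrics)
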