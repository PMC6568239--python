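"""Descriptive and pre/post-treatment statistics for motility parameters.

The before/after contrast used to assess a treatment (e.g. CCK-8S) works on
paired per-replicate metrics: ratios of after to before are log2-transformed
and compared to 0 with a one-sample t-test, reporting a 90% confidence
interval and the two-tier significance convention ('*' for 0.05 <= p < 0.1,
'**' for p < 0.05). Continuous contraction parameters, which are heavily
right-skewed, are categorized into low/medium/high by the first and third
quartiles. Cross-type comparisons use Kruskal-Wallis with Dunn's post hoc
test; cross-segment frequency comparisons use one-way ANOVA with Tukey HSD
and compact letter display.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats as sps

from .io_masks import LengthTrace

__all__ = [
    "CategoryBreakdown",
    "PrePostResult",
    "quartile_categories",
    "pre_post_log2",
    "one_sample_t",
    "significance_tier",
    "compare_types",
    "dunn_test",
    "compare_segments",
    "length_reduction",
]

CATEGORY_LABELS = ("low", "medium", "high")


@dataclass(eq=False)
class CategoryBreakdown:
    """Low/medium/high quartile categorization of one parameter.

    ``categories`` holds the per-value labels; ``proportions`` their shares
    (summing to 1). ``degenerate`` flags an all-equal sample where the
    quartiles coincide and every value is simultaneously <= Q1 and >= Q3.
    """

    parameter: str
    q1: float
    q3: float
    categories: np.ndarray
    proportions: dict
    degenerate: bool = False


@dataclass(eq=False)
class PrePostResult:
    """One-sample t-test of log2(after/before) ratios against 0."""

    metric: str
    ratios: np.ndarray
    n: int
    n_excluded: int
    mean: float | None
    t: float | None
    df: int | None
    p: float | None
    ci90: tuple[float, float] | None
    tier: str
    zero_variance: bool = False


def quartile_categories(values, parameter: str = "") -> CategoryBreakdown:
    """Categorize values as low (<= Q1), high (>= Q3) or medium (between).

    Quartiles use linear interpolation between order statistics (plotting
    position (k-1)/(n-1)); the convention matters near cutoffs and is
    recorded in the result. Requires >= 4 finite values.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 4:
        raise ValueError(f"quartile categorization needs >= 4 finite values, got {v.size}")
    q1, q3 = np.quantile(v, [0.25, 0.75])  # linear interpolation (default)
    degenerate = q1 == q3
    if degenerate:
        warnings.warn("all quartiles equal: low/high categories degenerate")
    cats = np.where(v <= q1, "low", np.where(v >= q3, "high", "medium"))
    props = {lab: float((cats == lab).mean()) for lab in CATEGORY_LABELS}
    return CategoryBreakdown(
        parameter=parameter,
        q1=float(q1),
        q3=float(q3),
        categories=cats,
        proportions=props,
        degenerate=degenerate,
    )


def pre_post_log2(before, after) -> tuple[np.ndarray, int]:
    """Per-replicate log2(after/before) ratios.

    Pairs where either side is 0 or missing are excluded (never zero-filled);
    the count of exclusions is returned alongside. Negative inputs are an
    error: motility parameters are nonnegative.
    """
    b = np.asarray(before, dtype=float)
    a = np.asarray(after, dtype=float)
    if b.shape != a.shape:
        raise ValueError("before and after must have the same length")
    if np.nanmin(b, initial=0) < 0 or np.nanmin(a, initial=0) < 0:
        raise ValueError("negative values are not valid motility parameters")
    valid = np.isfinite(b) & np.isfinite(a) & (b > 0) & (a > 0)
    ratios = np.log2(a[valid] / b[valid])
    return ratios, int(valid.size - valid.sum())


def significance_tier(p: float | None) -> str:
    """Two-tier convention: '**' for p < 0.05, '*' for 0.05 <= p < 0.1."""
    if p is None or not np.isfinite(p) or p >= 0.1:
        return ""
    return "**" if p < 0.05 else "*"


def one_sample_t(
    ratios,
    mu: float = 0.0,
    metric: str = "",
    n_excluded: int = 0,
    conf: float = 0.90,
) -> PrePostResult:
    """One-sample t-test of the ratios against ``mu`` with a 90% CI.

    A sample with zero variance (or fewer than 2 values) yields a flagged
    undefined result rather than a fabricated p-value.
    """
    r = np.asarray(ratios, dtype=float)
    r = r[np.isfinite(r)]
    n = int(r.size)
    if n < 2 or np.ptp(r) == 0:
        return PrePostResult(
            metric=metric,
            ratios=r,
            n=n,
            n_excluded=n_excluded,
            mean=float(r.mean()) if n else None,
            t=None,
            df=n - 1 if n else None,
            p=None,
            ci90=None,
            tier="",
            zero_variance=n >= 2,
        )
    res = sps.ttest_1samp(r, popmean=mu)
    ci = res.confidence_interval(confidence_level=conf)
    p = float(res.pvalue)
    return PrePostResult(
        metric=metric,
        ratios=r,
        n=n,
        n_excluded=n_excluded,
        mean=float(r.mean()),
        t=float(res.statistic),
        df=n - 1,
        p=p,
        ci90=(float(ci.low), float(ci.high)),
        tier=significance_tier(p),
    )


def pre_post_report(table, conf: float = 0.90):
    """Tidy one-sample-t report over a before/after metric table.

    ``table`` is a DataFrame with columns ``metric``, ``before`` and
    ``after``; rows are replicates (e.g. one fish each). Ratios are
    log2(after/before) per replicate; each metric gets a one-sample t-test
    against 0 with the two-tier significance convention.
    """
    import pandas as pd

    rows = []
    for metric, grp in table.groupby("metric", sort=False):
        ratios, n_excl = pre_post_log2(grp["before"].to_numpy(), grp["after"].to_numpy())
        res = one_sample_t(ratios, metric=str(metric), n_excluded=n_excl, conf=conf)
        rows.append(
            {
                "metric": metric,
                "n": res.n,
                "n_excluded": res.n_excluded,
                "mean_log2_ratio": res.mean,
                "t": res.t,
                "df": res.df,
                "p": res.p,
                "ci_low": res.ci90[0] if res.ci90 else None,
                "ci_high": res.ci90[1] if res.ci90 else None,
                "tier": res.tier,
                "zero_variance": res.zero_variance,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cross-type: Kruskal-Wallis + Dunn


def dunn_test(groups: dict, adjust: str = "holm"):
    """Dunn's pairwise z-tests on pooled ranks with tie correction.

    ``groups`` maps group name to 1-D values. Two-sided p-values are
    adjusted with ``adjust`` ('holm' by default, or 'bonferroni'/'none').
    Returns a list of dicts with z, raw and adjusted p per pair.
    """
    if adjust not in ("holm", "bonferroni", "none"):
        raise ValueError("adjust must be 'holm', 'bonferroni' or 'none'")
    names = list(groups)
    data = [np.asarray(groups[k], dtype=float) for k in names]
    pooled = np.concatenate(data)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes = {}, {}
    i = 0
    for name, d in zip(names, data):
        mean_ranks[name] = ranks[i : i + d.size].mean()
        sizes[name] = d.size
        i += d.size

    # tie correction term
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term

    rows = []
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            na, nb = names[a], names[b]
            se = math.sqrt(base_var * (1.0 / sizes[na] + 1.0 / sizes[nb]))
            z = (mean_ranks[na] - mean_ranks[nb]) / se
            p = 2.0 * sps.norm.sf(abs(z))
            rows.append({"group_a": na, "group_b": nb, "z": z, "p": p})

    if adjust == "none":
        for r in rows:
            r["p_adj"] = r["p"]
    else:
        from statsmodels.stats.multitest import multipletests

        _, p_adj, _, _ = multipletests([r["p"] for r in rows], method=adjust)
        for r, pa in zip(rows, p_adj):
            r["p_adj"] = float(pa)
    return rows


def compare_types(groups: dict, adjust: str = "holm") -> dict:
    """Kruskal-Wallis across contraction types followed by Dunn's test.

    ``groups`` maps type name to that type's parameter values. Groups with
    fewer than 2 values are excluded with a warning. Reports the H
    statistic, overall p, per-group medians and the pairwise Dunn table.
    """
    usable = {}
    excluded = []
    for k, v in groups.items():
        v = np.asarray(v, dtype=float)
        v = v[np.isfinite(v)]
        if v.size >= 2:
            usable[k] = v
        else:
            excluded.append(k)
    if excluded:
        warnings.warn(f"groups excluded with < 2 values: {excluded}")
    if len(usable) < 2:
        raise ValueError("need >= 2 groups with >= 2 values each")
    H, p = sps.kruskal(*usable.values())
    return {
        "H": float(H),
        "p": float(p),
        "medians": {k: float(np.median(v)) for k, v in usable.items()},
        "n": {k: int(v.size) for k, v in usable.items()},
        "dunn": dunn_test(usable, adjust=adjust),
        "excluded_groups": excluded,
    }


# ---------------------------------------------------------------------------
# cross-segment: ANOVA + Tukey


def _letters_from_pairwise(names, nonsig_pairs) -> dict:
    """Compact letter display: groups not significantly different share a letter."""
    nonsig = set(nonsig_pairs)
    letters: list[set] = []  # each entry: set of group indices sharing a letter
    for i in range(len(names)):
        placed = False
        for grp in letters:
            if all((min(i, j), max(i, j)) in nonsig for j in grp):
                grp.add(i)
                placed = True
        if not placed:
            letters.append({i})
    # absorb subsets
    letters = [g for g in letters if not any(g < h for h in letters)]
    out = {name: "" for name in names}
    for k, grp in enumerate(letters):
        for i in sorted(grp):
            out[names[i]] += chr(ord("a") + k)
    return out


def compare_segments(groups: dict, alpha: float = 0.05) -> dict:
    """One-way ANOVA across segments followed by Tukey HSD.

    ``groups`` maps segment name to per-replicate frequencies. Groups with
    fewer than 2 values are excluded with a warning. Segments whose Tukey
    p >= alpha share a compact-display letter.
    """
    usable = {}
    excluded = []
    for k, v in groups.items():
        v = np.asarray(v, dtype=float)
        v = v[np.isfinite(v)]
        if v.size >= 2:
            usable[k] = v
        else:
            excluded.append(k)
    if excluded:
        warnings.warn(f"groups excluded with < 2 values: {excluded}")
    if len(usable) < 2:
        raise ValueError("need >= 2 groups with >= 2 values each")

    names = list(usable)
    F, p = sps.f_oneway(*usable.values())
    tukey = sps.tukey_hsd(*usable.values())
    pairs = []
    nonsig = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            pij = float(tukey.pvalue[i, j])
            pairs.append({"group_a": names[i], "group_b": names[j], "p_adj": pij})
            if pij >= alpha:
                nonsig.append((i, j))
    return {
        "F": float(F),
        "p": float(p),
        "means": {k: float(v.mean()) for k, v in usable.items()},
        "n": {k: int(v.size) for k, v in usable.items()},
        "tukey": pairs,
        "letters": _letters_from_pairwise(names, nonsig),
        "excluded_groups": excluded,
    }


# ---------------------------------------------------------------------------
# gut-length reduction


def length_reduction(
    trace: LengthTrace,
    event_time_s: float,
    window_s: float = 600.0,
    prominence_frac: float = 0.01,
) -> dict:
    """Percent gut shortening and shortening-event frequency around a treatment.

    The percent reduction compares the mean length over the before-window
    (``window_s`` seconds up to the treatment) with the minimum length in
    the after-window. Shortening events are local minima of the length trace
    with prominence of at least ``prominence_frac`` of the before-window
    mean length; frequencies are events per minute per window.
    """
    times = trace.times_s
    before = (times >= event_time_s - window_s) & (times < event_time_s)
    after = (times >= event_time_s) & (times <= event_time_s + window_s)
    for name, sel in (("before", before), ("after", after)):
        if not sel.any() or not np.isfinite(trace.length_mm[sel]).any():
            raise ValueError(f"length trace does not cover the {name}-window")

    mean_before = float(np.nanmean(trace.length_mm[before]))
    min_after = float(np.nanmin(trace.length_mm[after]))
    pct_reduction = 100.0 * (mean_before - min_after) / mean_before

    prominence = prominence_frac * mean_before
    minima, _ = signal.find_peaks(-trace.length_mm, prominence=prominence)
    minutes = window_s / 60.0
    n_before = int(before[minima].sum()) if minima.size else 0
    n_after = int(after[minima].sum()) if minima.size else 0
    return {
        "percent_reduction": pct_reduction,
        "mean_length_before_mm": mean_before,
        "min_length_after_mm": min_after,
        "events_before": n_before,
        "events_after": n_after,
        "event_freq_before_per_min": n_before / minutes,
        "event_freq_after_per_min": n_after / minutes,
        "event_indices": minima.tolist(),
        "prominence_mm": prominence,
    }
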