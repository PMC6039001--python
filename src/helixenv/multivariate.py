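"""Descriptor filtering and inside-vs-outside MANOVA.

Descriptors are first screened per group with a Shapiro-Wilk normality
test, then thinned greedily until no pair exceeds the Pearson correlation
cutoff (default 0.9); the survivors feed a two-group one-way MANOVA
reported with the four canonical statistics (Wilks, Pillai,
Hotelling-Lawley, Roy).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.multivariate.manova import MANOVA

from helixenv._errors import DegenerateDataError, InputError

STATISTIC_NAMES = ("Wilks' lambda", "Pillai's trace",
                   "Hotelling-Lawley trace", "Roy's greatest root")

#: Condition-number guard for the pooled within-group covariance.
COND_LIMIT = 1e12


@dataclass
class FilterReport:
    """Bookkeeping of the two descriptor filters."""

    input: list[str]
    removed_nonnormal: list[dict] = field(default_factory=list)
    removed_correlated: list[dict] = field(default_factory=list)
    retained: list[str] = field(default_factory=list)

    @property
    def removed(self) -> list[str]:
        return ([d["descriptor"] for d in self.removed_nonnormal]
                + [d["descriptor"] for d in self.removed_correlated])


def _as_groups(labels) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    inside = labels.astype(bool) if labels.dtype != object else labels == "inside"
    return inside, ~inside


def normality_filter(table: pd.DataFrame, labels, alpha: float = 0.05,
                     report: FilterReport | None = None) -> FilterReport:
    """Keep a descriptor iff Shapiro-Wilk p >= alpha within *both* groups.

    Constant columns are removed and flagged as degenerate.
    """
    report = report or FilterReport(input=list(table.columns))
    inside, outside = _as_groups(labels)
    retained = []
    for name in table.columns:
        col = table[name].to_numpy(dtype=float)
        verdicts = []
        degenerate = False
        for group_name, mask in (("inside", inside), ("outside", outside)):
            vals = col[mask]
            vals = vals[~np.isnan(vals)]
            if vals.size < 3 or np.ptp(vals) == 0.0:
                report.removed_nonnormal.append({
                    "descriptor": name, "group": group_name,
                    "statistic": np.nan, "p": np.nan, "degenerate": True})
                degenerate = True
                break
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                stat, p = stats.shapiro(vals)
            verdicts.append((group_name, float(stat), float(p)))
        if degenerate:
            continue
        failed = [v for v in verdicts if v[2] < alpha]
        if failed:
            group_name, stat, p = failed[0]
            report.removed_nonnormal.append({
                "descriptor": name, "group": group_name,
                "statistic": stat, "p": p, "degenerate": False})
        else:
            retained.append(name)
    report.retained = retained
    return report


def correlation_filter(table: pd.DataFrame, cutoff: float = 0.9,
                       report: FilterReport | None = None) -> FilterReport:
    """Greedy elimination until all pairwise |Pearson r| < cutoff.

    At each step the most correlated pair is found and the member with the
    larger mean absolute correlation to all remaining descriptors is
    dropped (ties: the later column).
    """
    report = report or FilterReport(input=list(table.columns))
    cols = list(table.columns)
    corr = table[cols].corr().abs().to_numpy()
    np.fill_diagonal(corr, 0.0)
    alive = list(range(len(cols)))
    while len(alive) > 1:
        sub = corr[np.ix_(alive, alive)]
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        if sub[i, j] < cutoff or np.isnan(sub[i, j]):
            break
        mean_i = np.nanmean(np.delete(sub[i], i))
        mean_j = np.nanmean(np.delete(sub[j], j))
        if mean_i > mean_j:
            drop, partner = i, j
        elif mean_j > mean_i:
            drop, partner = j, i
        else:   # tie: later column order loses
            drop, partner = (i, j) if alive[i] > alive[j] else (j, i)
        report.removed_correlated.append({
            "descriptor": cols[alive[drop]],
            "partner": cols[alive[partner]],
            "r": float(table[cols[alive[drop]]].corr(
                table[cols[alive[partner]]])),
        })
        del alive[drop]
    report.retained = [cols[k] for k in alive]
    return report


def apply_filters(table: pd.DataFrame, labels, alpha: float = 0.05,
                  cutoff: float = 0.9) -> FilterReport:
    """Normality filter followed by correlation filter (in that order)."""
    report = normality_filter(table, labels, alpha)
    if report.retained:
        corr_part = correlation_filter(table[report.retained], cutoff)
        report.removed_correlated = corr_part.removed_correlated
        report.retained = corr_part.retained
    return report


@dataclass
class ManovaReport:
    n_inside: int
    n_outside: int
    descriptors: list[str]
    statistics: pd.DataFrame    # index: statistic name; value/F/df1/df2/p

    @property
    def min_p(self) -> float:
        return float(self.statistics["p"].min())


def _manova_one_descriptor(x_in: np.ndarray, x_out: np.ndarray,
                           ) -> pd.DataFrame:
    """Single response: reduce to one-way ANOVA; the one nonzero
    eigenvalue lam = SSH/SSE determines all four statistics."""
    n1, n2 = x_in.size, x_out.size
    grand = np.concatenate([x_in, x_out]).mean()
    ssh = n1 * (x_in.mean() - grand) ** 2 + n2 * (x_out.mean() - grand) ** 2
    sse = np.sum((x_in - x_in.mean()) ** 2) + np.sum((x_out - x_out.mean()) ** 2)
    if sse <= 0.0:
        raise DegenerateDataError("zero within-group variance")
    lam = ssh / sse
    df1, df2 = 1, n1 + n2 - 2
    f = lam * df2 / df1
    p = float(stats.f.sf(f, df1, df2))
    values = {"Wilks' lambda": 1.0 / (1.0 + lam),
              "Pillai's trace": lam / (1.0 + lam),
              "Hotelling-Lawley trace": lam,
              "Roy's greatest root": lam}
    return pd.DataFrame({
        "value": [values[s] for s in STATISTIC_NAMES],
        "F": f, "df1": float(df1), "df2": float(df2), "p": p,
    }, index=list(STATISTIC_NAMES))


def manova_inside_outside(table: pd.DataFrame, labels,
                          descriptors: Sequence[str] | None = None,
                          ) -> ManovaReport:
    """Two-group one-way MANOVA of inside vs outside residues.

    ``descriptors`` is typically ``FilterReport.retained``; a single
    descriptor reduces analytically to one-way ANOVA.
    """
    descriptors = list(descriptors if descriptors is not None
                       else table.columns)
    if not descriptors:
        raise InputError("no descriptors retained for MANOVA")
    inside, outside = _as_groups(labels)
    data = table[descriptors].to_numpy(dtype=float)
    keep = ~np.isnan(data).any(axis=1)
    data, inside, outside = data[keep], inside[keep], outside[keep]
    n1, n2 = int(inside.sum()), int(outside.sum())
    if n1 < 2 or n2 < 2:
        raise DegenerateDataError(
            f"each group needs >= 2 observations (inside={n1}, outside={n2})")
    if len(descriptors) == 1:
        statistics = _manova_one_descriptor(
            data[inside, 0], data[outside, 0])
        return ManovaReport(n1, n2, descriptors, statistics)

    pooled = (np.cov(data[inside].T) * (n1 - 1)
              + np.cov(data[outside].T) * (n2 - 1)) / (n1 + n2 - 2)
    if np.linalg.cond(pooled) > COND_LIMIT:
        raise DegenerateDataError(
            "pooled covariance is near-singular; apply a stricter "
            "correlation filter before MANOVA")

    exog = np.column_stack([np.ones(data.shape[0]),
                            inside.astype(float)])
    mv = MANOVA(data, exog)
    contrast = np.array([[0.0, 1.0]])
    result = mv.mv_test(hypotheses=[("group", contrast, None)])
    stat = result.results["group"]["stat"]
    statistics = pd.DataFrame({
        "value": stat["Value"].astype(float).to_numpy(),
        "F": stat["F Value"].astype(float).to_numpy(),
        "df1": stat["Num DF"].astype(float).to_numpy(),
        "df2": stat["Den DF"].astype(float).to_numpy(),
        "p": stat["Pr > F"].astype(float).to_numpy(),
    }, index=list(stat.index))
    statistics = statistics.rename(
        index={"Roy's greatest root": "Roy's greatest root"})
    return ManovaReport(n1, n2, descriptors, statistics)


def usage_ranking(retained_by_size: Mapping[int, Sequence[str]],
                  ) -> pd.DataFrame:
    """How often each descriptor survived filtering across helix sizes.

    Returns descriptor, count, pct (count over number of sizes, percent),
    sorted by descending count then name.
    """
    if not retained_by_size:
        raise InputError("no filter reports supplied")
    n_sizes = len(retained_by_size)
    counts: dict[str, int] = {}
    for retained in retained_by_size.values():
        for name in retained:
            counts[name] = counts.get(name, 0) + 1
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame({
        "descriptor": [name for name, _ in rows],
        "count": [c for _, c in rows],
        "pct": [100.0 * c / n_sizes for _, c in rows],
    })


def assess_region(table: pd.DataFrame, region: tuple[int, int],
                  threshold: float = 1e-6, alpha: float = 0.05,
                  cutoff: float = 0.9) -> dict:
    """Filtered MANOVA of one candidate region against the rest of a chain.

    ``table`` holds one chain (``residue_index`` plus descriptor columns);
    ``region`` is a 0-based inclusive span.  Verdict is 'helix-like' iff
    the smallest of the four MANOVA p-values is at or below ``threshold``.
    """
    if "residue_index" not in table.columns:
        raise InputError("table needs a residue_index column")
    start, end = region
    if end < start:
        raise InputError(f"bad region {region}")
    idx = table["residue_index"].to_numpy()
    labels = (idx >= start) & (idx <= end)
    n_in, n_out = int(labels.sum()), int((~labels).sum())
    if n_in == 0:
        raise InputError(f"region {region} contains no residues")
    if n_out == 0:
        raise InputError("region covers the whole chain; nothing outside")
    if n_in < 2 or n_out < 2:
        raise DegenerateDataError(
            f"insufficient group size (inside={n_in}, outside={n_out})")
    values = table.drop(columns=["residue_index", "chain_id"],
                        errors="ignore")
    report = apply_filters(values, labels, alpha=alpha, cutoff=cutoff)
    if not report.retained:
        raise DegenerateDataError("no descriptors survived filtering")
    manova = manova_inside_outside(values, labels, report.retained)
    return {
        "region": (int(start), int(end)),
        "n_inside": manova.n_inside,
        "n_outside": manova.n_outside,
        "retained": report.retained,
        "min_p": manova.min_p,
        "helix_like": bool(manova.min_p <= threshold),
        "manova": manova,
        "filter_report": report,
    }
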