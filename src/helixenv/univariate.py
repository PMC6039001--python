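"""Single-descriptor signal detection.

Pooled-variance two-sample t-test, two-sample Kolmogorov-Smirnov test,
sliding-window scans over alignment profiles, and normalized-difference
(inverse coefficient of variation) classification of descriptors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from helixenv._errors import DegenerateDataError
from helixenv.alignment import AlignedEnsemble, inside_outside_values

#: |normalized difference| below this -> no signal; above 1.0 -> strong.
CLASS_THRESHOLDS = (0.1, 1.0)


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    df: int
    p_value: float
    pooled_sd: float
    mean1: float
    mean2: float
    n1: int
    n2: int


@dataclass(frozen=True)
class KSResult:
    statistic: float            # Dn, the supremum ECDF gap
    p_value: float
    n1: int
    n2: int


def two_sample_t(x1, x2) -> TTestResult:
    """Pooled-variance Student's t-test with n1 + n2 - 2 degrees of freedom.

    Degenerate data (zero pooled variance): equal means give t = 0, p = 1
    so constant descriptors scan cleanly; unequal means raise
    :class:`DegenerateDataError`.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    n1, n2 = x1.size, x2.size
    df = n1 + n2 - 2
    if n1 < 1 or n2 < 1 or df < 1:
        raise DegenerateDataError(
            f"need n1 + n2 - 2 >= 1 degrees of freedom (n1={n1}, n2={n2})")
    m1, m2 = x1.mean(), x2.mean()
    ss = np.sum((x1 - m1) ** 2) + np.sum((x2 - m2) ** 2)
    pooled_sd = np.sqrt(ss / df)
    if pooled_sd == 0.0:
        if m1 == m2:
            return TTestResult(0.0, df, 1.0, 0.0, m1, m2, n1, n2)
        raise DegenerateDataError(
            "zero pooled variance with unequal means: t undefined")
    t = (m1 - m2) / (pooled_sd * np.sqrt(1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(float(t), df, float(p), float(pooled_sd),
                       float(m1), float(m2), n1, n2)


def ks_two_sample(x1, x2) -> KSResult:
    """Two-sample KS test: Dn = sup |F1(x) - F2(x)| over the pooled support,
    asymptotic p-value with effective size n1*n2/(n1+n2)."""
    x1 = np.sort(np.asarray(x1, dtype=float))
    x2 = np.sort(np.asarray(x2, dtype=float))
    n1, n2 = x1.size, x2.size
    if n1 < 1 or n2 < 1:
        raise DegenerateDataError("both samples must be nonempty")
    pooled = np.concatenate([x1, x2])
    f1 = np.searchsorted(x1, pooled, side="right") / n1
    f2 = np.searchsorted(x2, pooled, side="right") / n2
    dn = float(np.max(np.abs(f1 - f2)))
    n_eff = n1 * n2 / (n1 + n2)
    p = float(np.clip(special.kolmogorov(np.sqrt(n_eff) * dn), 0.0, 1.0))
    return KSResult(dn, p, n1, n2)


def _test_placement(inside: np.ndarray, outside: np.ndarray,
                    test: str) -> float:
    inside = inside[~np.isnan(inside)]
    outside = outside[~np.isnan(outside)]
    try:
        if test == "t":
            return two_sample_t(inside, outside).p_value
        if test == "ks":
            return ks_two_sample(inside, outside).p_value
    except DegenerateDataError:
        return np.nan
    raise ValueError(f"unknown test {test!r}; choose 't' or 'ks'")


@dataclass
class WindowScan:
    """p-values of a two-sample test for every placement of one window."""

    window: int
    test: str
    p_values: np.ndarray        # one entry per placement; NaN = undefined

    @property
    def n_placements(self) -> int:
        return self.p_values.size

    @property
    def argmin(self) -> int | None:
        """Earliest placement attaining the minimal defined p-value."""
        if np.all(np.isnan(self.p_values)):
            return None
        return int(np.nanargmin(self.p_values))


def sliding_window_scan(profile: Sequence[float], window: int,
                        test: str = "t") -> WindowScan:
    """Slide a window over per-position profile values; at each placement
    test the values under the window against all remaining values.

    Placements with too few non-missing values on either side yield a
    missing p-value.
    """
    values = np.asarray(profile, dtype=float)
    p_total = values.size
    if not 1 <= window <= p_total - 1:
        raise ValueError(
            f"window {window} out of range for {p_total} positions")
    n_placements = p_total - window + 1
    p_values = np.full(n_placements, np.nan)
    for s in range(n_placements):
        inside = values[s:s + window]
        outside = np.concatenate([values[:s], values[s + window:]])
        p_values[s] = _test_placement(inside, outside, test)
    return WindowScan(window=window, test=test, p_values=p_values)


def multi_window_scan(profile: Sequence[float], length: int,
                      test: str = "t",
                      windows: Iterable[int] | None = None,
                      ) -> dict[int, WindowScan]:
    """One scan per window size (default sizes 1 .. 2L, clipped to fit)."""
    p_total = np.asarray(profile).size
    if windows is None:
        windows = range(1, min(2 * length, p_total - 1) + 1)
    return {w: sliding_window_scan(profile, w, test) for w in windows}


def scan_summary(scans: dict[int, WindowScan]) -> pd.DataFrame:
    """Per window size: best placement and its p-value."""
    rows = []
    for w, scan in sorted(scans.items()):
        best = scan.argmin
        rows.append({
            "window": w,
            "best_placement": best if best is not None else pd.NA,
            "best_p": scan.p_values[best] if best is not None else np.nan,
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SignalClassification:
    descriptor: str
    inside_norm: float
    outside_norm: float
    difference: float
    label: str                  # none | moderate | strong | undefined


def _classify(diff: float) -> str:
    lo, hi = CLASS_THRESHOLDS
    if abs(diff) < lo:
        return "none"
    if abs(diff) <= hi:
        return "moderate"
    return "strong"


def icv_classify(ensemble: AlignedEnsemble, descriptor: str,
                 granularity: str = "residues") -> SignalClassification:
    """Inverse-CV normalized inside/outside comparison for one descriptor.

    Each region's value set is normalized as mean/SD; the absolute
    difference of the two normalized values sets the class (none below
    0.1, moderate up to 1.0, strong above).  Region value sets default to
    raw residue values.
    """
    inside, outside = inside_outside_values(ensemble, descriptor, granularity)
    sd_in = np.std(inside, ddof=1) if inside.size >= 2 else 0.0
    sd_out = np.std(outside, ddof=1) if outside.size >= 2 else 0.0
    if sd_in == 0.0 or sd_out == 0.0:
        return SignalClassification(descriptor, np.nan, np.nan, np.nan,
                                    "undefined")
    norm_in = float(np.mean(inside) / sd_in)
    norm_out = float(np.mean(outside) / sd_out)
    diff = norm_in - norm_out
    return SignalClassification(descriptor, norm_in, norm_out, diff,
                                _classify(diff))


def signal_census(ensemble: AlignedEnsemble,
                  descriptors: Sequence[str] | None = None,
                  granularity: str = "residues",
                  ) -> tuple[pd.DataFrame, dict[str, float]]:
    """Classify every descriptor and summarise the counts.

    Returns the per-descriptor table and a summary with class counts and
    the percentage of descriptors bearing a signal (strong + moderate).
    """
    descriptors = list(descriptors or ensemble.values)
    entries = [icv_classify(ensemble, d, granularity) for d in descriptors]
    table = pd.DataFrame([e.__dict__ for e in entries])
    counts = {label: int(sum(e.label == label for e in entries))
              for label in ("strong", "moderate", "none", "undefined")}
    summary = dict(counts)
    summary["signal_pct"] = census_percentage(
        counts["strong"], counts["moderate"], len(descriptors))
    return table, summary


def census_percentage(n_strong: int, n_moderate: int, n_total: int) -> float:
    """Signal-bearing share of the descriptor set, in percent (1 decimal)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return round(100.0 * (n_strong + n_moderate) / n_total, 1)
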