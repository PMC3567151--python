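"""Windowed substitution rates, per-replicate regressions, and counts.

The simulation analogue of comparing branch-specific dN/dS between genes:
the absolute change in a locus's mean allelic value over each window of
generations is its substitution rate for that window; rates of two loci
are regressed against each other within a replicate, the slope classified
(positive / negative / none) at a significance level, classifications are
counted across replicates, and a Fisher's exact test contrasts the decoy
pair against the neutral control pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .errors import InputError
from .population import LOCI, Trajectory

__all__ = [
    "RateSeries",
    "RegressionResult",
    "ReplicateSummary",
    "substitution_rates",
    "fit_rate_regression",
    "classify_correlation",
    "summarize_replicates",
    "fisher_exact_2x2",
    "LOCUS_PAIRS",
]

LOCUS_PAIRS = (
    ("male", "female"),
    ("male", "decoy"),
    ("male", "neutral"),
    ("female", "decoy"),
    ("female", "neutral"),
    ("decoy", "neutral"),
)


@dataclass
class RateSeries:
    """Per-window substitution rates for one locus of one replicate.

    ``rates`` are absolute changes of the mean allelic value per window
    (allele units); ``signed`` retains the raw changes for diagnostics.
    """

    locus: str
    rates: np.ndarray
    window: int
    signed: Optional[np.ndarray] = None

    def __len__(self) -> int:
        return len(self.rates)


@dataclass
class RegressionResult:
    """Least-squares fit of one rate series on another.

    ``p_value`` is the two-sided test of zero slope; ``weighted`` records
    whether weighted least squares was used and ``weight_desc`` what the
    weights were.
    """

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    weighted: bool = False
    weight_desc: str = "none"
    slope_se: float = float("nan")

    def conf_int(self, alpha: float = 0.05) -> tuple[float, float]:
        """Two-sided confidence interval for the slope."""
        t = scipy.stats.t.ppf(1.0 - alpha / 2.0, self.n - 2)
        return (self.slope - t * self.slope_se, self.slope + t * self.slope_se)


@dataclass
class ReplicateSummary:
    """Classification counts per locus pair across replicates.

    ``counts`` maps pair -> {"positive": int, "negative": int, "none": int};
    ``fisher`` holds the one- and two-sided Fisher p-values for the default
    decoy-vs-neutral contrast.
    """

    counts: dict
    n_replicates: int
    alpha: float
    classifications: pd.DataFrame = field(default_factory=pd.DataFrame)
    fisher_one_sided: float = float("nan")
    fisher_two_sided: float = float("nan")
    fisher_table: Optional[np.ndarray] = None

    def count(self, pair, kind: str) -> int:
        return self.counts[tuple(pair)][kind]

    def to_report(self) -> str:
        """Structured key=value report."""
        lines = [f"n_replicates = {self.n_replicates}", f"alpha = {self.alpha}"]
        for pair, c in self.counts.items():
            key = f"{pair[0]}-{pair[1]}"
            for kind in ("positive", "negative", "none"):
                lines.append(f"{key}.{kind} = {c[kind]}")
        if self.fisher_table is not None:
            lines.append(
                "fisher_table = " + ";".join(",".join(map(str, r)) for r in self.fisher_table)
            )
        lines.append(f"fisher_one_sided_p = {self.fisher_one_sided:.6g}")
        lines.append(f"fisher_two_sided_p = {self.fisher_two_sided:.6g}")
        return "\n".join(lines) + "\n"


def substitution_rates(traj: Trajectory, window: int) -> dict[str, RateSeries]:
    """Windowed substitution rates for every locus of a trajectory.

    The rate in a window is the absolute change of the mean allelic value
    from the window's start to its end (a nonnegative rate proxy, like
    dN/dS); the signed change is retained on the series.  The trajectory
    length (generations) must be divisible by the window.
    """
    n_gen = traj.means.shape[0] - 1
    if window <= 0 or n_gen % window != 0:
        raise InputError(
            f"trajectory of {n_gen} generations is not divisible into "
            f"windows of {window}"
        )
    checkpoints = traj.means[::window]
    diffs = np.diff(checkpoints, axis=0)
    return {
        locus: RateSeries(
            locus=locus,
            rates=np.abs(diffs[:, i]),
            window=window,
            signed=diffs[:, i],
        )
        for i, locus in enumerate(LOCI)
    }


def _as_rates(x) -> np.ndarray:
    return x.rates if isinstance(x, RateSeries) else np.asarray(x, dtype=float)


def fit_rate_regression(
    x, y, weights: Optional[Sequence[float]] = None
) -> RegressionResult:
    """Least squares of rate series ``y`` on ``x`` (optionally weighted).

    Ordinary least squares when ``weights`` is None; weighted least
    squares with the given per-point weights otherwise.  Returns slope,
    intercept, r-squared and the two-sided p-value for slope = 0.
    """
    xv, yv = _as_rates(x), _as_rates(y)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise InputError("rate series must be one-dimensional and equal length")
    n = len(xv)
    if n < 3:
        raise InputError("at least 3 points are required for a regression")
    if np.ptp(xv) == 0:
        raise InputError("degenerate fit: predictor series has zero variance")
    X = sm.add_constant(xv)
    if weights is None:
        fit = sm.OLS(yv, X).fit()
        weighted, desc = False, "none"
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != xv.shape:
            raise InputError("weights must match the series length")
        if np.any(w <= 0):
            raise InputError("weights must be positive")
        fit = sm.WLS(yv, X, weights=w).fit()
        weighted, desc = True, "user-supplied per-point weights"
    r2 = float(fit.rsquared)
    p = float(fit.pvalues[1])
    # a constant response has zero centered TSS: no slope, no evidence
    if not np.isfinite(r2):
        r2 = 0.0
    if not np.isfinite(p):
        p = 1.0
    return RegressionResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r_squared=r2,
        p_value=p,
        n=n,
        weighted=weighted,
        weight_desc=desc,
        slope_se=float(fit.bse[1]),
    )


def classify_correlation(res: RegressionResult, alpha: float = 0.05) -> str:
    """'positive' / 'negative' if the slope is significant at ``alpha``, else 'none'."""
    if not np.isfinite(res.p_value) or not np.isfinite(res.slope):
        return "none"
    if res.p_value < alpha and res.slope > 0:
        return "positive"
    if res.p_value < alpha and res.slope < 0:
        return "negative"
    return "none"


def classify_trajectory(
    traj: Trajectory, window: int, alpha: float = 0.05
) -> dict[tuple, str]:
    """Classification of every locus pair of one replicate.

    Pairs whose regression is degenerate (zero-variance rates, e.g. a
    constant trajectory) classify as 'none' rather than raising.
    """
    series = substitution_rates(traj, window)
    out = {}
    for a, b in LOCUS_PAIRS:
        try:
            res = fit_rate_regression(series[a], series[b])
            out[(a, b)] = classify_correlation(res, alpha)
        except InputError:
            out[(a, b)] = "none"
    return out


def summarize_replicates(
    classifications: Sequence[dict],
    alpha: float = 0.05,
    fisher_pairs: tuple = (("male", "decoy"), ("male", "neutral")),
    fisher_kind: str = "negative",
) -> ReplicateSummary:
    """Counts per locus pair plus the Fisher contrast.

    ``classifications`` is one dict per replicate mapping pair ->
    'positive'/'negative'/'none' (as from :func:`classify_trajectory`).
    The Fisher 2x2 table contrasts, across replicates, significance of
    ``fisher_kind`` (default: negative slopes, or 'any' for any
    significant slope) between the two ``fisher_pairs`` (default: the
    male-decoy pair against the male-neutral control pair).
    """
    if len(classifications) == 0:
        raise InputError("at least one replicate is required")
    pairs = sorted({p for c in classifications for p in c})
    counts = {
        p: {"positive": 0, "negative": 0, "none": 0} for p in pairs
    }
    rows = []
    for i, c in enumerate(classifications):
        for p, kind in c.items():
            counts[p][kind] += 1
            rows.append({"replicate": i, "pair": f"{p[0]}-{p[1]}", "class": kind})

    def hits(pair):
        c = counts[tuple(pair)]
        if fisher_kind == "any":
            return c["positive"] + c["negative"]
        return c[fisher_kind]

    n = len(classifications)
    table = np.array(
        [
            [hits(fisher_pairs[0]), n - hits(fisher_pairs[0])],
            [hits(fisher_pairs[1]), n - hits(fisher_pairs[1])],
        ]
    )
    return ReplicateSummary(
        counts=counts,
        n_replicates=n,
        alpha=alpha,
        classifications=pd.DataFrame(rows),
        fisher_one_sided=fisher_exact_2x2(table, "greater"),
        fisher_two_sided=fisher_exact_2x2(table, "two-sided"),
        fisher_table=table,
    )


def fisher_exact_2x2(table, sidedness: str = "two-sided") -> float:
    """Fisher's exact test for a 2x2 table of nonnegative counts.

    Exact hypergeometric p-value with the table margins fixed.
    ``sidedness``: 'greater' (tail of the observed or larger [0,0] cell),
    'less', or 'two-sided' (sum over tables whose probability does not
    exceed the observed one).
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise InputError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        if np.any(t != np.floor(t)) or np.any(t < 0):
            raise InputError("table entries must be nonnegative integers")
        t = t.astype(int)
    if sidedness not in ("two-sided", "greater", "less"):
        raise InputError(f"unknown sidedness '{sidedness}'")
    if t.sum() == 0:
        return 1.0
    return float(scipy.stats.fisher_exact(t, alternative=sidedness)[1])


def write_rate_table(series: dict[str, RateSeries], path) -> None:
    """Tab-separated per-window rates, one column per locus (plus signed)."""
    df = pd.DataFrame({locus: s.rates for locus, s in series.items()})
    for locus, s in series.items():
        if s.signed is not None:
            df[f"{locus}_signed"] = s.signed
    df.insert(0, "window", np.arange(len(df)))
    df.to_csv(path, sep="\t", index=False)
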