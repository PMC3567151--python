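"""Branch-specific evolutionary-rate correlations between genes.

Applies the same regression machinery used on simulation rate windows to
empirical tables of branch-specific dN/dS (omega) estimates — e.g. from a
codon branch model — for two or more genes over a shared tree topology.
Regressions may be weighted by branch length, the convention for rate
comparisons across branches of unequal depth.  A fixture generator
produces synthetic tables with a configurable linear relationship so the
machinery is testable without codon-model output.

Table format (tab-separated, header required)::

    branch  length  <gene1>  <gene2>  [...]

``branch`` is an arbitrary identifier, ``length`` the branch length in
substitutions per codon (> 0), and each gene column holds the branch's
omega estimate (>= 0).  Branches with undefined omega must be resolved
upstream; non-numeric entries are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError
from .rate_stats import RegressionResult, fit_rate_regression

__all__ = [
    "BranchRateTable",
    "read_branch_rates",
    "write_branch_rates",
    "branch_rate_regression",
    "simulate_branch_rates",
]


@dataclass
class BranchRateTable:
    """Per-branch omega values for >= 2 genes plus branch lengths."""

    data: pd.DataFrame  # columns: branch, length, one per gene

    def __post_init__(self):
        cols = list(self.data.columns)
        for required in ("branch", "length"):
            if required not in cols:
                raise InputError(f"branch-rate table lacks a '{required}' column")
        if len(self.genes) < 1:
            raise InputError("branch-rate table has no gene columns")
        lengths = self.data["length"].to_numpy()
        bad = np.flatnonzero(~(lengths > 0))
        if bad.size:
            raise InputError(
                f"branch length must be positive (row {bad[0] + 1})"
            )
        for gene in self.genes:
            om = self.data[gene].to_numpy()
            bad = np.flatnonzero(~np.isfinite(om) | (om < 0))
            if bad.size:
                raise InputError(
                    f"omega for gene '{gene}' must be a nonnegative number "
                    f"(row {bad[0] + 1})"
                )

    @property
    def genes(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("branch", "length")]

    @property
    def n_branches(self) -> int:
        return len(self.data)

    def omega(self, gene: str) -> np.ndarray:
        if gene not in self.genes:
            raise InputError(f"gene '{gene}' not present in table")
        return self.data[gene].to_numpy(dtype=float)

    @property
    def lengths(self) -> np.ndarray:
        return self.data["length"].to_numpy(dtype=float)


def read_branch_rates(path) -> BranchRateTable:
    """Parse a tab-separated branch-rate table (see module docstring)."""
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # noqa: BLE001 - surface as a format error
        raise InputError(f"cannot parse branch-rate table {path}: {exc}") from exc
    for col in df.columns:
        if col in ("branch",):
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(coerced.isna() & df[col].notna())
        if bad.size:
            raise InputError(
                f"non-numeric value in column '{col}' (row {bad[0] + 1})"
            )
        df[col] = coerced
    return BranchRateTable(df)


def write_branch_rates(table: BranchRateTable, path) -> None:
    table.data.to_csv(path, sep="\t", index=False)


def branch_rate_regression(
    table: BranchRateTable, gene_x: str, gene_y: str, weighted: bool = False
) -> RegressionResult:
    """Regression of ``gene_y`` omega on ``gene_x`` omega across branches.

    When ``weighted``, per-branch weights equal the branch length exactly
    (no normalization): longer branches carry proportionally more
    information about the underlying rates.
    """
    x = table.omega(gene_x)
    y = table.omega(gene_y)
    res = fit_rate_regression(x, y, weights=table.lengths if weighted else None)
    if weighted:
        res.weight_desc = "branch length"
    return res


def simulate_branch_rates(
    n_branches: int,
    slope: float,
    intercept: float = 0.0,
    noise_sd: float = 0.1,
    length_distribution=None,
    seed: int = 0,
) -> BranchRateTable:
    """Synthetic branch-rate fixture with a known linear relationship.

    ``gene_x`` omegas are drawn from a lognormal centred near 1 (clipped
    nonnegative), ``gene_y = max(0, intercept + slope * gene_x + eps)``
    with Gaussian noise ``eps``, and branch lengths from
    ``length_distribution(rng, n)`` (default: lognormal, mean ~0.1
    substitutions per codon).  Fully reproducible from ``seed``.
    """
    if n_branches < 3:
        raise InputError("n_branches must be >= 3")
    if noise_sd < 0:
        raise InputError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    x = rng.lognormal(mean=0.0, sigma=0.6, size=n_branches)
    y = np.maximum(0.0, intercept + slope * x + rng.normal(0.0, noise_sd, n_branches))
    if length_distribution is None:
        lengths = rng.lognormal(mean=np.log(0.1), sigma=0.5, size=n_branches)
    else:
        lengths = np.asarray(length_distribution(rng, n_branches), dtype=float)
    df = pd.DataFrame(
        {
            "branch": [f"b{i}" for i in range(n_branches)],
            "length": lengths,
            "gene_x": x,
            "gene_y": y,
        }
    )
    return BranchRateTable(df)
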