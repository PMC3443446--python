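"""Per-gene ANOVA differential expression on a dose x time design.

A saturated cell-means model is fitted gene by gene: one mean per
(dose, time) cell and a gene-specific pooled residual variance (MSE) with
n_samples - n_cells degrees of freedom (12 for the full 3 x 4 x 2 design).
Dose-vs-control contrasts at each time point are t-tests on the cell-mean
difference using that pooled gene-specific MSE; the Benjamini–Hochberg
step-up procedure controls the FDR within each contrast (q = 0.10 by
default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from coexdiff.design import StudyDesign


@dataclass
class CellMeansFit:
    """Saturated ANOVA fit: per-gene cell means, pooled MSE, residual df."""

    means: pd.DataFrame           # genes x cells; columns are (dose, time) tuples
    mse: pd.Series                # gene-specific pooled residual mean square
    df_resid: int
    cell_n: dict                  # (dose, time) -> replicate count
    design: StudyDesign


@dataclass
class DEComparison:
    """One dose-vs-control contrast at one time point."""

    dose: float
    time: float
    table: pd.DataFrame           # gene-indexed: estimate, t, p, q, de
    q_threshold: float = 0.10

    @property
    def de_set(self) -> set:
        return set(self.table.index[self.table["de"]])

    @property
    def n_de(self) -> int:
        return int(self.table["de"].sum())


@dataclass
class CommonSetSummary:
    """Overlap of the low- and high-dose DE sets at one time point."""

    time: float
    n_de_low: int
    n_de_high: int
    n_common: int
    pct_common: float = field(init=False)

    def __post_init__(self):
        if self.n_common > min(self.n_de_low, self.n_de_high):
            raise ValueError("intersection larger than a set")
        union = self.n_de_low + self.n_de_high - self.n_common
        self.pct_common = round(100.0 * self.n_common / union, 1) if union else 0.0


def fit_cell_means(matrix: pd.DataFrame, design: StudyDesign) -> CellMeansFit:
    """Fit the saturated cell-means model to every gene at once."""
    values = matrix.to_numpy(dtype=float)
    cells = design.cell_indices()
    n = values.shape[1]
    df_resid = n - len(cells)
    if df_resid <= 0:
        raise ValueError(
            f"zero residual df: {n} samples for {len(cells)} design cells"
        )
    means = {}
    rss = np.zeros(values.shape[0])
    for cell, cols in cells.items():
        block = values[:, cols]
        m = block.mean(axis=1)
        means[cell] = m
        rss += ((block - m[:, None]) ** 2).sum(axis=1)
    mean_df = pd.DataFrame(means, index=matrix.index)
    mse = pd.Series(rss / df_resid, index=matrix.index, name="mse")
    return CellMeansFit(
        means=mean_df,
        mse=mse,
        df_resid=df_resid,
        cell_n={c: len(cols) for c, cols in cells.items()},
        design=design,
    )


def dose_contrast(
    fit: CellMeansFit,
    dose: float,
    time: float,
    control: float = 0.0,
    q: float = 0.10,
    pooled: bool = True,
    matrix: pd.DataFrame | None = None,
) -> DEComparison:
    """t-test of (dose, time) vs (control, time) cell means.

    With ``pooled=True`` (default) the gene-specific pooled MSE and its full
    residual df are used:  t = (m_dose - m_ctrl) / sqrt(MSE (1/n1 + 1/n2)).
    With ``pooled=False`` a per-comparison Welch two-sample t-test on the
    raw replicate values is run instead (requires ``matrix``).
    """
    for cell in [(dose, time), (control, time)]:
        if cell not in fit.cell_n:
            raise KeyError(f"design cell {cell} absent from fit")
    diff = fit.means[(dose, time)] - fit.means[(control, time)]
    if pooled:
        n1, n2 = fit.cell_n[(dose, time)], fit.cell_n[(control, time)]
        se = np.sqrt(fit.mse.to_numpy() * (1.0 / n1 + 1.0 / n2))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = diff.to_numpy() / se
        p = 2.0 * stats.t.sf(np.abs(t), fit.df_resid)
        # degenerate MSE=0: zero difference -> no evidence; nonzero -> p=0
        zero_se = se == 0
        t[zero_se & (diff.to_numpy() == 0)] = 0.0
        p[zero_se & (diff.to_numpy() == 0)] = 1.0
        p[zero_se & (diff.to_numpy() != 0)] = 0.0
    else:
        if matrix is None:
            raise ValueError("pooled=False requires the expression matrix")
        cols1 = fit.design.column_indices(doses=[dose], times=[time])
        cols2 = fit.design.column_indices(doses=[control], times=[time])
        v = matrix.to_numpy(dtype=float)
        t, p = stats.ttest_ind(v[:, cols1], v[:, cols2], axis=1, equal_var=False)
    qvals, flags = bh_fdr(p, q)
    table = pd.DataFrame(
        {"estimate": diff, "t": t, "p": p, "q": qvals, "de": flags},
        index=fit.means.index,
    )
    return DEComparison(dose=dose, time=time, table=table, q_threshold=q)


def bh_fdr(pvalues, q: float = 0.10) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up: (adjusted p-values, reject flags at q)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return adj, reject


def common_sets(
    cmp_low: DEComparison, cmp_high: DEComparison
) -> tuple[CommonSetSummary, set]:
    """Intersection of the two dose contrasts' DE sets at one time point."""
    if cmp_low.time != cmp_high.time:
        raise ValueError(
            f"time mismatch: {cmp_low.time} vs {cmp_high.time}"
        )
    low, high = cmp_low.de_set, cmp_high.de_set
    common = low & high
    summary = CommonSetSummary(
        time=cmp_low.time,
        n_de_low=len(low),
        n_de_high=len(high),
        n_common=len(common),
    )
    return summary, common


def summary_from_counts(
    time: float, n_de_low: int, n_de_high: int, n_common: int
) -> CommonSetSummary:
    """Common-set summary from printed counts (pct = 100 |A∩B| / |A∪B|)."""
    return CommonSetSummary(
        time=time, n_de_low=n_de_low, n_de_high=n_de_high, n_common=n_common
    )


def pct_of_set(subset_size: int, set_size: int) -> float:
    """Percentage of a set covered by a subset, rounded to one decimal."""
    if set_size <= 0:
        raise ValueError("set size must be positive")
    if not 0 <= subset_size <= set_size:
        raise ValueError("subset size must lie in [0, set size]")
    return round(100.0 * subset_size / set_size, 1)
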