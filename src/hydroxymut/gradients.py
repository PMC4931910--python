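"""Dose-response binning: mutation frequency along modification gradients.

Modified CpG sites are binned by hmc_rel (the hydroxymethylated share of
their modification) into 9 right-open intervals — evenly spaced or
quantile-based — and the fraction of mutated sites per bin is regressed
on the bin midpoint, with an F-test for a zero slope.  A two-dimensional
variant bins sites by (5mC level, 5hmC level) into a 9x9 grid whose
marginal slices (unmethylated top row, 5hmC-free first column, and the
fully modified diagonal) feed the same slope test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm


@dataclass
class BinSpec:
    """Binning scheme over hmc_rel in [0, 1].

    ``even_right_open``: 9 equal right-open intervals, the last closed at 1
    so hmc_rel = 1 is binned.  ``quantile``: all hmc_rel = 0 sites form the
    first bin; the remaining sites are split into n_bins − 1 quantile bins
    of approximately equal occupancy.  ``mod_floor`` filters to modified
    sites (inclusive, mod level ≥ 10% by default).
    """

    n_bins: int = 9
    scheme: str = "even_right_open"
    mod_floor: float = 0.10
    mod_floor_inclusive: bool = True

    def __post_init__(self):
        if self.n_bins < 2:
            raise ValueError("need at least 2 bins")
        if self.scheme not in ("even_right_open", "quantile"):
            raise ValueError(f"unknown binning scheme {self.scheme!r}")


def _eligible_mask(sites: pd.DataFrame, spec: BinSpec) -> np.ndarray:
    mod = sites["mod_level"].to_numpy(float)
    if spec.mod_floor_inclusive:
        return mod >= spec.mod_floor
    return mod > spec.mod_floor


def assign_bins(values: np.ndarray, spec: BinSpec):
    """Bin indices plus (edge_lo, edge_hi) arrays for hmc_rel values.

    Right-open intervals [lo, hi), with the last interval closed at the
    domain top so the maximal value is binned.
    """
    values = np.asarray(values, float)
    if np.isnan(values).any():
        raise ValueError("hmc_rel undefined (NaN) for an eligible site")
    if spec.scheme == "even_right_open":
        edges = np.linspace(0.0, 1.0, spec.n_bins + 1)
        idx = np.minimum((values * spec.n_bins).astype(int), spec.n_bins - 1)
    else:
        nonzero = values[values > 0]
        inner = np.quantile(nonzero, np.linspace(0, 1, spec.n_bins),
                            method="linear") if len(nonzero) else \
            np.linspace(0, 1, spec.n_bins)
        # first bin isolates the zeros; remaining mass split into n_bins-1
        eps = np.finfo(float).tiny
        edges = np.concatenate([[0.0, eps if len(nonzero) else 1.0 / spec.n_bins],
                                inner[1:]])
        edges[-1] = max(edges[-1], 1.0)
        idx = np.clip(np.searchsorted(edges, values, side="right") - 1,
                      0, spec.n_bins - 1)
        # right-open everywhere except the closed top edge
        top = values >= edges[-1]
        idx[top] = spec.n_bins - 1
    return idx, edges


@dataclass
class BinTable:
    """Per-bin site and mutation tallies; ``df`` columns: bin, edge_lo,
    edge_hi, midpoint, n_sites, n_mutated, frequency (NaN when empty)."""

    df: pd.DataFrame
    spec: BinSpec | None = None

    def populated(self) -> pd.DataFrame:
        return self.df.loc[self.df["n_sites"] > 0]


def _tally(idx, n_bins, edges, mutated_mask) -> BinTable:
    rows = []
    for b in range(n_bins):
        in_bin = idx == b
        n_sites = int(in_bin.sum())
        n_mut = int((in_bin & mutated_mask).sum())
        lo, hi = float(edges[b]), float(edges[b + 1])
        freq = n_mut / n_sites if n_sites else np.nan
        rows.append((b, lo, hi, (lo + hi) / 2, n_sites, n_mut, freq))
    return BinTable(pd.DataFrame(rows, columns=[
        "bin", "edge_lo", "edge_hi", "midpoint", "n_sites", "n_mutated", "frequency"]))


def _mutated_sites_mask(n_sites: int, joins: pd.DataFrame, mutation_type: str):
    mask = np.zeros(n_sites, dtype=bool)
    sub = joins.loc[joins["mut_type"] == mutation_type, "site_index"]
    mask[np.unique(sub.to_numpy(int))] = True
    return mask


def bin_by_hmc_rel(sites: pd.DataFrame, joins: pd.DataFrame,
                   spec: BinSpec | None = None,
                   mutation_type: str = "C>T") -> BinTable:
    """Fraction of mutated sites per hmc_rel bin (a site counts as mutated
    when mutated in at least one sample)."""
    spec = spec or BinSpec()
    eligible = _eligible_mask(sites, spec)
    rel = sites["hmc_rel"].to_numpy(float)[eligible]
    idx, edges = assign_bins(rel, spec)
    mutated = _mutated_sites_mask(len(sites), joins, mutation_type)[eligible]
    table = _tally(idx, spec.n_bins, edges, mutated)
    table.spec = spec
    return table


@dataclass
class SlopeResult:
    slope: float
    intercept: float
    f_p_value: float
    n_bins: int


def slope_test(table: BinTable, weighted: bool = False) -> SlopeResult:
    """Least-squares regression of per-bin frequency on bin midpoint with
    an F-test of the zero-slope hypothesis.

    Unweighted by default (each populated bin contributes equally);
    ``weighted=True`` weights bins by site count.
    """
    pop = table.populated()
    if len(pop) < 3:
        raise ValueError("need >= 3 populated bins for the slope test")
    x = pop["midpoint"].to_numpy(float)
    y = pop["frequency"].to_numpy(float)
    X = sm.add_constant(x)
    if weighted:
        fit = sm.WLS(y, X, weights=pop["n_sites"].to_numpy(float)).fit()
    else:
        fit = sm.OLS(y, X).fit()
    return SlopeResult(slope=float(fit.params[1]), intercept=float(fit.params[0]),
                       f_p_value=float(fit.f_pvalue), n_bins=len(pop))


# ---------------------------------------------------------------------------
# 9x9 (5mC level x 5hmC level) grid
# ---------------------------------------------------------------------------

@dataclass
class Grid2DResult:
    n_sites: pd.DataFrame       # mc bin (rows) x hmc bin (cols)
    n_mutated: pd.DataFrame
    frequency: pd.DataFrame     # NaN where empty; structurally impossible cells too
    structural_missing: pd.DataFrame   # True where edge_lo sums >= 1
    top_row: BinTable           # unmethylated slice, binned by hmc level
    first_column: BinTable      # 5hmC-free slice, binned by mc level
    diagonal: BinTable          # fully modified (mod >= 0.90), binned by hmc level


def grid_2d(sites: pd.DataFrame, joins: pd.DataFrame, n_bins: int = 9,
            mutation_type: str = "C>T", fully_modified_floor: float = 0.90) -> Grid2DResult:
    """Mutation frequency over a (5mC level, 5hmC level) grid with the
    three diagnostic slices.

    Cells whose lower edges already sum to ≥ 1 cannot contain sites (mc +
    hmc = mod ≤ 1) and are flagged structurally missing.
    """
    mc = sites["mc_level"].to_numpy(float)
    hmc = sites["hmc_level"].to_numpy(float)
    mutated = _mutated_sites_mask(len(sites), joins, mutation_type)

    def bin_of(v):
        return np.minimum((np.asarray(v, float) * n_bins).astype(int), n_bins - 1)

    bi, bj = bin_of(mc), bin_of(hmc)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    n_sites = np.zeros((n_bins, n_bins), dtype=np.int64)
    n_mut = np.zeros((n_bins, n_bins), dtype=np.int64)
    np.add.at(n_sites, (bi, bj), 1)
    np.add.at(n_mut, (bi, bj), mutated.astype(np.int64))
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_sites > 0, n_mut / np.where(n_sites > 0, n_sites, 1), np.nan)
    structural = np.add.outer(edges[:-1], edges[:-1]) >= 1.0

    labels = [f"[{edges[k]:.3f},{edges[k + 1]:.3f})" for k in range(n_bins)]
    as_df = lambda a: pd.DataFrame(a, index=labels, columns=labels)

    spec = BinSpec(n_bins=n_bins)
    top_mask = bi == 0                       # essentially unmethylated sites
    top = _tally(bj[top_mask], n_bins, edges, mutated[top_mask])
    col_mask = bj == 0                       # essentially 5hmC-free sites
    col = _tally(bi[col_mask], n_bins, edges, mutated[col_mask])
    mod = sites["mod_level"].to_numpy(float)
    diag_mask = mod >= fully_modified_floor
    diag = _tally(bin_of(hmc[diag_mask]), n_bins, edges, mutated[diag_mask])
    for t in (top, col, diag):
        t.spec = spec

    return Grid2DResult(n_sites=as_df(n_sites), n_mutated=as_df(n_mut),
                        frequency=as_df(freq), structural_missing=as_df(structural),
                        top_row=top, first_column=col, diagonal=diag)
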