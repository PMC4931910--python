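"""Window-level mutation modeling: features, Poisson GLM, D² rankings,
cross-tissue prediction matrices, and smoothed genome tracks.

The genome is tiled into fixed-size windows (default 100 kb; the last,
partial window of each chromosome is kept with its true size).  Each
window gets modification, annotation and expression covariates plus a
CpG>T mutation count with an eligible-CpG exposure, and the Poisson GLM
core (:mod:`hydroxymut.glm`) measures how much deviance each predictor
set explains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .glm import GlmResult, fit_poisson_glm
from .io_formats import IntervalSet, merge_intervals

#: default predictor columns, in the order they appear in the feature table
PREDICTOR_COLUMNS = [
    "mean_hmc", "mean_mc", "mean_hmc_rel", "mean_mod", "mean_log_expression",
    "gene_density", "exon_density", "cpg_density", "modcpg_density", "cgi_density",
]


@dataclass
class WindowSpec:
    """Tiling of chromosomes into non-overlapping windows anchored at 0."""

    window_size_bp: int = 100_000
    chrom_sizes: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.window_size_bp < 1000:
            raise ValueError("window size below 1 kb is not supported")

    def windows(self) -> pd.DataFrame:
        rows = []
        for chrom in sorted(self.chrom_sizes):
            size = self.chrom_sizes[chrom]
            starts = np.arange(0, size, self.window_size_bp)
            ends = np.minimum(starts + self.window_size_bp, size)
            rows.extend(zip([chrom] * len(starts), starts, ends))
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def window_spec_from_sites(sites: pd.DataFrame, window_size_bp: int = 100_000,
                           chrom_sizes: dict | None = None) -> WindowSpec:
    """Build a spec covering all site coordinates when true chromosome
    sizes are not supplied."""
    if chrom_sizes is None:
        chrom_sizes = {c: int(g["pos"].max()) + 1 for c, g in sites.groupby("chrom")}
    return WindowSpec(window_size_bp=window_size_bp, chrom_sizes=dict(chrom_sizes))


def _coverage_per_window(windows: pd.DataFrame, intervals: IntervalSet,
                         spec: WindowSpec, values: dict | None = None):
    """Covered-bp (and optionally value-weighted bp) per window."""
    covered = np.zeros(len(windows))
    weighted = np.zeros(len(windows)) if values is not None else None
    win_index = {}
    for i, (chrom, g) in enumerate(windows.groupby("chrom")):
        win_index[chrom] = (g.index.to_numpy(), g["start"].to_numpy())
    w = spec.window_size_bp
    for _, row in intervals.df.iterrows():
        entry = win_index.get(row["chrom"])
        if entry is None:
            continue
        idxs, starts = entry
        first = int(row["start"]) // w
        last = (int(row["end"]) - 1) // w
        for k in range(first, min(last, len(idxs) - 1) + 1):
            lo = max(row["start"], starts[k])
            hi = min(row["end"], starts[k] + w)
            ov = max(hi - lo, 0)
            covered[idxs[k]] += ov
            if weighted is not None:
                weighted[idxs[k]] += ov * values.get(row.get("label", ""), 0.0)
    return covered, weighted


def build_window_table(sites: pd.DataFrame, joins: pd.DataFrame, catalogs,
                       genes: IntervalSet, exons: IntervalSet, cgi: IntervalSet,
                       expression_medians: pd.Series,
                       spec: WindowSpec, mod_floor: float = 0.10,
                       mutation_type: str = "C>T",
                       include_assays=("WGS",)) -> pd.DataFrame:
    """One feature row per genomic window.

    Modification means are taken over sites with mod level ≥ ``mod_floor``
    except ``mean_mod`` (raw BS signal over all sites).  The response is
    the summed mutation count of ``include_assays`` samples at the
    window's CpG sites, with exposure = eligible CpGs x number of included
    samples.  Windows without eligible CpGs are flagged ``excluded``.
    """
    windows = spec.windows()
    n_win = len(windows)
    w = spec.window_size_bp

    # map each site to its window row
    win_row = {}
    for chrom, g in windows.groupby("chrom"):
        win_row[chrom] = g.index.to_numpy()
    site_win = np.full(len(sites), -1, dtype=np.int64)
    for chrom, g in sites.groupby("chrom"):
        rows = win_row.get(chrom)
        if rows is None:
            continue
        k = (g["pos"].to_numpy() // w).astype(int)
        ok = k < len(rows)
        site_win[g.index.to_numpy()[ok]] = rows[k[ok]]

    mod = sites["mod_level"].to_numpy(float)
    eligible_mod = mod >= mod_floor

    def mean_by_window(values, mask):
        s = np.zeros(n_win)
        c = np.zeros(n_win)
        sel = mask & (site_win >= 0) & ~np.isnan(values)
        np.add.at(s, site_win[sel], values[sel])
        np.add.at(c, site_win[sel], 1.0)
        with np.errstate(invalid="ignore"):
            return np.where(c > 0, s / np.maximum(c, 1), np.nan)

    all_mask = np.ones(len(sites), dtype=bool)
    windows["mean_hmc"] = mean_by_window(sites["hmc_level"].to_numpy(float), eligible_mod)
    windows["mean_mc"] = mean_by_window(sites["mc_level"].to_numpy(float), eligible_mod)
    windows["mean_hmc_rel"] = mean_by_window(sites["hmc_rel"].to_numpy(float), eligible_mod)
    windows["mean_mod"] = mean_by_window(mod, all_mask)

    n_cpg = np.zeros(n_win)
    np.add.at(n_cpg, site_win[site_win >= 0], 1.0)
    n_modcpg = np.zeros(n_win)
    np.add.at(n_modcpg, site_win[(site_win >= 0) & eligible_mod], 1.0)
    sizes = (windows["end"] - windows["start"]).to_numpy(float)
    windows["cpg_density"] = n_cpg / sizes
    windows["modcpg_density"] = n_modcpg / sizes

    log_expr = {g: float(np.log1p(v)) for g, v in expression_medians.items()}
    gene_cov, gene_weighted = _coverage_per_window(
        windows, genes, spec, values=log_expr)
    windows["gene_density"] = gene_cov / sizes
    with np.errstate(invalid="ignore"):
        windows["mean_log_expression"] = np.where(
            gene_cov > 0, gene_weighted / np.maximum(gene_cov, 1), 0.0)
    exon_cov, _ = _coverage_per_window(windows, merge_intervals(exons), spec)
    windows["exon_density"] = exon_cov / sizes
    cgi_cov, _ = _coverage_per_window(windows, merge_intervals(cgi), spec)
    windows["cgi_density"] = cgi_cov / sizes

    included = {c.sample_id for c in catalogs if c.assay in set(include_assays)}
    n_samples = len(included)
    counts = np.zeros(n_win)
    sub = joins.loc[(joins["mut_type"] == mutation_type)
                    & joins["sample_id"].isin(included)]
    hit = site_win[sub["site_index"].to_numpy(int)]
    np.add.at(counts, hit[hit >= 0], 1.0)
    windows["n_mutations"] = counts.astype(np.int64)
    windows["eligible_cpg"] = n_cpg.astype(np.int64)
    windows["exposure"] = n_cpg * max(n_samples, 1)
    windows["excluded"] = n_cpg == 0
    return windows


def fit_glm(table: pd.DataFrame, predictors, response: str = "n_mutations",
            exposure: str = "exposure") -> GlmResult:
    """Poisson GLM of the window mutation count on the named predictors,
    with log-exposure offset; excluded windows are dropped."""
    fitting = table.loc[~table["excluded"]] if "excluded" in table.columns else table
    if len(fitting) < 10:
        raise ValueError("need >= 10 windows with eligible CpGs")
    X = fitting[list(predictors)].to_numpy(float)
    # rows with undefined modification means (no eligible sites) are dropped
    ok = np.isfinite(X).all(axis=1)
    fitting = fitting.loc[ok]
    X = X[ok]
    return fit_poisson_glm(fitting[response].to_numpy(float), X,
                           fitting[exposure].to_numpy(float),
                           predictor_names=list(predictors))


def rank_predictors(table: pd.DataFrame, predictors=None) -> pd.DataFrame:
    """Univariate D² ranking with cumulative nested models.

    Returns one row per predictor, sorted by univariate D² descending:
    d2_univariate, d2_cumulative (model with the top-k predictors),
    pearson_r and spearman_rho of the predictor against the per-window
    mutation frequency.
    """
    predictors = list(predictors) if predictors is not None else [
        p for p in PREDICTOR_COLUMNS if p in table.columns]
    if len(predictors) < 2:
        raise ValueError("need >= 2 predictors to rank")
    fitting = table.loc[~table["excluded"]]
    freq = fitting["n_mutations"] / fitting["exposure"]
    rows = []
    for p in predictors:
        d2 = fit_glm(table, [p]).d2
        ok = np.isfinite(fitting[p])
        rows.append((p, d2,
                     float(stats.pearsonr(fitting[p][ok], freq[ok]).statistic),
                     float(stats.spearmanr(fitting[p][ok], freq[ok]).statistic)))
    out = pd.DataFrame(rows, columns=["predictor", "d2_univariate",
                                      "pearson_r", "spearman_rho"])
    out = out.sort_values("d2_univariate", ascending=False).reset_index(drop=True)
    cumulative = []
    for k in range(1, len(out) + 1):
        cumulative.append(fit_glm(table, out["predictor"].iloc[:k].tolist()).d2)
    out["d2_cumulative"] = cumulative
    return out


def d2_by_window_size(sites, joins, catalogs, genes, exons, cgi,
                      expression_medians, window_sizes, chrom_sizes,
                      predictors=None, **kwargs) -> pd.DataFrame:
    """Univariate D² per predictor across a range of window sizes."""
    frames = []
    for size in window_sizes:
        spec = WindowSpec(window_size_bp=int(size), chrom_sizes=dict(chrom_sizes))
        table = build_window_table(sites, joins, catalogs, genes, exons, cgi,
                                   expression_medians, spec, **kwargs)
        preds = list(predictors) if predictors is not None else [
            p for p in PREDICTOR_COLUMNS if p in table.columns]
        for p in preds:
            frames.append((int(size), p, fit_glm(table, [p]).d2))
    return pd.DataFrame(frames, columns=["window_size_bp", "predictor", "d2"])


# ---------------------------------------------------------------------------
# cross-tissue prediction matrix
# ---------------------------------------------------------------------------

@dataclass
class CrossMapResult:
    d2: pd.DataFrame          # cancer types x tissue maps, raw D²
    z: pd.DataFrame           # per-row z-scores (NaN rows flagged)
    degenerate_rows: list


def cross_map_matrix(cancer_windows: dict, tissue_maps: pd.DataFrame) -> CrossMapResult:
    """D² of each tissue's window-level hmc_rel map predicting each cancer
    type's window CpG>T counts.

    ``cancer_windows`` maps cancer type → DataFrame with n_mutations and
    exposure columns on the same window grid as ``tissue_maps`` (one
    column per tissue).  Rows of the raw D² matrix are z-scored to remove
    cohort-size effects; zero-variance rows yield NaN z-scores and are
    listed in ``degenerate_rows``.
    """
    n_windows = len(tissue_maps)
    raw = {}
    for cancer, table in cancer_windows.items():
        if len(table) != n_windows:
            raise ValueError(f"window grid mismatch for cancer type {cancer!r}")
        row = {}
        for tissue in tissue_maps.columns:
            res = fit_poisson_glm(table["n_mutations"].to_numpy(float),
                                  tissue_maps[tissue].to_numpy(float),
                                  table["exposure"].to_numpy(float),
                                  predictor_names=[tissue])
            row[tissue] = res.d2
        raw[cancer] = row
    d2 = pd.DataFrame(raw).T[list(tissue_maps.columns)]
    means = d2.mean(axis=1)
    sds = d2.std(axis=1, ddof=0)
    degenerate = d2.index[sds == 0].tolist()
    z = d2.sub(means, axis=0).div(sds.replace(0, np.nan), axis=0)
    return CrossMapResult(d2=d2, z=z, degenerate_rows=degenerate)


# ---------------------------------------------------------------------------
# smoothed track export
# ---------------------------------------------------------------------------

@dataclass
class TrackSmoothingConfig:
    """Gaussian kernel of ``n`` window-units with standard deviation
    ``sigma`` (in windows), renormalised at chromosome edges."""

    n: int = 50
    sigma: float = 2.5
    zscore: bool = True

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.n < 1:
            raise ValueError("kernel length must be >= 1")

    def kernel(self) -> np.ndarray:
        x = np.arange(self.n) - (self.n - 1) / 2.0
        k = np.exp(-0.5 * (x / self.sigma) ** 2)
        return k / k.sum()


def gaussian_smooth(values: np.ndarray, cfg: TrackSmoothingConfig) -> np.ndarray:
    """Normalised Gaussian smoothing that renormalises at edges and
    around missing (NaN) entries, so a constant track stays constant."""
    v = np.asarray(values, float)
    k = cfg.kernel()
    finite = np.isfinite(v)
    filled = np.where(finite, v, 0.0)
    num = np.convolve(filled, k, mode="same")
    den = np.convolve(finite.astype(float), k, mode="same")
    with np.errstate(invalid="ignore"):
        out = np.where(den > 0, num / den, np.nan)
    out[~finite] = np.nan
    return out


@dataclass
class SmoothedTracks:
    per_chrom: dict           # chrom -> DataFrame of smoothed (z-scored) tracks
    correlations: dict        # chrom -> Pearson correlation matrix DataFrame
    unsmoothed_chroms: list


def export_smoothed_tracks(table: pd.DataFrame, cfg: TrackSmoothingConfig | None = None,
                           columns=None) -> SmoothedTracks:
    """Smoothed, optionally z-scored per-chromosome tracks plus their
    pairwise Pearson correlations.

    Tracks default to the mutation frequency and all predictor columns.
    Chromosomes with fewer windows than the kernel are exported
    unsmoothed with a warning.
    """
    cfg = cfg or TrackSmoothingConfig()
    table = table.copy()
    table["mutation_frequency"] = np.where(
        table["exposure"] > 0, table["n_mutations"] / table["exposure"], np.nan)
    columns = list(columns) if columns is not None else \
        ["mutation_frequency"] + [p for p in PREDICTOR_COLUMNS if p in table.columns]
    per_chrom, correlations, unsmoothed = {}, {}, []
    for chrom, g in table.groupby("chrom"):
        g = g.sort_values("start")
        out = g[["start", "end"]].copy()
        smooth_ok = len(g) >= cfg.n
        if not smooth_ok:
            unsmoothed.append(chrom)
            warnings.warn(f"{chrom}: fewer windows ({len(g)}) than kernel "
                          f"length {cfg.n}; exporting unsmoothed")
        for col in columns:
            track = g[col].to_numpy(float)
            if smooth_ok:
                track = gaussian_smooth(track, cfg)
            if cfg.zscore:
                sd = np.nanstd(track)
                track = (track - np.nanmean(track)) / sd if sd > 0 else \
                    np.full_like(track, np.nan)
            out[col] = track
        per_chrom[chrom] = out.reset_index(drop=True)
        correlations[chrom] = out[columns].corr(method="pearson")
    return SmoothedTracks(per_chrom=per_chrom, correlations=correlations,
                          unsmoothed_chroms=unsmoothed)
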