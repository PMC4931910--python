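"""Per-sample comparisons of mutation frequency between site classes.

This module carries the cohort-level statistics: per-sample mutated
fractions of 5mC-high vs 5hmC-high sites, paired Wilcoxon signed-rank
tests, threshold sweeps, expression stratification, the matched-pairing
control, the aligned ±2 kb mutation profile, the age correlation, and the
cross-tissue normalised-ratio correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import IntervalSet
from .site_model import ClassificationConfig, classify_sites

SITE_CLASSES = ("mc_high", "hmc_high")


# ---------------------------------------------------------------------------
# class fractions and the signed-rank comparison
# ---------------------------------------------------------------------------

def class_fractions(sites: pd.DataFrame, labels: pd.Series, joins: pd.DataFrame,
                    catalogs, mutation_type: str = "C>T",
                    stratum: IntervalSet | None = None,
                    exons: IntervalSet | None = None) -> pd.DataFrame:
    """Per sample x site class: eligible sites, mutated sites, fraction.

    ``joins`` is the output of :func:`site_model.join_mutations_to_sites`.
    ``stratum`` optionally restricts sites to an interval set (e.g. highly
    expressed gene bodies).  Whole-exome samples are restricted to
    ``exons`` (merged) when provided, since they only observe exonic
    sites.  Samples for which a class has zero eligible sites are flagged
    ``excluded`` and carry a NaN fraction.
    """
    chrom = sites["chrom"].to_numpy()
    pos = sites["pos"].to_numpy()
    in_stratum = stratum.contains(chrom, pos) if stratum is not None else \
        np.ones(len(sites), dtype=bool)
    in_exome = exons.contains(chrom, pos) if exons is not None else \
        np.ones(len(sites), dtype=bool)
    label_arr = labels.to_numpy()

    sub = joins.loc[joins["mut_type"] == mutation_type]
    mutated = sub.groupby("sample_id")["site_index"].agg(lambda s: set(s))

    rows = []
    for cat in catalogs:
        eligible = in_stratum.copy()
        if cat.assay == "WXS":
            eligible &= in_exome
        muts = mutated.get(cat.sample_id, set())
        for cls in SITE_CLASSES:
            cls_mask = eligible & (label_arr == cls)
            n_sites = int(cls_mask.sum())
            if n_sites == 0:
                rows.append((cat.sample_id, cls, 0, 0, np.nan, True))
                continue
            idx = set(np.flatnonzero(cls_mask))
            n_mut = len(idx & muts) if muts else 0
            rows.append((cat.sample_id, cls, n_sites, n_mut, n_mut / n_sites, False))
    return pd.DataFrame(rows, columns=["sample_id", "site_class", "n_sites",
                                       "n_mutated", "fraction", "excluded"])


@dataclass
class ComparisonResult:
    p_value: float
    reduction: float          # 1 − mean(hmc_high)/mean(mc_high) over samples
    mean_mc: float
    mean_hmc: float
    n_samples: int
    alternative: str
    degenerate: bool = False  # all per-sample differences were zero


def paired_signed_rank(differences, alternative: str = "two-sided") -> float:
    """Wilcoxon signed-rank p-value for paired differences.

    Zero differences are dropped; the exact null distribution is used for
    n ≤ 25 when ranks are untied, otherwise the normal approximation with
    continuity correction.
    """
    d = np.asarray(differences, float)
    d = d[d != 0]
    if len(d) == 0:
        return 1.0
    ties = len(np.unique(np.abs(d))) < len(d)
    if len(d) <= 25 and not ties:
        method = "exact"
        res = stats.wilcoxon(d, alternative=alternative, method=method)
    else:
        res = stats.wilcoxon(d, alternative=alternative, method="approx", correction=True)
    return float(res.pvalue)


def compare_classes(table: pd.DataFrame, alternative: str = "two-sided") -> ComparisonResult:
    """Paired signed-rank comparison of per-sample mutated fractions.

    ``alternative='greater'`` tests for elevated mc_high fractions (right
    tail), ``'less'`` the reverse.  The effect summary is the percent
    reduction of the (unweighted) mean 5hmC-high fraction relative to the
    mean 5mC-high fraction.
    """
    wide = table.loc[~table["excluded"]].pivot(
        index="sample_id", columns="site_class", values="fraction")
    if any(cls not in wide.columns for cls in SITE_CLASSES):
        raise ValueError("a site class has no eligible sites in any sample")
    wide = wide.dropna()
    if len(wide) < 6:
        raise ValueError(f"need >= 6 samples with both fractions, got {len(wide)}")
    d = (wide["mc_high"] - wide["hmc_high"]).to_numpy()
    degenerate = bool(np.all(d == 0))
    p = 1.0 if degenerate else paired_signed_rank(d, alternative)
    mean_mc = float(wide["mc_high"].mean())
    mean_hmc = float(wide["hmc_high"].mean())
    reduction = np.nan if mean_mc == 0 else 1.0 - mean_hmc / mean_mc
    return ComparisonResult(p_value=p, reduction=float(reduction), mean_mc=mean_mc,
                            mean_hmc=mean_hmc, n_samples=len(wide),
                            alternative=alternative, degenerate=degenerate)


def threshold_sweep(sites: pd.DataFrame, joins: pd.DataFrame, catalogs,
                    thresholds_mc, thresholds_hmc, mutation_type: str = "C>T",
                    mod_floor: float = 0.10, exons: IntervalSet | None = None):
    """Redo classification and the one-sided comparisons over a threshold grid.

    Returns ``(p_right, p_left)`` DataFrames indexed by threshold_5mC with
    threshold_5hmC columns: right tail = elevated mutation frequency in
    mc_high, left tail = elevated in hmc_high.  Cells with threshold_5mC ≥
    threshold_5hmC, or with an empty class, are NaN.
    """
    p_right = pd.DataFrame(np.nan, index=list(thresholds_mc), columns=list(thresholds_hmc))
    p_left = p_right.copy()
    for t_mc in thresholds_mc:
        for t_hmc in thresholds_hmc:
            if not t_mc < t_hmc:
                continue
            cfg = ClassificationConfig(mod_floor=mod_floor, threshold_5mC=t_mc,
                                       threshold_5hmC=t_hmc)
            labels = classify_sites(sites, cfg)
            table = class_fractions(sites, labels, joins, catalogs,
                                    mutation_type=mutation_type, exons=exons)
            try:
                p_right.loc[t_mc, t_hmc] = compare_classes(table, "greater").p_value
                p_left.loc[t_mc, t_hmc] = compare_classes(table, "less").p_value
            except ValueError:
                pass  # empty class in too many samples -> missing cell
    return p_right, p_left


# ---------------------------------------------------------------------------
# expression strata
# ---------------------------------------------------------------------------

def expression_strata(genes: IntervalSet, medians: pd.Series):
    """Split genes at the median of per-gene median expression.

    Genes are ordered by (median expression descending, gene id ascending —
    the deterministic tie rule) and the top half is the highly expressed
    stratum.  Returns ``(high, low)`` interval sets of gene bodies.
    """
    df = genes.df.copy()
    df["median_expression"] = df["label"].map(medians)
    if df["median_expression"].isna().any():
        missing = df.loc[df["median_expression"].isna(), "label"].tolist()[:3]
        raise ValueError(f"genes without expression values, e.g. {missing}")
    df = df.sort_values(["median_expression", "label"],
                        ascending=[False, True], kind="mergesort")
    n_high = len(df) // 2
    high = df.iloc[:n_high]
    low = df.iloc[n_high:]
    return (IntervalSet(high[["chrom", "start", "end", "label"]], name="high_expression"),
            IntervalSet(low[["chrom", "start", "end", "label"]], name="low_expression"))


# ---------------------------------------------------------------------------
# matched pairing
# ---------------------------------------------------------------------------

@dataclass
class PairedSites:
    """Greedy nearest-neighbour matching of 5hmC-high to 5mC-high sites."""

    pairs: pd.DataFrame       # hmc_index, mc_index, distance (mc pos − hmc pos)
    seed: int
    n_unpaired_hmc: int

    def __len__(self):
        return len(self.pairs)


class _NeighbourFinder:
    """Nearest-alive lookup over a sorted position array, with removal.

    Two path-compressed pointer arrays give amortised near-constant
    "nearest alive slot to the left/right" queries after removals.
    """

    def __init__(self, positions, original_indices):
        self.pos = positions
        self.idx = original_indices
        n = len(positions)
        self._l = np.arange(n)        # alive slot s has _l[s] == s; removed points left
        self._r = np.arange(n)        # likewise for rightward search

    def _find_left(self, i):
        path = []
        while i >= 0 and self._l[i] != i:
            path.append(i)
            i = self._l[i]
        for p in path:
            self._l[p] = i
        return i                      # -1 means no alive slot to the left

    def _find_right(self, i):
        n = len(self.pos)
        path = []
        while i < n and self._r[i] != i:
            path.append(i)
            i = self._r[i]
        for p in path:
            self._r[p] = i
        return i                      # n means no alive slot to the right

    def nearest(self, x):
        """Nearest alive position to x; ties resolve to the smaller
        coordinate.  Returns (slot, original_index, signed distance) or
        None when no alive slot remains."""
        i = int(np.searchsorted(self.pos, x))
        li = self._find_left(i - 1)
        ri = self._find_right(i)
        left_ok = li >= 0
        right_ok = ri < len(self.pos)
        if not left_ok and not right_ok:
            return None
        if left_ok and right_ok:
            slot = li if (x - self.pos[li]) <= (self.pos[ri] - x) else ri
        else:
            slot = li if left_ok else ri
        return slot, int(self.idx[slot]), int(self.pos[slot] - x)

    def remove(self, slot):
        self._l[slot] = slot - 1
        self._r[slot] = slot + 1 if slot + 1 < len(self.pos) else len(self.pos)


def pair_sites(sites: pd.DataFrame, labels: pd.Series,
               exons: IntervalSet | None, seed: int = 0) -> PairedSites:
    """Pair each 5hmC-high site with its nearest unused 5mC-high site.

    Sites are visited in an order shuffled by ``seed``; a pair must share
    chromosome, exon status (both inside or both outside merged exons) and
    sequence context class (CG/CHG/CHH).  Equidistant candidates resolve
    to the smaller coordinate.  5hmC-high sites with no eligible partner
    left are dropped and counted.
    """
    label_arr = labels.to_numpy()
    hmc_idx = np.flatnonzero(label_arr == "hmc_high")
    mc_idx = np.flatnonzero(label_arr == "mc_high")
    if len(mc_idx) == 0:
        raise ValueError("no mc_high sites available for pairing")

    chrom = sites["chrom"].to_numpy()
    pos = sites["pos"].to_numpy()
    context = sites["context"].to_numpy()
    exonic = exons.contains(chrom, pos) if exons is not None else \
        np.zeros(len(sites), dtype=bool)

    finders = {}
    for j in mc_idx:
        key = (chrom[j], bool(exonic[j]), context[j])
        finders.setdefault(key, []).append(j)
    for key, members in finders.items():
        members = np.asarray(members)
        order = np.argsort(pos[members], kind="mergesort")
        members = members[order]
        finders[key] = _NeighbourFinder(pos[members].astype(np.int64), members)

    rng = np.random.default_rng(seed)
    visit = rng.permutation(hmc_idx)
    rows = []
    n_unpaired = 0
    for i in visit:
        key = (chrom[i], bool(exonic[i]), context[i])
        finder = finders.get(key)
        hit = finder.nearest(pos[i]) if finder is not None else None
        if hit is None:
            n_unpaired += 1
            continue
        slot, j, dist = hit
        finder.remove(slot)
        rows.append((int(i), j, dist))
    pairs = pd.DataFrame(rows, columns=["hmc_index", "mc_index", "distance"])
    return PairedSites(pairs=pairs, seed=seed, n_unpaired_hmc=n_unpaired)


def paired_comparison(pairs: PairedSites, joins: pd.DataFrame, catalogs,
                      mutation_type: str = "C>T"):
    """Per-sample (mutated mc-in-pairs − mutated hmc-in-pairs) count
    differences, with a two-sided signed-rank p.

    Returns ``(DataFrame[sample_id, n_mut_mc, n_mut_hmc, diff], p_value)``.
    """
    mc_set = set(pairs.pairs["mc_index"])
    hmc_set = set(pairs.pairs["hmc_index"])
    sub = joins.loc[joins["mut_type"] == mutation_type]
    by_sample = {sid: set(g["site_index"]) for sid, g in sub.groupby("sample_id")}
    rows = []
    for cat in catalogs:
        hit = by_sample.get(cat.sample_id, set())
        n_mc = len(hit & mc_set)
        n_hmc = len(hit & hmc_set)
        rows.append((cat.sample_id, n_mc, n_hmc, n_mc - n_hmc))
    df = pd.DataFrame(rows, columns=["sample_id", "n_mut_mc", "n_mut_hmc", "diff"])
    d = df["diff"].to_numpy(float)
    p = 1.0 if np.all(d == 0) else paired_signed_rank(d, "two-sided")
    return df, float(p)


# ---------------------------------------------------------------------------
# aligned profile around isolated modified sites
# ---------------------------------------------------------------------------

@dataclass
class AlignedProfile:
    profile: pd.DataFrame     # site_class, offset_lo, offset_hi, n_mutations, frequency
    anchors: pd.DataFrame     # site_class, n_anchors, anchor_mutation_frequency
    radius_bp: int
    bin_width_bp: int


def aligned_profile(sites: pd.DataFrame, labels: pd.Series, joins: pd.DataFrame,
                    catalogs, radius_bp: int = 2000, bin_width_bp: int = 100,
                    mod_floor: float = 0.10,
                    mutation_type: str = "C>T") -> AlignedProfile:
    """Mutation frequency around isolated modified sites.

    Anchors are modified sites (mod level ≥ ``mod_floor``) of class
    mc_high / hmc_high with no other modified site within ``radius_bp``.
    For each anchor class and offset bin the frequency is mutations per
    base pair per anchor per sample; the anchor position itself is
    reported separately as the fraction of (anchor, sample) pairs mutated.
    """
    n_samples = len(catalogs)
    modified = sites["mod_level"].to_numpy() >= mod_floor
    pos = sites["pos"].to_numpy()
    chrom = sites["chrom"].to_numpy()
    label_arr = labels.to_numpy()

    isolated = np.zeros(len(sites), dtype=bool)
    for c in np.unique(chrom):
        m = np.flatnonzero((chrom == c) & modified)
        if len(m) == 0:
            continue
        p = np.sort(pos[m])
        order = np.argsort(pos[m], kind="mergesort")
        gap_left = np.diff(p, prepend=p[0] - 2 * radius_bp - 1)
        gap_right = np.diff(p, append=p[-1] + 2 * radius_bp + 1)
        iso_sorted = (gap_left > radius_bp) & (gap_right > radius_bp)
        isolated[m[order]] = iso_sorted
    anchor_mask = isolated & np.isin(label_arr, SITE_CLASSES)
    if not anchor_mask.any():
        raise ValueError("no isolated modified anchors found")

    # mutation positions of the requested type, per chromosome, over all samples
    mut_pos = {}
    for cat in catalogs:
        df = cat.mutations
        if len(df) == 0:
            continue
        sel = df.loc[(df["pyr_ref"] + ">" + df["pyr_alt"]) == mutation_type]
        for c, g in sel.groupby("chrom"):
            mut_pos.setdefault(c, []).append(g["pos"].to_numpy())
    mut_pos = {c: np.sort(np.concatenate(v)) for c, v in mut_pos.items()}

    edges = np.arange(-radius_bp, radius_bp + bin_width_bp, bin_width_bp)
    n_bins = len(edges) - 1
    counts = {cls: np.zeros(n_bins, dtype=np.int64) for cls in SITE_CLASSES}
    n_anchors = {cls: 0 for cls in SITE_CLASSES}

    sub = joins.loc[joins["mut_type"] == mutation_type]
    anchor_events = sub.groupby("site_index").size()
    anchor_freq = {}
    for cls in SITE_CLASSES:
        cls_anchor = np.flatnonzero(anchor_mask & (label_arr == cls))
        n_anchors[cls] = len(cls_anchor)
        events = int(anchor_events.reindex(cls_anchor).fillna(0).sum())
        anchor_freq[cls] = events / (len(cls_anchor) * n_samples) if len(cls_anchor) else np.nan
        for j in cls_anchor:
            mp = mut_pos.get(chrom[j])
            if mp is None:
                continue
            lo = np.searchsorted(mp, pos[j] - radius_bp)
            hi = np.searchsorted(mp, pos[j] + radius_bp, side="right")
            offs = mp[lo:hi] - pos[j]
            offs = offs[offs != 0]  # anchor position reported separately
            if len(offs):
                counts[cls] += np.histogram(offs, bins=edges)[0]

    rows = []
    for cls in SITE_CLASSES:
        denom = n_anchors[cls] * bin_width_bp * n_samples
        for b in range(n_bins):
            freq = counts[cls][b] / denom if denom else np.nan
            rows.append((cls, int(edges[b]), int(edges[b + 1]),
                         int(counts[cls][b]), freq))
    profile = pd.DataFrame(rows, columns=["site_class", "offset_lo", "offset_hi",
                                          "n_mutations", "frequency"])
    anchors = pd.DataFrame({
        "site_class": list(SITE_CLASSES),
        "n_anchors": [n_anchors[c] for c in SITE_CLASSES],
        "anchor_mutation_frequency": [anchor_freq[c] for c in SITE_CLASSES],
    })
    return AlignedProfile(profile=profile, anchors=anchors,
                          radius_bp=radius_bp, bin_width_bp=bin_width_bp)


# ---------------------------------------------------------------------------
# age correlation
# ---------------------------------------------------------------------------

@dataclass
class AgeCorrelationResult:
    per_class: pd.DataFrame   # site_class, pearson_r, slope, slope_se, n
    slope_difference_p: float


def age_correlation(catalogs, joins: pd.DataFrame, labels: pd.Series,
                    mutation_type: str = "C>T") -> AgeCorrelationResult:
    """Regress per-patient mutation counts in each site class on age.

    Returns Pearson r, the least-squares slope with standard error per
    class, and the p-value of the age x class interaction (test for a
    difference in slopes).
    """
    import statsmodels.api as sm

    aged = [c for c in catalogs if c.age_years is not None]
    if len(aged) < 10:
        raise ValueError("need >= 10 samples with age")
    ages = np.array([c.age_years for c in aged], float)
    if np.ptp(ages) == 0:
        raise ValueError("zero age variance")

    label_arr = labels.to_numpy()
    sub = joins.loc[joins["mut_type"] == mutation_type]
    counts_by_sample = {
        sid: g["site_index"].to_numpy() for sid, g in sub.groupby("sample_id")}

    rows, long = [], []
    for cls in SITE_CLASSES:
        cls_sites = set(np.flatnonzero(label_arr == cls))
        y = np.array([
            len([s for s in counts_by_sample.get(c.sample_id, ()) if s in cls_sites])
            for c in aged], float)
        r = float(stats.pearsonr(ages, y).statistic) if y.std() > 0 else 0.0
        X = sm.add_constant(ages)
        fit = sm.OLS(y, X).fit()
        rows.append((cls, r, float(fit.params[1]), float(fit.bse[1]), len(y)))
        long.extend((a, yy, cls) for a, yy in zip(ages, y))
    per_class = pd.DataFrame(rows, columns=["site_class", "pearson_r", "slope",
                                            "slope_se", "n"])
    ld = pd.DataFrame(long, columns=["age", "count", "site_class"])
    ld["is_mc"] = (ld["site_class"] == "mc_high").astype(float)
    X = sm.add_constant(np.column_stack([
        ld["age"], ld["is_mc"], ld["age"] * ld["is_mc"]]))
    fit = sm.OLS(ld["count"].to_numpy(float), X).fit()
    return AgeCorrelationResult(per_class=per_class,
                                slope_difference_p=float(fit.pvalues[3]))


# ---------------------------------------------------------------------------
# cross-tissue normalised ratio
# ---------------------------------------------------------------------------

@dataclass
class TissueRatioResult:
    table: pd.DataFrame       # tissue, ratio, bulk_hmc
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    dropped: list = field(default_factory=list)


def tissue_ratio_correlation(table: pd.DataFrame, exclude=()) -> TissueRatioResult:
    """Correlate the normalised mutation-frequency ratio with bulk 5hmC.

    ``table`` needs columns tissue, freq_modified, freq_unmodified,
    bulk_hmc.  The ratio freq_modified / freq_unmodified removes
    cancer-type-specific overall mutability; tissues with a zero
    denominator are dropped with a warning, and ``exclude`` names tissues
    to leave out (e.g. smoking-dominated ones).
    """
    df = table.loc[~table["tissue"].isin(set(exclude))].copy()
    dropped = df.loc[df["freq_unmodified"] <= 0, "tissue"].tolist()
    df = df.loc[df["freq_unmodified"] > 0]
    if len(df) < 4:
        raise ValueError("need >= 4 tissues with nonzero unmodified frequency")
    df["ratio"] = df["freq_modified"] / df["freq_unmodified"]
    if df["ratio"].nunique() == 1 or df["bulk_hmc"].nunique() == 1:
        # constant input: correlation undefined, reported as NaN
        pr_r = pr_p = sr_r = sr_p = float("nan")
    else:
        pr = stats.pearsonr(df["ratio"], df["bulk_hmc"])
        sr = stats.spearmanr(df["ratio"], df["bulk_hmc"])
        pr_r, pr_p = float(pr.statistic), float(pr.pvalue)
        sr_r, sr_p = float(sr.statistic), float(sr.pvalue)
    return TissueRatioResult(
        table=df[["tissue", "ratio", "bulk_hmc"]].reset_index(drop=True),
        pearson_r=pr_r, pearson_p=pr_p, spearman_rho=sr_r, spearman_p=sr_p,
        dropped=dropped)
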