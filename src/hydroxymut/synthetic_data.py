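"""Synthetic cohorts with known ground truth.

The generator emulates the statistical structure the downstream analyses
assume, without any external data:

* per-CpG true modification state: mod level ~ Beta (mostly-high, as in
  somatic tissue), and the hydroxymethylated share hmc_rel from a mixture
  of a point mass at 0 and a Beta component, so that both the
  predominantly-methylated and predominantly-hydroxymethylated site
  classes are populated;
* observed BS/TAB read counts drawn binomially from the true levels at
  Poisson-distributed depths, so level estimates carry realistic noise;
* regional structure: genes with exons, CpG islands and expression, and a
  smoothly varying window-level field modulating the local mean hmc_rel,
  giving window features genuine spatial autocorrelation;
* patient mutation catalogs in which each CpG mutates C>T with probability
  baseline x (1 + rr_mc * mc_level + rr_hmc * hmc_level); the default
  relative risks make methylated sites about twice as mutable as
  hydroxymethylated ones, with 5hmC itself neutral (its apparent
  protection comes from displacing 5mC), plus low-rate background
  mutations at non-CpG cytosines and thymines for the gene-level
  response-definition chain.

Everything is driven by one ``numpy`` Generator seeded from the config, so
a fixed seed reproduces the cohort byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import io_formats
from .io_formats import IntervalSet
from .site_model import (ClassificationConfig, SampleCatalog, annotate_catalog,
                         compute_levels_arrays)

DEFAULT_SEED = 17082


@dataclass
class CohortSimConfig:
    """Study conditions for one simulated cohort (defaults documented in
    docs/methods.md)."""

    seed: int = DEFAULT_SEED
    n_chromosomes: int = 2
    chrom_length_bp: int = 5_000_000
    cpg_density: float = 0.01                 # CpG sites per bp
    n_patients: int = 100
    fraction_wxs: float = 0.0                 # remainder are WGS
    cancer_type: str = "SYNTH"
    # mutation model
    baseline_mut_prob: float = 5e-4           # per CpG site per patient
    relative_risk_mc: float = 6.0             # multiplier per unit mc_level
    relative_risk_hmc: float = 0.0            # multiplier per unit hmc_level
    background_c_mut_prob: float = 1e-4       # exonic non-CpG C pairs, per patient
    background_t_mut_prob: float = 1e-4       # exonic T pairs, per patient
    # sequencing depth
    bs_depth_mean: float = 30.0
    tab_depth_mean: float = 25.0
    # true-level priors
    mod_alpha: float = 5.0
    mod_beta: float = 1.5
    hmc_rel_zero_weight: float = 0.30         # point mass at hmc_rel = 0
    hmc_rel_alpha: float = 1.5
    hmc_rel_beta: float = 2.5
    hmc_concentration: float = 4.0            # Beta concentration at modulated mean
    hmc_spatial_amp: float = 0.15             # window-level modulation of mean hmc_rel
    lattice_window_bp: int = 100_000
    # annotations / expression
    gene_density: float = 0.40                # fraction of genome inside genes
    mean_gene_length_bp: int = 40_000
    exon_fraction: float = 0.30               # of gene length
    exons_per_gene: int = 5
    cgi_per_mbp: float = 8.0
    gc_fraction: float = 0.42
    expression_log_mean: float = 1.0
    expression_log_sd: float = 1.2
    n_expression_samples: int = 5
    # age model (used by simulate_age_effect)
    age_min: float = 20.0
    age_max: float = 80.0

    def __post_init__(self):
        if not 0 <= self.baseline_mut_prob <= 1:
            raise ValueError("baseline_mut_prob must be a probability")
        if self.relative_risk_mc < 0 or self.relative_risk_hmc < 0:
            raise ValueError("relative risks must be >= 0")


@dataclass
class GroundTruth:
    """What the generator knows that the pipeline must rediscover."""

    config: CohortSimConfig
    site_truth: pd.DataFrame          # true_mod, true_hmc_rel, true_mc, true_hmc, mut_prob, true_class
    class_summary: pd.DataFrame       # per class: n_sites, n_mut_events, rate, and the realized reduction
    gene_composition: pd.DataFrame    # per gene: exonic site counts by kind
    injected: dict = field(default_factory=dict)

    @property
    def realized_reduction(self) -> float:
        """1 − rate(hmc_high)/rate(mc_high) over the realized cohort."""
        s = self.class_summary.set_index("site_class")["rate"]
        return float(1.0 - s["hmc_high"] / s["mc_high"])


@dataclass
class SimulatedCohort:
    sites: pd.DataFrame
    catalogs: list
    genes: IntervalSet
    exons: IntervalSet
    cgi: IntervalSet
    expression_table: pd.DataFrame    # gene x sample FPKM-like
    truth: GroundTruth

    @property
    def expression_medians(self) -> pd.Series:
        return self.expression_table.median(axis=1).rename("median_expression")


# ---------------------------------------------------------------------------
# pieces
# ---------------------------------------------------------------------------

def _smooth_field(n: int, rng, half_width: int = 5) -> np.ndarray:
    """Standardised spatially autocorrelated field on n lattice points."""
    noise = rng.standard_normal(n + 2 * half_width)
    kernel = np.exp(-0.5 * (np.arange(-half_width, half_width + 1) / (half_width / 2)) ** 2)
    kernel /= kernel.sum()
    sm = np.convolve(noise, kernel, mode="valid")
    sm = sm[:n]
    sd = sm.std()
    return (sm - sm.mean()) / sd if sd > 0 else np.zeros(n)


def _draw_sites(cfg: CohortSimConfig, rng):
    chroms, positions, strands = [], [], []
    fields = {}
    for c in range(cfg.n_chromosomes):
        name = f"chr{c + 1}"
        n = rng.poisson(cfg.chrom_length_bp * cfg.cpg_density)
        pos = np.unique(rng.integers(1, cfg.chrom_length_bp - 1, size=n))
        chroms.append(np.repeat(name, len(pos)))
        positions.append(pos)
        strands.append(np.where(rng.random(len(pos)) < 0.5, "+", "-"))
        n_windows = max(int(np.ceil(cfg.chrom_length_bp / cfg.lattice_window_bp)), 1)
        fields[name] = _smooth_field(n_windows, rng)
    sites = pd.DataFrame({
        "chrom": np.concatenate(chroms),
        "pos": np.concatenate(positions).astype(np.int64),
        "strand": np.concatenate(strands),
        "context": "CG",
    })
    return sites, fields


def _true_levels(cfg: CohortSimConfig, sites: pd.DataFrame, fields, rng):
    n = len(sites)
    true_mod = rng.beta(cfg.mod_alpha, cfg.mod_beta, size=n)
    base_mean = cfg.hmc_rel_alpha / (cfg.hmc_rel_alpha + cfg.hmc_rel_beta)
    local_mean = np.empty(n)
    for chrom, sub in sites.groupby("chrom", sort=False):
        f = fields[chrom]
        centers = (np.arange(len(f)) + 0.5) * cfg.lattice_window_bp
        u = np.interp(sub["pos"].to_numpy(float), centers, f)
        local_mean[sub.index.to_numpy()] = np.clip(
            base_mean + cfg.hmc_spatial_amp * u, 0.02, 0.98)
    k = cfg.hmc_concentration
    rel = rng.beta(local_mean * k, (1 - local_mean) * k)
    rel[rng.random(n) < cfg.hmc_rel_zero_weight] = 0.0
    true_hmc = rel * true_mod
    true_mc = true_mod - true_hmc
    return true_mod, rel, true_mc, true_hmc


def _observe_reads(cfg: CohortSimConfig, true_mod, true_hmc, rng):
    n = len(true_mod)
    bs_total = np.maximum(rng.poisson(cfg.bs_depth_mean, size=n), 1)
    tab_total = np.maximum(rng.poisson(cfg.tab_depth_mean, size=n), 1)
    bs_unconv = rng.binomial(bs_total, true_mod)
    tab_unconv = rng.binomial(tab_total, true_hmc)
    return bs_total, bs_unconv, tab_total, tab_unconv


def _make_annotations(cfg: CohortSimConfig, rng):
    genes, exons, cgis = [], [], []
    gene_id = 0
    for c in range(cfg.n_chromosomes):
        chrom = f"chr{c + 1}"
        covered = 0
        cursor = int(rng.integers(0, cfg.mean_gene_length_bp))
        target = cfg.gene_density * cfg.chrom_length_bp
        while covered < target and cursor < cfg.chrom_length_bp - 2000:
            length = int(np.clip(rng.exponential(cfg.mean_gene_length_bp), 2_000,
                                 cfg.chrom_length_bp // 10))
            end = min(cursor + length, cfg.chrom_length_bp)
            gid = f"G{gene_id:05d}"
            genes.append((chrom, cursor, end, gid))
            # exons: equal-length blocks at random offsets inside the gene
            exon_len = max(int((end - cursor) * cfg.exon_fraction / cfg.exons_per_gene), 50)
            starts = np.sort(rng.integers(cursor, max(end - exon_len, cursor + 1),
                                          size=cfg.exons_per_gene))
            for s in starts:
                exons.append((chrom, int(s), int(min(s + exon_len, end)), gid))
            gene_id += 1
            covered += end - cursor
            cursor = end + int(rng.exponential(
                cfg.mean_gene_length_bp * (1 - cfg.gene_density) / cfg.gene_density))
        n_cgi = rng.poisson(cfg.cgi_per_mbp * cfg.chrom_length_bp / 1e6)
        for _ in range(n_cgi):
            s = int(rng.integers(0, cfg.chrom_length_bp - 2000))
            cgis.append((chrom, s, s + int(rng.integers(500, 2000)), ""))
    cols = ["chrom", "start", "end", "label"]
    return (IntervalSet(pd.DataFrame(genes, columns=cols), name="genes"),
            IntervalSet(pd.DataFrame(exons, columns=cols), name="exons"),
            IntervalSet(pd.DataFrame(cgis, columns=cols), name="cgi"))


def _make_expression(cfg: CohortSimConfig, gene_ids, rng) -> pd.DataFrame:
    base = rng.lognormal(cfg.expression_log_mean, cfg.expression_log_sd, size=len(gene_ids))
    noise = rng.lognormal(0.0, 0.1, size=(len(gene_ids), cfg.n_expression_samples))
    table = pd.DataFrame(base[:, None] * noise, index=pd.Index(gene_ids, name="gene_id"),
                         columns=[f"S{i + 1}" for i in range(cfg.n_expression_samples)])
    return table


def _cpg_trinucleotide(strand, rng):
    """Plus-strand trinucleotide centred on the mutated base of a CpG."""
    flank = "ACGT"[rng.integers(0, 4)]
    return flank + "CG" if strand == "+" else "CG" + flank


def _site_mutation_prob(cfg: CohortSimConfig, true_mc, true_hmc):
    p = cfg.baseline_mut_prob * (
        1.0 + cfg.relative_risk_mc * true_mc + cfg.relative_risk_hmc * true_hmc)
    return np.clip(p, 0.0, 0.999)


def _background_records(cfg, exons_merged, comp_totals, chrom_lengths, rng,
                        exon_lookup):
    """Low-rate background SNVs at exonic non-CpG C pairs and T pairs."""
    rows = []
    n_c, n_t = comp_totals
    for ref_pool, alt_pool, rate, n_avail in (
            ("C", "AGT", cfg.background_c_mut_prob, n_c),
            ("T", "ACG", cfg.background_t_mut_prob, n_t)):
        k = rng.poisson(n_avail * rate)
        for _ in range(k):
            chrom, pos = _random_exonic_position(exon_lookup, rng)
            pyr = ref_pool
            alt = alt_pool[rng.integers(0, len(alt_pool))]
            if rng.random() < 0.5:   # pyrimidine on the minus strand
                ref_plus = {"C": "G", "T": "A"}[pyr]
                alt_plus = {"A": "T", "C": "G", "G": "C", "T": "A"}[alt]
            else:
                ref_plus, alt_plus = pyr, alt
            left = "ACGT"[rng.integers(0, 4)]
            right = "ACGT"[rng.integers(0, 4)]
            rows.append((chrom, pos, ref_plus, alt_plus, left + ref_plus + right))
    return rows


def _random_exonic_position(exon_lookup, rng):
    chroms, starts, lengths, cumlen = exon_lookup
    total = cumlen[-1]
    r = rng.integers(0, total)
    i = int(np.searchsorted(cumlen, r, side="right"))
    offset = r - (cumlen[i - 1] if i else 0)
    return chroms[i], int(starts[i] + offset)


def simulate_cohort(cfg: CohortSimConfig | None = None) -> SimulatedCohort:
    """Generate one full synthetic cohort (sites, catalogs, annotations,
    expression, and a ground-truth ledger)."""
    cfg = cfg or CohortSimConfig()
    rng = np.random.default_rng(cfg.seed)

    sites, fields = _draw_sites(cfg, rng)
    true_mod, true_rel, true_mc, true_hmc = _true_levels(cfg, sites, fields, rng)
    bs_total, bs_unconv, tab_total, tab_unconv = _observe_reads(cfg, true_mod, true_hmc, rng)
    sites["bs_total"] = bs_total
    sites["bs_unconverted"] = bs_unconv
    sites["tab_total"] = tab_total
    sites["tab_unconverted"] = tab_unconv
    mod, hmc, mc, rel = compute_levels_arrays(bs_unconv, bs_total, tab_unconv, tab_total)
    sites["mod_level"], sites["hmc_level"] = mod, hmc
    sites["mc_level"], sites["hmc_rel"] = mc, rel

    genes, exons, cgi = _make_annotations(cfg, rng)
    expression = _make_expression(cfg, genes.df["label"].tolist(), rng)
    exons_merged = io_formats.merge_intervals(exons)

    p_site = _site_mutation_prob(cfg, true_mc, true_hmc)
    if p_site.sum() > len(sites):
        raise ValueError("expected mutations per patient exceed the number of sites")

    # gene-wise exonic site composition (denominators for the response kinds)
    comp = _gene_composition(cfg, genes, exons, sites, true_mod, rng)
    ex = exons_merged.df
    exon_lookup = (ex["chrom"].tolist(), ex["start"].to_numpy(),
                   (ex["end"] - ex["start"]).to_numpy(),
                   np.cumsum((ex["end"] - ex["start"]).to_numpy()))
    bg_totals = (int(comp["n_c"].sum()), int(comp["n_t"].sum()))

    site_exonic = exons_merged.contains(sites["chrom"].to_numpy(), sites["pos"].to_numpy())
    n_wxs = int(round(cfg.fraction_wxs * cfg.n_patients))
    assays = np.array(["WXS"] * n_wxs + ["WGS"] * (cfg.n_patients - n_wxs))

    catalogs = []
    n_events = np.zeros(len(sites), dtype=np.int64)
    chrom_arr = sites["chrom"].to_numpy()
    pos_arr = sites["pos"].to_numpy()
    strand_arr = sites["strand"].to_numpy()
    for i in range(cfg.n_patients):
        hit = np.flatnonzero(rng.random(len(sites)) < p_site)
        if assays[i] == "WXS":
            hit = hit[site_exonic[hit]]
        n_events[hit] += 1
        rows = []
        for j in hit:
            strand = strand_arr[j]
            tri = _cpg_trinucleotide(strand, rng)
            ref, alt = ("C", "T") if strand == "+" else ("G", "A")
            rows.append((chrom_arr[j], int(pos_arr[j]), ref, alt, tri))
        rows.extend(_background_records(cfg, exons_merged, bg_totals,
                                        None, rng, exon_lookup))
        muts = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "trinucleotide"])
        cat = SampleCatalog(sample_id=f"P{i + 1:04d}", cancer_type=cfg.cancer_type,
                            assay=assays[i], mutations=muts)
        annotate_catalog(cat)
        catalogs.append(cat)

    truth = _build_truth(cfg, sites, true_mod, true_rel, true_mc, true_hmc,
                         p_site, n_events, comp)
    return SimulatedCohort(sites=sites, catalogs=catalogs, genes=genes, exons=exons,
                           cgi=cgi, expression_table=expression, truth=truth)


def _gene_composition(cfg, genes, exons, sites, true_mod, rng):
    """Per-gene exonic site counts: all base pairs, C pairs, T pairs, CpG
    sites, and modified-CpG sites (true mod level above the 10% floor)."""
    rows = []
    site_chrom = sites["chrom"].to_numpy()
    site_pos = sites["pos"].to_numpy()
    modified = true_mod > 0.10
    for gid, sub in exons.df.groupby("label", sort=True):
        merged = io_formats.merge_intervals(IntervalSet(sub[["chrom", "start", "end"]]
                                                        .assign(label="")))
        n_all = merged.total_bases()
        n_c = int(rng.binomial(n_all, cfg.gc_fraction))
        inside = merged.contains(site_chrom, site_pos)
        n_cpg = int(inside.sum())
        n_modc = int((inside & modified).sum())
        # CpG cytosines are themselves C pairs; keep counts consistent
        n_c = max(n_c, n_cpg)
        rows.append((gid, n_all, n_c, n_all - n_c, n_cpg, n_modc))
    return pd.DataFrame(rows, columns=["gene_id", "n_all", "n_c", "n_t", "n_cpg", "n_modc"])


def _build_truth(cfg, sites, true_mod, true_rel, true_mc, true_hmc, p_site,
                 n_events, comp, injected=None):
    site_truth = pd.DataFrame({
        "true_mod": true_mod, "true_hmc_rel": true_rel,
        "true_mc": true_mc, "true_hmc": true_hmc,
        "mut_prob": p_site, "n_mut_events": n_events,
    }, index=sites.index)
    labels = np.full(len(sites), "neither", dtype=object)
    ccfg = ClassificationConfig()
    eligible = true_mod > ccfg.mod_floor
    labels[eligible & (true_rel <= ccfg.threshold_5mC)] = "mc_high"
    labels[eligible & (true_rel >= ccfg.threshold_5hmC)] = "hmc_high"
    site_truth["true_class"] = labels
    rows = []
    for cls in ("mc_high", "hmc_high", "neither"):
        m = labels == cls
        n_sites = int(m.sum())
        events = int(n_events[m].sum())
        rate = events / (n_sites * cfg.n_patients) if n_sites else np.nan
        rows.append((cls, n_sites, events, rate))
    summary = pd.DataFrame(rows, columns=["site_class", "n_sites", "n_mut_events", "rate"])
    return GroundTruth(config=cfg, site_truth=site_truth, class_summary=summary,
                       gene_composition=comp, injected=injected or {})


# ---------------------------------------------------------------------------
# age effect
# ---------------------------------------------------------------------------

def simulate_age_effect(cfg: CohortSimConfig | None = None,
                        slope_mc: float = 2e-5,
                        slope_hmc: float = 5e-6) -> SimulatedCohort:
    """Cohort whose per-site mutation probability grows linearly with age:
    p_i(age) = baseline + (slope_mc * mc_i + slope_hmc * hmc_i) * age.

    Ages are uniform on [age_min, age_max].  The ledger records the
    injected slopes and each patient's age.
    """
    if slope_mc < 0 or slope_hmc < 0:
        raise ValueError("slopes must be >= 0")
    cfg = cfg or CohortSimConfig()
    rng = np.random.default_rng(cfg.seed)

    sites, fields = _draw_sites(cfg, rng)
    true_mod, true_rel, true_mc, true_hmc = _true_levels(cfg, sites, fields, rng)
    bs_total, bs_unconv, tab_total, tab_unconv = _observe_reads(cfg, true_mod, true_hmc, rng)
    sites["bs_total"], sites["bs_unconverted"] = bs_total, bs_unconv
    sites["tab_total"], sites["tab_unconverted"] = tab_total, tab_unconv
    mod, hmc, mc, rel = compute_levels_arrays(bs_unconv, bs_total, tab_unconv, tab_total)
    sites["mod_level"], sites["hmc_level"] = mod, hmc
    sites["mc_level"], sites["hmc_rel"] = mc, rel

    genes, exons, cgi = _make_annotations(cfg, rng)
    expression = _make_expression(cfg, genes.df["label"].tolist(), rng)

    ages = rng.uniform(cfg.age_min, cfg.age_max, size=cfg.n_patients)
    catalogs = []
    n_events = np.zeros(len(sites), dtype=np.int64)
    chrom_arr = sites["chrom"].to_numpy()
    pos_arr = sites["pos"].to_numpy()
    strand_arr = sites["strand"].to_numpy()
    for i in range(cfg.n_patients):
        p = np.clip(cfg.baseline_mut_prob
                    + (slope_mc * true_mc + slope_hmc * true_hmc) * ages[i], 0, 0.999)
        hit = np.flatnonzero(rng.random(len(sites)) < p)
        n_events[hit] += 1
        rows = []
        for j in hit:
            strand = strand_arr[j]
            tri = _cpg_trinucleotide(strand, rng)
            ref, alt = ("C", "T") if strand == "+" else ("G", "A")
            rows.append((chrom_arr[j], int(pos_arr[j]), ref, alt, tri))
        muts = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "trinucleotide"])
        cat = SampleCatalog(sample_id=f"P{i + 1:04d}", cancer_type=cfg.cancer_type,
                            assay="WGS", age_years=float(ages[i]), mutations=muts)
        annotate_catalog(cat)
        catalogs.append(cat)

    comp = pd.DataFrame(columns=["gene_id", "n_all", "n_c", "n_t", "n_cpg", "n_modc"])
    truth = _build_truth(cfg, sites, true_mod, true_rel, true_mc, true_hmc,
                         np.full(len(sites), np.nan), n_events, comp,
                         injected={"slope_mc": slope_mc, "slope_hmc": slope_hmc,
                                   "ages": ages})
    return SimulatedCohort(sites=sites, catalogs=catalogs, genes=genes, exons=exons,
                           cgi=cgi, expression_table=expression, truth=truth)


# ---------------------------------------------------------------------------
# window-level simulators (cross-tissue and power analyses)
# ---------------------------------------------------------------------------

def simulate_window_cpg_counts(genome_bp: int, window_bp: int, cpg_density: float,
                               rng) -> np.ndarray:
    """Per-window CpG counts for a synthetic genome tiled at ``window_bp``."""
    n_windows = int(np.ceil(genome_bp / window_bp))
    sizes = np.full(n_windows, window_bp, dtype=float)
    sizes[-1] = genome_bp - window_bp * (n_windows - 1)
    return rng.poisson(sizes * cpg_density)


def simulate_tissue_maps(n_windows: int, n_tissues: int = 3,
                         shared_weight: float = 0.5, seed: int = DEFAULT_SEED,
                         names=None) -> pd.DataFrame:
    """Window-level hmc_rel maps for several tissues.

    Each map is a logistic transform of a shared smooth field plus a
    tissue-specific smooth field, weighted by ``shared_weight``; tissues
    therefore correlate without being interchangeable, mimicking real
    cross-tissue 5hmC maps.
    """
    rng = np.random.default_rng(seed)
    shared = _smooth_field(n_windows, rng)
    cols = {}
    names = names or [f"tissue{i + 1}" for i in range(n_tissues)]
    for name in names:
        specific = _smooth_field(n_windows, rng)
        z = shared_weight * shared + (1 - shared_weight) * specific
        cols[name] = 1.0 / (1.0 + np.exp(-z))
    return pd.DataFrame(cols)


def simulate_window_mutation_counts(map_values, cpg_counts, n_patients: int,
                                    baseline: float, effect: float, rng) -> np.ndarray:
    """CpG>T counts per window for a cohort whose mutation rate decreases
    with the (tissue-specific) window hmc_rel: rate = baseline x
    (1 + effect x (1 − hmc_rel))."""
    rate = baseline * (1.0 + effect * (1.0 - np.asarray(map_values, float)))
    lam = np.asarray(cpg_counts, float) * n_patients * rate
    return rng.poisson(lam)


# ---------------------------------------------------------------------------
# file export
# ---------------------------------------------------------------------------

def write_cohort(cohort: SimulatedCohort, outdir) -> dict:
    """Write the cohort in the standard on-disk formats; returns the paths.

    The files round-trip through :mod:`hydroxymut.io_formats`.
    """
    import os
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "modifications": os.path.join(outdir, "modifications.tsv"),
        "mutations": os.path.join(outdir, "mutations.tsv"),
        "genes": os.path.join(outdir, "genes.bed"),
        "exons": os.path.join(outdir, "exons.bed"),
        "cgi": os.path.join(outdir, "cgi.bed"),
        "expression": os.path.join(outdir, "expression.tsv"),
        "truth": os.path.join(outdir, "ground_truth_classes.tsv"),
    }
    io_formats.write_modification_table(cohort.sites, paths["modifications"])
    io_formats.write_mutation_table(cohort.catalogs, paths["mutations"])
    io_formats.write_bed(cohort.genes, paths["genes"])
    io_formats.write_bed(cohort.exons, paths["exons"])
    io_formats.write_bed(cohort.cgi, paths["cgi"])
    io_formats.write_expression_table(cohort.expression_table, paths["expression"])
    cohort.truth.class_summary.to_csv(paths["truth"], sep="\t", index=False)
    return paths
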