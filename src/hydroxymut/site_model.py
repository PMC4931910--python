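"""Per-site modification levels, site classes, and 96-type mutation context.

Each cytosine covered by both bisulfite (BS) and Tet-assisted bisulfite
(TAB) sequencing gets four derived quantities:

* ``mod_level``  — fraction of BS reads unconverted (any modification),
* ``hmc_level``  — fraction of TAB reads unconverted (5hmC specifically),
* ``mc_level``   — mod_level − hmc_level, clipped at 0 (5mC),
* ``hmc_rel``    — hmc_level / mod_level, the hydroxymethylated share of a
  site's modification; undefined (NaN) below ``mod_floor``.

Sites are classified as 5mC-high (mostly methylated), 5hmC-high (mostly
hydroxymethylated) or neither; somatic SNVs are normalised to the
pyrimidine strand and classified into the standard 96 trinucleotide types.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

DEFAULT_MOD_FLOOR = 0.10

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Fixed lexicographic order of the 96 pyrimidine-strand mutation types:
#: substitution (C>A, C>G, C>T, T>A, T>C, T>G) major, 5' flank then 3' flank minor.
MUT96_LABELS = tuple(
    f"{five}[{ref}>{alt}]{three}"
    for ref, alt in (("C", "A"), ("C", "G"), ("C", "T"),
                     ("T", "A"), ("T", "C"), ("T", "G"))
    for five, three in product("ACGT", "ACGT")
)
_MUT96_INDEX = {label: i for i, label in enumerate(MUT96_LABELS)}


@dataclass
class ClassificationConfig:
    """Thresholds defining the 5mC-high / 5hmC-high site classes.

    A site qualifies for either class only when mod_level exceeds
    ``mod_floor`` (strictly, per the "mod level > 10%" definition).  Within
    sufficiently modified sites, hmc_rel ≤ ``threshold_5mC`` marks 5mC-high
    and hmc_rel ≥ ``threshold_5hmC`` marks 5hmC-high; both comparisons are
    inclusive.
    """

    mod_floor: float = DEFAULT_MOD_FLOOR
    threshold_5mC: float = 0.3
    threshold_5hmC: float = 0.5

    def __post_init__(self):
        if not (0 <= self.threshold_5mC <= self.threshold_5hmC <= 1):
            raise ValueError("need 0 <= threshold_5mC <= threshold_5hmC <= 1")
        if not (0 < self.mod_floor < 1):
            raise ValueError("mod_floor must be in (0, 1)")


@dataclass
class SampleCatalog:
    """One patient's somatic SNVs plus metadata.

    ``mutations`` is a DataFrame with columns chrom, pos (0-based), ref, alt
    and, after :func:`annotate_catalog`, mut96, pyrimidine_strand, pyr_ref,
    pyr_alt.
    """

    sample_id: str
    cancer_type: str = "NA"
    assay: str = "WGS"
    age_years: float | None = None
    mutations: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __len__(self):
        return len(self.mutations)


# ---------------------------------------------------------------------------
# levels
# ---------------------------------------------------------------------------

def compute_levels(bs_unconverted, bs_total, tab_unconverted, tab_total,
                   mod_floor: float = DEFAULT_MOD_FLOOR):
    """Derive (mod_level, hmc_level, mc_level, hmc_rel) for one site.

    hmc_rel is ``nan`` when mod_level < mod_floor.  Raises on zero totals or
    unconverted counts exceeding totals.
    """
    for unconv, total, name in ((bs_unconverted, bs_total, "BS"),
                                (tab_unconverted, tab_total, "TAB")):
        if total <= 0:
            raise ValueError(f"{name} total must be positive")
        if not (0 <= unconv <= total):
            raise ValueError(f"{name} unconverted must lie in [0, total]")
    mod = bs_unconverted / bs_total
    hmc = tab_unconverted / tab_total
    mc = max(mod - hmc, 0.0)
    rel = hmc / mod if mod >= mod_floor else float("nan")
    return mod, hmc, mc, rel


def compute_levels_arrays(bs_unconverted, bs_total, tab_unconverted, tab_total,
                          mod_floor: float = DEFAULT_MOD_FLOOR):
    """Vectorised :func:`compute_levels`; also returns the raw (possibly
    negative) mod−hmc difference clipped into ``mc``."""
    bs_total = np.asarray(bs_total, float)
    tab_total = np.asarray(tab_total, float)
    if (bs_total <= 0).any() or (tab_total <= 0).any():
        raise ValueError("read totals must be positive")
    mod = np.asarray(bs_unconverted, float) / bs_total
    hmc = np.asarray(tab_unconverted, float) / tab_total
    mc = np.clip(mod - hmc, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(mod >= mod_floor, hmc / np.where(mod > 0, mod, np.nan), np.nan)
    return mod, hmc, mc, rel


# ---------------------------------------------------------------------------
# site classification
# ---------------------------------------------------------------------------

def classify_sites(sites: pd.DataFrame, cfg: ClassificationConfig | None = None) -> pd.Series:
    """Label each site ``mc_high`` / ``hmc_high`` / ``neither``.

    Expects mod_level and hmc_rel columns (hmc_rel NaN counts as neither).
    """
    cfg = cfg or ClassificationConfig()
    mod = sites["mod_level"].to_numpy(float)
    rel = sites["hmc_rel"].to_numpy(float)
    eligible = mod > cfg.mod_floor
    with np.errstate(invalid="ignore"):
        mc = eligible & (rel <= cfg.threshold_5mC)
        hmc = eligible & (rel >= cfg.threshold_5hmC)
    labels = np.full(len(sites), "neither", dtype=object)
    labels[mc] = "mc_high"
    labels[hmc] = "hmc_high"
    return pd.Series(labels, index=sites.index, name="site_class")


def classify_site(call, cfg: ClassificationConfig | None = None) -> str:
    """Scalar version of :func:`classify_sites` for a mapping-like record."""
    cfg = cfg or ClassificationConfig()
    mod = call["mod_level"]
    rel = call["hmc_rel"]
    if not mod > cfg.mod_floor or np.isnan(rel):
        return "neither"
    if rel <= cfg.threshold_5mC:
        return "mc_high"
    if rel >= cfg.threshold_5hmC:
        return "hmc_high"
    return "neither"


# ---------------------------------------------------------------------------
# 96-type mutation classification
# ---------------------------------------------------------------------------

def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def classify_mutation_96(ref: str, alt: str, trinucleotide: str) -> str:
    """Classify a substitution into one of the 96 trinucleotide types.

    ``trinucleotide`` is the 3-mer centred on ``ref`` on the + strand.
    Purine references are reverse-complemented (context included) so the
    mutated base is reported as the pyrimidine of the Watson-Crick pair.
    Returns the label "X[P>Q]Y"; raises on invalid bases (ambiguous bases
    are the caller's responsibility to filter).
    """
    ref, alt, trinucleotide = ref.upper(), alt.upper(), trinucleotide.upper()
    if ref not in "ACGT" or alt not in "ACGT" or ref == alt:
        raise ValueError(f"invalid substitution {ref}>{alt}")
    if len(trinucleotide) != 3 or any(b not in "ACGT" for b in trinucleotide):
        raise ValueError(f"invalid trinucleotide {trinucleotide!r}")
    if trinucleotide[1] != ref:
        raise ValueError("trinucleotide must be centred on ref")
    if ref in "AG":  # normalise to the pyrimidine strand
        ref, alt = reverse_complement(ref), reverse_complement(alt)
        trinucleotide = reverse_complement(trinucleotide)
    return f"{trinucleotide[0]}[{ref}>{alt}]{trinucleotide[2]}"


def pyrimidine_normalise(ref: str, alt: str):
    """Return (pyr_ref, pyr_alt, pyrimidine_strand) for a + strand SNV."""
    if ref in "CT":
        return ref, alt, "+"
    return reverse_complement(ref), reverse_complement(alt), "-"


def annotate_catalog(catalog: SampleCatalog) -> SampleCatalog:
    """Add pyrimidine-strand fields (and mut96 when a trinucleotide column
    is present) to a catalog's mutation table, in place."""
    df = catalog.mutations
    if len(df) == 0:
        return catalog
    pyr = [pyrimidine_normalise(r, a) for r, a in zip(df["ref"], df["alt"])]
    df["pyr_ref"], df["pyr_alt"], df["pyrimidine_strand"] = zip(*pyr)
    if "trinucleotide" in df.columns:
        df["mut96"] = [
            classify_mutation_96(r, a, t)
            for r, a, t in zip(df["ref"], df["alt"], df["trinucleotide"])
        ]
    return catalog


def spectrum(catalog: SampleCatalog, trinucleotide_genome_counts: dict) -> np.ndarray:
    """Mutation spectrum: per-type count normalised by the genome-wide
    frequency of the type's trinucleotide (pyrimidine-strand counts).

    Vector order is :data:`MUT96_LABELS`.  Raises if a needed trinucleotide
    has zero genome count.
    """
    if "mut96" not in catalog.mutations.columns:
        raise ValueError("catalog lacks mut96 annotation; run annotate_catalog "
                         "with a trinucleotide column")
    counts = np.zeros(96, dtype=float)
    for label in catalog.mutations["mut96"]:
        counts[_MUT96_INDEX[label]] += 1
    out = np.zeros(96, dtype=float)
    for i, label in enumerate(MUT96_LABELS):
        tri = label[0] + label[2] + label[-1]
        genome = trinucleotide_genome_counts.get(tri, 0)
        if counts[i] and not genome:
            raise ValueError(f"zero genome count for trinucleotide {tri}")
        out[i] = counts[i] / genome if genome else 0.0
    return out


# ---------------------------------------------------------------------------
# joining mutations onto modification sites
# ---------------------------------------------------------------------------

#: pyrimidine-strand substitution classes usable as ``mutation_types``.
CPG_MUTATION_TYPES = ("C>T", "C>A", "C>G")


def join_mutations_to_sites(sites: pd.DataFrame, catalogs,
                            mutation_types=("C>T",)) -> pd.DataFrame:
    """Match somatic mutations onto cytosine sites.

    A mutation matches a site iff chromosome and position coincide and the
    mutation's pyrimidine strand equals the strand carrying the site's
    cytosine.  Returns a long DataFrame with columns site_index (the
    positional row number in ``sites``), sample_id, mut_type; unmatched
    mutations are ignored.
    """
    mutation_types = set(mutation_types)
    site_key = pd.MultiIndex.from_arrays(
        [sites["chrom"], sites["pos"], sites["strand"]])
    lookup = pd.Series(np.arange(len(sites)), index=site_key)
    if lookup.index.has_duplicates:
        raise ValueError("duplicate (chrom, pos, strand) records in site table")

    frames = []
    for cat in catalogs:
        df = cat.mutations
        if len(df) == 0:
            continue
        if "pyrimidine_strand" not in df.columns:
            annotate_catalog(cat)
            df = cat.mutations
        mtype = df["pyr_ref"] + ">" + df["pyr_alt"]
        sel = df.loc[mtype.isin(mutation_types)]
        mtype = mtype.loc[sel.index]
        if len(sel) == 0:
            continue
        key = pd.MultiIndex.from_arrays(
            [sel["chrom"], sel["pos"], sel["pyrimidine_strand"]])
        hit = lookup.reindex(key)
        ok = hit.notna().to_numpy()
        if not ok.any():
            continue
        frames.append(pd.DataFrame({
            "site_index": hit.to_numpy()[ok].astype(np.int64),
            "sample_id": cat.sample_id,
            "mut_type": mtype.to_numpy()[ok],
        }))
    if not frames:
        return pd.DataFrame(columns=["site_index", "sample_id", "mut_type"])
    return pd.concat(frames, ignore_index=True)
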