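"""Readers and writers for the tabular genomic formats the pipeline consumes.

Every reader validates its input and converts coordinates to the single
internal convention (0-based, half-open intervals, strand-resolved cytosine
records).  Positions in VCF/MAF-like sources and in the per-cytosine
modification tables are 1-based on disk and shifted on the way in; writers
shift back, so a write-then-read round trip is the identity.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pyranges as pr
import pysam

from .site_model import DEFAULT_MOD_FLOOR, SampleCatalog, compute_levels_arrays

MODIFICATION_COLUMNS = [
    "chrom", "pos", "strand", "context",
    "bs_total", "bs_unconverted", "tab_total", "tab_unconverted",
]

MUTATION_COLUMNS = ["chrom", "pos", "ref", "alt", "sample_id", "cancer_type", "assay"]

_VALID_CONTEXTS = {"CG", "CHG", "CHH"}
_BASES = set("ACGT")


@dataclass
class LoadReport:
    """Bookkeeping for a single file load."""

    path: str
    n_read: int = 0
    n_kept: int = 0
    n_dropped_low_tab: int = 0
    n_skipped_indels: int = 0
    warnings: list = field(default_factory=list)


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


# ---------------------------------------------------------------------------
# modification tables
# ---------------------------------------------------------------------------

def read_modification_table(path, min_tab_reads: int = 5, mod_floor: float = DEFAULT_MOD_FLOOR):
    """Read a per-cytosine BS/TAB read-count table.

    The file is a TSV with header columns chrom, pos (1-based), strand,
    context, bs_total, bs_unconverted, tab_total, tab_unconverted.  Sites
    with ``tab_total <= min_tab_reads`` are dropped (the maps only trust
    5hmC calls with more than ``min_tab_reads`` TAB-Seq reads).  Returns
    ``(DataFrame, LoadReport)`` with 0-based positions and derived
    modification levels (mod_level, hmc_level, mc_level, hmc_rel).
    """
    report = LoadReport(path=str(path))
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str, "context": str})
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: cannot parse modification table: {exc}") from exc
    missing = [c for c in MODIFICATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    report.n_read = len(df)

    for col in ("pos", "bs_total", "bs_unconverted", "tab_total", "tab_unconverted"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna()
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # +1 header, +1 1-based
            raise FormatError(f"{path}: malformed value in column '{col}' at line {line}")
        df[col] = vals.astype(np.int64)
    _check_row_validity(df, path)

    keep = df["tab_total"] > int(min_tab_reads)
    report.n_dropped_low_tab = int((~keep).sum())
    df = df.loc[keep].reset_index(drop=True)
    df["pos"] = df["pos"] - 1  # to 0-based
    mod, hmc, mc, rel = compute_levels_arrays(
        df["bs_unconverted"].to_numpy(float), df["bs_total"].to_numpy(float),
        df["tab_unconverted"].to_numpy(float), df["tab_total"].to_numpy(float),
        mod_floor=mod_floor,
    )
    df["mod_level"] = mod
    df["hmc_level"] = hmc
    df["mc_level"] = mc
    df["hmc_rel"] = rel
    report.n_kept = len(df)
    return df, report


def _check_row_validity(df, path):
    if (df["pos"] < 1).any():
        line = int(np.flatnonzero((df["pos"] < 1).to_numpy())[0]) + 2
        raise FormatError(f"{path}: non-positive 1-based position at line {line}")
    bad_strand = ~df["strand"].isin(["+", "-"])
    if bad_strand.any():
        line = int(np.flatnonzero(bad_strand.to_numpy())[0]) + 2
        raise FormatError(f"{path}: strand must be + or - at line {line}")
    bad_ctx = ~df["context"].isin(_VALID_CONTEXTS)
    if bad_ctx.any():
        line = int(np.flatnonzero(bad_ctx.to_numpy())[0]) + 2
        raise FormatError(f"{path}: context must be one of {sorted(_VALID_CONTEXTS)} at line {line}")
    for prefix in ("bs", "tab"):
        over = df[f"{prefix}_unconverted"] > df[f"{prefix}_total"]
        if over.any():
            line = int(np.flatnonzero(over.to_numpy())[0]) + 2
            raise FormatError(
                f"{path}: {prefix}_unconverted exceeds {prefix}_total at line {line}")
        if (df[f"{prefix}_total"] < 0).any() or (df[f"{prefix}_unconverted"] < 0).any():
            raise FormatError(f"{path}: negative read count in {prefix} columns")


def write_modification_table(df: pd.DataFrame, path) -> None:
    """Write a modification table (internal 0-based) back to 1-based TSV."""
    out = df[MODIFICATION_COLUMNS].copy()
    out["pos"] = out["pos"] + 1
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# mutation catalogs
# ---------------------------------------------------------------------------

def read_mutation_table(path, dialect: str = "maf_tsv", metadata: pd.DataFrame | None = None):
    """Read somatic SNVs into :class:`SampleCatalog` objects.

    ``dialect`` is ``"vcf"`` (single- or multi-sample; sample id taken from
    the genotype column name, or the file name stem for site-only VCFs) or
    ``"maf_tsv"`` (TSV with chrom, pos, ref, alt, sample_id and optionally
    cancer_type, assay, age_years).  Only single-nucleotide substitutions
    are retained; indels are skipped and counted in the report.  ``metadata``
    is an optional sidecar table indexed by sample_id carrying cancer_type /
    assay / age_years for formats that cannot.
    """
    if dialect == "vcf":
        df, report = _read_vcf(path)
    elif dialect == "maf_tsv":
        df, report = _read_maf_tsv(path)
    else:
        raise ValueError(f"unknown mutation dialect: {dialect!r}")

    if metadata is not None:
        meta = metadata.set_index("sample_id") if "sample_id" in metadata.columns else metadata
        for col in ("cancer_type", "assay", "age_years"):
            if col in meta.columns:
                df[col] = df["sample_id"].map(meta[col]).fillna(df.get(col))

    catalogs = []
    for sample_id, sub in df.groupby("sample_id", sort=True):
        first = sub.iloc[0]
        age = first.get("age_years", np.nan)
        catalogs.append(SampleCatalog(
            sample_id=str(sample_id),
            cancer_type=str(first.get("cancer_type", "NA")),
            assay=str(first.get("assay", "WGS")),
            age_years=None if pd.isna(age) else float(age),
            mutations=sub.reset_index(drop=True),
        ))
    return catalogs, report


def _validate_snv(ref, alt, path, where):
    if ref == alt:
        raise FormatError(f"{path}: ref equals alt at {where}")
    if ref not in _BASES or alt not in _BASES:
        raise FormatError(f"{path}: non-ACGT allele at {where}")


def _read_vcf(path):
    report = LoadReport(path=str(path))
    rows = []
    with pysam.VariantFile(os.fspath(path)) as vcf:
        samples = list(vcf.header.samples)
        default_sample = samples[0] if samples else os.path.basename(
            os.fspath(path)).rsplit(".vcf", 1)[0]
        for rec in vcf:
            report.n_read += 1
            ref = rec.ref.upper()
            for alt in rec.alts or ():
                alt = alt.upper()
                if len(ref) != 1 or len(alt) != 1:
                    report.n_skipped_indels += 1
                    continue
                _validate_snv(ref, alt, path, f"{rec.chrom}:{rec.pos}")
                rows.append((rec.chrom, rec.pos - 1, ref, alt, default_sample))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "sample_id"])
    report.n_kept = len(df)
    return df, report


def _read_maf_tsv(path):
    report = LoadReport(path=str(path))
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str,
                                            "sample_id": str})
    missing = [c for c in ("chrom", "pos", "ref", "alt", "sample_id") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    report.n_read = len(df)
    df["ref"] = df["ref"].str.upper()
    df["alt"] = df["alt"].str.upper()
    is_snv = (df["ref"].str.len() == 1) & (df["alt"].str.len() == 1) & (df["alt"] != "-") \
        & (df["ref"] != "-")
    report.n_skipped_indels = int((~is_snv).sum())
    df = df.loc[is_snv].reset_index(drop=True)
    for i, (ref, alt, chrom, pos) in enumerate(zip(df["ref"], df["alt"], df["chrom"], df["pos"])):
        _validate_snv(ref, alt, path, f"{chrom}:{pos}")
    df["pos"] = df["pos"].astype(np.int64) - 1
    report.n_kept = len(df)
    return df, report


def write_mutation_table(catalogs, path) -> None:
    """Write catalogs as a 1-based MAF-like TSV (round-trips through
    ``read_mutation_table(dialect='maf_tsv')``)."""
    frames = []
    for cat in catalogs:
        sub = cat.mutations[["chrom", "pos", "ref", "alt"]].copy()
        sub["pos"] = sub["pos"] + 1
        sub["sample_id"] = cat.sample_id
        sub["cancer_type"] = cat.cancer_type
        sub["assay"] = cat.assay
        if cat.age_years is not None:
            sub["age_years"] = cat.age_years
        frames.append(sub)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# intervals (BED)
# ---------------------------------------------------------------------------

@dataclass
class IntervalSet:
    """A named set of half-open 0-based genomic intervals.

    ``df`` has columns chrom, start, end and optionally label (gene id).
    """

    df: pd.DataFrame
    name: str = ""

    def __post_init__(self):
        df = self.df.reset_index(drop=True)
        if len(df) and (df["start"] >= df["end"]).any():
            bad = df.loc[df["start"] >= df["end"]].iloc[0]
            raise FormatError(
                f"interval start >= end: {bad['chrom']}:{bad['start']}-{bad['end']}")
        self.df = df

    def __len__(self):
        return len(self.df)

    def total_bases(self) -> int:
        return int((self.df["end"] - self.df["start"]).sum())

    def contains(self, chrom, pos) -> np.ndarray:
        """Vectorized membership test for positions (0-based)."""
        chrom = np.asarray(chrom)
        pos = np.asarray(pos)
        out = np.zeros(pos.shape, dtype=bool)
        for c, sub in self.df.groupby("chrom"):
            mask = chrom == c
            if not mask.any():
                continue
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            order = np.argsort(starts)
            starts, ends = starts[order], ends[order]
            idx = np.searchsorted(starts, pos[mask], side="right") - 1
            ok = idx >= 0
            hit = np.zeros(idx.shape, dtype=bool)
            hit[ok] = pos[mask][ok] < ends[idx[ok]]
            out[mask] = hit
        return out


def read_bed(path, name: str = "") -> IntervalSet:
    """Read BED3/BED6 (0-based half-open); column 4, when present, is the label."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: fewer than 3 BED columns at line {lineno}")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise FormatError(f"{path}: start >= end at line {lineno}")
            label = parts[3] if len(parts) > 3 else ""
            rows.append((chrom, start, end, label))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])
    return IntervalSet(df, name=name or os.path.basename(os.fspath(path)))


def write_bed(intervals: IntervalSet, path) -> None:
    cols = ["chrom", "start", "end"]
    if "label" in intervals.df.columns and (intervals.df["label"] != "").any():
        cols.append("label")
    intervals.df[cols].to_csv(path, sep="\t", header=False, index=False)


def merge_intervals(intervals: IntervalSet) -> IntervalSet:
    """Merge overlapping/bookended intervals so each base is covered at most once."""
    if len(intervals) == 0:
        return IntervalSet(intervals.df.copy(), name=intervals.name)
    gr = pr.PyRanges(intervals.df.rename(
        columns={"chrom": "Chromosome", "start": "Start", "end": "End"}))
    merged = gr.merge().df.rename(
        columns={"Chromosome": "chrom", "Start": "start", "End": "end"})
    merged["chrom"] = merged["chrom"].astype(str)
    merged = merged.sort_values(["chrom", "start"]).reset_index(drop=True)
    merged["label"] = ""
    return IntervalSet(merged, name=intervals.name)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def read_expression_table(path) -> pd.Series:
    """Read a gene x sample FPKM table; return the per-gene median.

    Log-transforming is left to consumers (the window/gene models use
    log(1 + expression)).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = df.to_numpy(float)
    if (values < 0).any():
        gene = df.index[np.flatnonzero((values < 0).any(axis=1))[0]]
        raise FormatError(f"{path}: negative expression value for gene {gene}")
    return pd.Series(np.median(values, axis=1), index=df.index, name="median_expression")


def write_expression_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")
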