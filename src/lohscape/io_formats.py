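"""Reading and writing of site tables, VCFs, interval tracks and event tables.

Two input forms normalize to the same paired per-site stream: a pair of
single-sample VCFs (fields CHROM/POS/REF/ALT plus DP, AD, QD and SB or FS
from INFO or FORMAT), or flat tab-separated site tables.  Coordinates are
1-based inclusive internally; BED output is 0-based half-open.  Chromosome
names are normalized by stripping a leading ``chr`` prefix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

SITE_COLUMNS = [
    "sample_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "depth",
    "ad_ref",
    "ad_alt",
    "qd",
    "sb",
    "fs",
]

_BASES = {"A", "C", "G", "T"}


class FormatError(ValueError):
    """Malformed or unsorted input file."""


class DataInconsistencyError(ValueError):
    """Contradictory observations between paired sources."""


def normalize_chrom(values: pd.Series) -> pd.Series:
    return values.astype(str).str.replace(r"^chr", "", regex=True)


def _check_sorted(df: pd.DataFrame, what: str) -> None:
    # chromosomes must be grouped, positions non-decreasing within each
    chrom = df["chrom"].to_numpy()
    seen: set[str] = set()
    prev: Optional[str] = None
    for c in chrom:
        if c != prev:
            if c in seen:
                raise FormatError(f"{what}: chromosome {c} occurs in disjoint blocks")
            seen.add(c)
            prev = c
    pos = df["pos"].to_numpy()
    breaks = np.flatnonzero(chrom[1:] == chrom[:-1])
    if len(breaks) and (pos[breaks + 1] < pos[breaks]).any():
        raise FormatError(f"{what}: positions not sorted within chromosome")


def read_site_table(path: Union[str, Path], sample_id: Optional[str] = None) -> pd.DataFrame:
    """Load a flat TSV site table, validate sorting and uniqueness.

    Non-ACGT ref alleles and multi-base (indel) alleles are dropped at parse
    time.  Missing qd/sb/fs values may be empty or ``.`` and become NaN.
    """
    df = pd.read_csv(path, sep="\t", na_values=["."], dtype={"chrom": str, "ref": str, "alt": str})
    missing = [c for c in SITE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"site table {path} lacks columns {missing}")
    df["chrom"] = normalize_chrom(df["chrom"])
    df["alt"] = df["alt"].fillna("")
    snv = df["ref"].isin(_BASES) & (df["alt"].isin(_BASES) | (df["alt"] == ""))
    if not snv.all():
        log.info("dropping %d non-SNV rows from %s", (~snv).sum(), path)
        df = df[snv].reset_index(drop=True)
    if sample_id is not None:
        df = df[df["sample_id"] == sample_id].reset_index(drop=True)
    _check_sorted(df, str(path))
    if df.duplicated(["sample_id", "chrom", "pos"]).any():
        raise FormatError(f"duplicate (sample_id, chrom, pos) rows in {path}")
    return df[SITE_COLUMNS]


def _info_or_format(variant, field: str):
    val = variant.INFO.get(field)
    if val is not None:
        return val
    try:
        arr = variant.format(field)
    except KeyError:
        return None
    if arr is None:
        return None
    v = np.asarray(arr).ravel()
    return float(v[0]) if len(v) else None


def read_vcf(path: Union[str, Path], sample_id: Optional[str] = None) -> pd.DataFrame:
    """Read a single-sample VCF into the site-table layout.

    Only biallelic SNVs are kept.  DP and AD are taken from the first
    sample's FORMAT fields when present, otherwise from INFO; QD, SB and FS
    are taken from INFO (or FORMAT as fallback).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sid = sample_id or (vcf.samples[0] if vcf.samples else Path(path).stem)
    rows = []
    for v in vcf:
        if len(v.REF) != 1 or v.REF not in _BASES:
            continue
        alt = v.ALT[0] if v.ALT else ""
        if alt and (len(alt) != 1 or alt not in _BASES):
            continue
        if len(v.ALT) > 1:
            continue
        if v.gt_depths is not None and len(v.gt_depths) and v.gt_depths[0] >= 0:
            depth = int(v.gt_depths[0])
        else:
            depth = int(v.INFO.get("DP", 0))
        fmt_ad = v.format("AD") if "AD" in (v.FORMAT or []) else None
        if fmt_ad is not None:
            ad = np.asarray(fmt_ad)[0]
            ad_ref, ad_alt = int(ad[0]), int(ad[1]) if len(ad) > 1 else 0
        else:
            ad_ref = ad_alt = 0
        rows.append(
            {
                "sample_id": sid,
                "chrom": v.CHROM,
                "pos": v.POS,
                "ref": v.REF,
                "alt": alt,
                "depth": depth,
                "ad_ref": ad_ref,
                "ad_alt": ad_alt,
                "qd": _info_or_format(v, "QD"),
                "sb": _info_or_format(v, "SB"),
                "fs": _info_or_format(v, "FS"),
            }
        )
    df = pd.DataFrame(rows, columns=SITE_COLUMNS)
    df["chrom"] = normalize_chrom(df["chrom"])
    _check_sorted(df, str(path))
    return df


def load_sites(path: Union[str, Path], sample_id: Optional[str] = None) -> pd.DataFrame:
    """Dispatch on extension: ``.vcf``/``.vcf.gz`` via cyvcf2, else TSV."""
    name = str(path)
    if name.endswith((".vcf", ".vcf.gz", ".bcf")):
        return read_vcf(path, sample_id)
    return read_site_table(path, sample_id)


def read_paired_sites(
    control_source: Union[str, Path, pd.DataFrame],
    tumor_source: Union[str, Path, pd.DataFrame],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Intersect two sorted sources on (chrom, pos).

    Returns aligned (control, tumor) tables restricted to positions present
    in both sources -- the co-present set whose size is the basis of the
    "total analyzed" denominator.  Contradictory reference alleles at a
    shared position raise :class:`DataInconsistencyError`.
    """
    c = control_source if isinstance(control_source, pd.DataFrame) else load_sites(control_source)
    t = tumor_source if isinstance(tumor_source, pd.DataFrame) else load_sites(tumor_source)
    merged = c.merge(t, on=["chrom", "pos"], suffixes=("_c", "_t"), how="inner", sort=False)
    bad = merged["ref_c"] != merged["ref_t"]
    if bad.any():
        row = merged[bad].iloc[0]
        raise DataInconsistencyError(
            f"reference mismatch at {row['chrom']}:{row['pos']}: "
            f"{row['ref_c']} (control) vs {row['ref_t']} (tumor)"
        )
    control = merged[["chrom", "pos"]].copy()
    tumor = merged[["chrom", "pos"]].copy()
    for col in SITE_COLUMNS:
        if col in ("chrom", "pos"):
            continue
        control[col] = merged[f"{col}_c"].to_numpy()
        tumor[col] = merged[f"{col}_t"].to_numpy()
    control["ref"] = merged["ref_c"].to_numpy()
    tumor["ref"] = merged["ref_c"].to_numpy()
    return control[SITE_COLUMNS], tumor[SITE_COLUMNS]


@dataclass
class IntervalTrack:
    """A named set of 0-based half-open labelled intervals."""

    name: str
    df: pd.DataFrame  # columns chrom, start, end, label

    def __post_init__(self) -> None:
        if (self.df["start"] >= self.df["end"]).any():
            raise FormatError(f"track {self.name}: interval with start >= end")

    def for_chrom(self, chrom: str) -> pd.DataFrame:
        return self.df[self.df["chrom"] == chrom]


def read_interval_track(path: Union[str, Path], kind: str = "auto", name: Optional[str] = None) -> IntervalTrack:
    """Read a BED3+1 or UCSC cytoband file into an :class:`IntervalTrack`.

    ``kind``: ``bed``, ``cytoband`` or ``auto`` (cytoband when the file has
    5 columns and the 5th looks like a Giemsa stain code).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        log.warning("empty interval file %s", path)
        return IntervalTrack(
            name or path.stem,
            pd.DataFrame(columns=["chrom", "start", "end", "label"]).astype(
                {"start": int, "end": int}
            ),
        )
    if kind == "auto":
        stains = {"gneg", "gpos25", "gpos50", "gpos75", "gpos100", "acen", "gvar", "stalk"}
        kind = (
            "cytoband"
            if df.shape[1] >= 5 and df[4].isin(stains).all()
            else "bed"
        )
    out = pd.DataFrame(
        {
            "chrom": normalize_chrom(df[0]),
            "start": df[1].astype(int),
            "end": df[2].astype(int),
            "label": df[3] if df.shape[1] > 3 else "",
        }
    )
    return IntervalTrack(name or path.stem, out)


def write_events(events: pd.DataFrame, tsv_path: Union[str, Path], bed_path: Union[str, Path, None] = None) -> None:
    """Write the event table as TSV (and optionally BED, 0-based half-open).

    The TSV round-trips bit-stably through :func:`read_events`; rows are
    sorted by (sample_id, chrom, pos) with a fixed column order.
    """
    df = events.sort_values(["sample_id", "chrom", "pos"], kind="mergesort").reset_index(drop=True)
    df.to_csv(tsv_path, sep="\t", index=False)
    if bed_path is not None:
        bed = pd.DataFrame(
            {
                "chrom": df["chrom"],
                "start": df["pos"] - 1,
                "end": df["pos"],
                "name": df["sample_id"].astype(str) + ":" + df["kind"].astype(str),
            }
        )
        bed.to_csv(bed_path, sep="\t", index=False, header=False)


def read_events(tsv_path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(
        tsv_path,
        sep="\t",
        dtype={"chrom": str, "ref": str, "control_m": str, "tumor_m": str},
        keep_default_na=False,
        na_values=[],
    )
    df["pos"] = df["pos"].astype(np.int64)
    df["copy_neutral"] = df["copy_neutral"].astype(str).str.lower().isin(["true", "1"])
    return df


def write_segments_bed(segments: pd.DataFrame, path: Union[str, Path]) -> None:
    """CNV segments as BED4 with the gain/loss call in the name column."""
    bed = segments[["chrom", "start", "end", "call"]]
    bed.to_csv(path, sep="\t", index=False, header=False)


def write_site_table(df: pd.DataFrame, path: Union[str, Path]) -> None:
    df[SITE_COLUMNS].to_csv(path, sep="\t", index=False, na_rep=".")
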