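"""Spatial LOH analyses: fragment runs, interstitial classification,
per-chromosome densities, cross-type correlations, recurrent genes.

An *LOH fragment run* is a maximal run of consecutive LOH events on one
chromosome uninterrupted by any co-callable heterozygous site that remained
heterozygous in the tumor.  Its length (last - first event position + 1,
so an isolated event has length 1 bp) approximates the extent of the
underlying converted tract; short (<= 1 Mb) runs are the signature of gene
conversion, very long runs of segmental events.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats as sps

from lohscape.calling import PairCallResult
from lohscape.core import EventKind, LOH_KINDS
from lohscape.io_formats import IntervalTrack

LOH_KIND_VALUES = [k.value for k in LOH_KINDS]
AUTOSOMES = [str(i) for i in range(1, 23)]

RUN_COLUMNS = ["sample_id", "chrom", "start", "end", "n_events", "length", "interstitial"]


def fragment_runs(
    events: pd.DataFrame,
    retained_het: pd.DataFrame,
    sample_id: Optional[str] = None,
) -> pd.DataFrame:
    """Maximal runs of consecutive LOH events unbroken by retained Mm sites.

    ``events`` may contain any event kinds; only LOH kinds delimit runs.
    Returns one row per run with its 1-based inclusive span.
    """
    loh = events[events["kind"].isin(LOH_KIND_VALUES)]
    if sample_id is not None:
        loh = loh[loh["sample_id"] == sample_id]
    rows = []
    for chrom, grp in loh.groupby("chrom", sort=True):
        pos = np.sort(grp["pos"].to_numpy(dtype=np.int64))
        ret = np.sort(
            retained_het.loc[retained_het["chrom"] == chrom, "pos"].to_numpy(dtype=np.int64)
        )
        if len(pos) == 0:
            continue
        # a retained het strictly between two successive LOHs splits the run
        split_after = np.zeros(len(pos), dtype=bool)
        if len(pos) > 1 and len(ret):
            k = np.searchsorted(ret, pos)
            split_after[:-1] = k[1:] > k[:-1]
        run_start = 0
        for i in range(len(pos)):
            if i == len(pos) - 1 or split_after[i]:
                start, end = int(pos[run_start]), int(pos[i])
                rows.append(
                    {
                        "sample_id": sample_id if sample_id is not None else "",
                        "chrom": chrom,
                        "start": start,
                        "end": end,
                        "n_events": i - run_start + 1,
                        "length": end - start + 1,
                        "interstitial": pd.NA,
                    }
                )
                run_start = i + 1
    return pd.DataFrame(rows, columns=RUN_COLUMNS)


def run_length_histogram(lengths: Sequence[int], n_log_bins: int = 8) -> pd.DataFrame:
    """Histogram with a dedicated <= 1 Mb bin plus log-spaced larger bins."""
    lengths = np.asarray(lengths, dtype=float)
    mb = 1_000_000.0
    edges = [0.0, mb]
    if len(lengths) and lengths.max() > mb:
        edges.extend(np.logspace(np.log10(mb), np.log10(lengths.max() + 1), n_log_bins + 1)[1:])
    else:
        edges.append(10 * mb)
    counts, _ = np.histogram(lengths, bins=edges)
    return pd.DataFrame(
        {"bin_lo_bp": edges[:-1], "bin_hi_bp": edges[1:], "n_runs": counts}
    )


def analyzed_extent(per_sample_sites: pd.DataFrame) -> dict[str, tuple[int, int]]:
    """Per-chromosome (min, max) analyzed position from any site table."""
    ext = per_sample_sites.groupby("chrom")["pos"].agg(["min", "max"])
    return {str(c): (int(r["min"]), int(r["max"])) for c, r in ext.iterrows()}


def classify_interstitial(
    run,
    extent: Mapping[str, tuple[int, int]],
    cytobands: Optional[IntervalTrack] = None,
) -> bool:
    """True iff the run touches neither end of its chromosome's analyzed
    extent nor (when a cytoband track is given) a terminal band.

    ``run`` needs attributes/keys chrom, start, end.  Terminal bands are the
    first and last band of the chromosome in the supplied track.
    """
    chrom = str(run["chrom"] if isinstance(run, (dict, pd.Series)) else run.chrom)
    start = int(run["start"] if isinstance(run, (dict, pd.Series)) else run.start)
    end = int(run["end"] if isinstance(run, (dict, pd.Series)) else run.end)
    if chrom not in extent:
        raise KeyError(f"no analyzed extent for chromosome {chrom}")
    lo, hi = extent[chrom]
    if start <= lo or end >= hi:
        return False
    if cytobands is not None:
        bands = cytobands.for_chrom(chrom).sort_values("start")
        if len(bands):
            for band in (bands.iloc[0], bands.iloc[-1]):
                # 1-based run vs 0-based half-open band
                if start <= band["end"] and end > band["start"]:
                    return False
    return True


def annotate_interstitial(
    runs: pd.DataFrame,
    extent: Mapping[str, tuple[int, int]],
    cytobands: Optional[IntervalTrack] = None,
) -> pd.DataFrame:
    out = runs.copy()
    out["interstitial"] = [
        classify_interstitial(row, extent, cytobands) for _, row in out.iterrows()
    ]
    return out


def chromosome_densities(
    results: Iterable[PairCallResult],
    sexes: Mapping[str, str],
    copy_neutral_only: bool = False,
) -> pd.DataFrame:
    """Pooled per-chromosome LOH densities.

    ``loh_per_Mm`` divides by control heterozygous sites analyzed,
    ``loh_per_bp`` by co-callable positions.  The X chromosome pools female
    samples only (two active X homologs are required for interhomolog LOH
    bookkeeping to be comparable); Y is excluded.
    """
    loh_counts: dict[str, int] = {}
    denom_mm: dict[str, int] = {}
    denom_bp: dict[str, int] = {}
    for res in results:
        sex = sexes.get(res.sample_id)
        if sex is None:
            raise ValueError(f"missing sex for sample {res.sample_id}")
        ev = res.events
        ev = ev[ev["kind"].isin(LOH_KIND_VALUES)]
        if copy_neutral_only and len(ev):
            ev = ev[ev["copy_neutral"]]
        for chrom, cnt in ev.groupby("chrom").size().items():
            chrom = str(chrom)
            if chrom == "Y" or (chrom == "X" and sex != "F"):
                continue
            loh_counts[chrom] = loh_counts.get(chrom, 0) + int(cnt)
        for row in res.per_chrom.itertuples(index=False):
            chrom = str(row.chrom)
            if chrom == "Y" or (chrom == "X" and sex != "F"):
                continue
            denom_mm[chrom] = denom_mm.get(chrom, 0) + int(row.n_Mm)
            denom_bp[chrom] = denom_bp.get(chrom, 0) + int(row.n_co)
    chroms = sorted(denom_mm, key=lambda c: (len(c), c))
    rows = []
    for chrom in chroms:
        n_mm, n_bp = denom_mm[chrom], denom_bp[chrom]
        n_loh = loh_counts.get(chrom, 0)
        rows.append(
            {
                "chrom": chrom,
                "n_loh": n_loh,
                "n_Mm": n_mm,
                "n_bp": n_bp,
                "loh_per_Mm": n_loh / n_mm if n_mm else np.nan,
                "loh_per_bp": n_loh / n_bp if n_bp else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=["chrom", "n_loh", "n_Mm", "n_bp", "loh_per_Mm", "loh_per_bp"])


def per_chromosome_event_totals(results: Iterable[PairCallResult]) -> pd.DataFrame:
    """Pooled autosome totals of LOH, GOH-M and GOH-m events."""
    totals = pd.DataFrame(0, index=pd.Index(AUTOSOMES, name="chrom"), columns=["loh", "goh_M", "goh_m"])
    for res in results:
        ev = res.events
        if len(ev) == 0:
            continue
        ev = ev[ev["chrom"].astype(str).isin(AUTOSOMES)]
        for col, kinds in (
            ("loh", LOH_KIND_VALUES),
            ("goh_M", [EventKind.GOH_M.value]),
            ("goh_m", [EventKind.GOH_m.value]),
        ):
            cnt = ev[ev["kind"].isin(kinds)].groupby("chrom").size()
            totals.loc[cnt.index, col] += cnt
    return totals.reset_index()


def correlate_types(totals: pd.DataFrame) -> dict[str, float]:
    """Pearson correlations between per-autosome LOH, GOH-M, GOH-m totals.

    Each point is one autosome.  A coefficient is absent (NaN) when either
    vector has zero variance.
    """
    out = {}
    for a, b, key in (
        ("loh", "goh_M", "loh_vs_goh_M"),
        ("loh", "goh_m", "loh_vs_goh_m"),
        ("goh_m", "goh_M", "goh_m_vs_goh_M"),
    ):
        x = totals[a].to_numpy(dtype=float)
        y = totals[b].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            out[key] = np.nan
        else:
            out[key] = float(sps.pearsonr(x, y).statistic)
    return out


@dataclass
class GeneReport:
    table: pd.DataFrame
    min_samples: int


def recurrent_genes(
    events: pd.DataFrame,
    genes: IntervalTrack,
    min_samples: int = 3,
    kinds: Sequence[str] = tuple(LOH_KIND_VALUES),
) -> pd.DataFrame:
    """Genes hit by events of the queried kinds in >= ``min_samples`` distinct
    samples, with counts split by homozygous-major vs -minor outcome.

    An event inside two overlapping genes counts for both.
    """
    if len(genes.df) == 0:
        raise ValueError("empty gene track")
    trees: dict[str, IntervalTree] = {}
    for row in genes.df.itertuples(index=False):
        trees.setdefault(str(row.chrom), IntervalTree()).addi(row.start, row.end, row.label)

    ev = events[events["kind"].isin(list(kinds))]
    hits: dict[str, dict] = {}
    for row in ev.itertuples(index=False):
        tree = trees.get(str(row.chrom))
        if tree is None:
            continue
        for iv in tree.overlap(row.pos - 1, row.pos):  # event as 0-based point
            rec = hits.setdefault(
                iv.data,
                {"chrom": str(row.chrom), "samples": set(), "n_to_MM": 0, "n_to_mm": 0, "n_events": 0},
            )
            rec["samples"].add(row.sample_id)
            rec["n_events"] += 1
            if row.kind == EventKind.LOH_TO_MM.value:
                rec["n_to_MM"] += 1
            elif row.kind == EventKind.LOH_TO_mm.value:
                rec["n_to_mm"] += 1
    rows = [
        {
            "gene": gene,
            "chrom": rec["chrom"],
            "n_samples": len(rec["samples"]),
            "samples": ",".join(sorted(rec["samples"])),
            "n_events": rec["n_events"],
            "n_to_MM": rec["n_to_MM"],
            "n_to_mm": rec["n_to_mm"],
        }
        for gene, rec in hits.items()
        if len(rec["samples"]) >= min_samples
    ]
    cols = ["gene", "chrom", "n_samples", "samples", "n_events", "n_to_MM", "n_to_mm"]
    return pd.DataFrame(rows, columns=cols).sort_values(
        ["n_samples", "gene"], ascending=[False, True]
    ).reset_index(drop=True)
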