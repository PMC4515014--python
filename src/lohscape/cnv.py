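"""Windowed read-depth CNV calling via the Geary-Hinkley ratio transform.

The ratio w of tumor to control read depth in a genomic window is the ratio
of two approximately normal sums.  The Geary-Hinkley transformation

    z = (mu_c * w - mu_t) / sqrt(sigma_c^2 * w^2 + sigma_t^2)

maps w to an approximately standard-normal statistic under the null
hypothesis that the true ratio equals mu_t / mu_c, so copy-number gains and
losses appear as large positive / negative z.  Windows are fixed-width,
library sizes are equalized by median scaling, and runs of consecutive
same-call windows are merged into segments.

The null parameters (mu, sigma) are estimated genome-wide from the window
sums themselves: mu as the median and sigma as 1.4826 x the median absolute
deviation.  On Poisson-distributed depths this reproduces the sqrt(mu)
Poisson value, while on overdispersed (negative-binomial-like) capture data
it widens appropriately instead of flooding the caller with false windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

WINDOW_COLUMNS = ["chrom", "start", "end", "n_sites", "depth_t", "depth_c", "w", "z", "call"]
SEGMENT_COLUMNS = ["chrom", "start", "end", "call", "n_windows"]


@dataclass(frozen=True)
class GHParams:
    """Normal-approximation parameters for the two depth sums."""

    mu_t: float
    sigma_t: float
    mu_c: float
    sigma_c: float

    def __post_init__(self) -> None:
        if self.sigma_t <= 0 or self.sigma_c <= 0:
            raise ValueError("sigmas must be positive")


def gh_transform(w, mu_t: float, sigma_t: float, mu_c: float, sigma_c: float):
    """Geary-Hinkley z for a depth ratio ``w`` (scalar or array)."""
    if sigma_t <= 0 or sigma_c <= 0:
        raise ValueError("sigmas must be positive")
    w = np.asarray(w, dtype=float)
    z = (mu_c * w - mu_t) / np.sqrt(sigma_c**2 * w**2 + sigma_t**2)
    return z if z.shape else float(z)


def _robust_sigma(x: np.ndarray) -> float:
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    return float(1.4826 * mad)


def bin_depths(
    control: pd.DataFrame,
    tumor: pd.DataFrame,
    window_size: int = 500_000,
    min_sites: int = 10,
    z_crit: float = 1.96,
) -> pd.DataFrame:
    """Sum per-site depths into fixed windows and compute per-window z.

    Tumor window sums are rescaled by the ratio of global median per-site
    depths (control/tumor) so that library-size differences cancel.  Windows
    covered by fewer than ``min_sites`` sites are emitted uncalled
    (z = NaN).  Both tables must be aligned on the same loci.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    if len(control) != len(tumor):
        raise ValueError("control/tumor tables must be aligned")
    if len(control) == 0:
        return pd.DataFrame(columns=WINDOW_COLUMNS)

    chrom = control["chrom"].astype(str).to_numpy()
    pos = control["pos"].to_numpy(dtype=np.int64)
    dc = control["depth"].to_numpy(dtype=float)
    dt = tumor["depth"].to_numpy(dtype=float)

    med_c = np.median(dc[dc > 0]) if (dc > 0).any() else 1.0
    med_t = np.median(dt[dt > 0]) if (dt > 0).any() else 1.0
    scale_t = med_c / med_t if med_t > 0 else 1.0

    win = (pos - 1) // window_size
    df = pd.DataFrame({"chrom": chrom, "win": win, "dc": dc, "dt": dt * scale_t})
    grouped = df.groupby(["chrom", "win"], sort=True).agg(
        n_sites=("dc", "size"), depth_c=("dc", "sum"), depth_t=("dt", "sum")
    )
    windows = grouped.reset_index()
    windows["start"] = windows["win"] * window_size
    windows["end"] = windows["start"] + window_size

    ok = (
        (windows["n_sites"] >= min_sites)
        & (windows["depth_c"] > 0)
        & (windows["depth_t"] > 0)
    ).to_numpy()
    w = np.full(len(windows), np.nan)
    w[ok] = windows.loc[ok, "depth_t"].to_numpy() / windows.loc[ok, "depth_c"].to_numpy()
    windows["w"] = w

    z = np.full(len(windows), np.nan)
    if ok.sum() >= 2:
        t_sums = windows.loc[ok, "depth_t"].to_numpy()
        c_sums = windows.loc[ok, "depth_c"].to_numpy()
        mu_t, mu_c = float(np.median(t_sums)), float(np.median(c_sums))
        sigma_t = max(_robust_sigma(t_sums), np.sqrt(max(mu_t, 1.0)))
        sigma_c = max(_robust_sigma(c_sums), np.sqrt(max(mu_c, 1.0)))
        z[ok] = gh_transform(w[ok], mu_t, sigma_t, mu_c, sigma_c)
    windows["z"] = z

    call = np.where(z >= z_crit, "gain", np.where(z <= -z_crit, "loss", "neutral"))
    call = np.where(np.isnan(z), "uncalled", call)
    windows["call"] = call
    return windows[WINDOW_COLUMNS]


def call_cnv(windows: pd.DataFrame, z_crit: float = 1.96, min_run: int = 2) -> pd.DataFrame:
    """Merge runs of >= ``min_run`` consecutive same-call windows into segments.

    Windows are re-thresholded at ``z_crit``; neutral or uncalled windows
    break runs, and runs shorter than ``min_run`` are dropped.
    """
    if len(windows) == 0:
        return pd.DataFrame(columns=SEGMENT_COLUMNS)
    df = windows.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    z = df["z"].to_numpy(dtype=float)
    call = np.where(z >= z_crit, "gain", np.where(z <= -z_crit, "loss", ""))
    call[np.isnan(z)] = ""

    segs = []
    run_start = run_end = None
    run_call = ""
    run_n = 0
    run_chrom = ""

    def flush():
        if run_call and run_n >= min_run:
            segs.append(
                {
                    "chrom": run_chrom,
                    "start": run_start,
                    "end": run_end,
                    "call": run_call,
                    "n_windows": run_n,
                }
            )

    for row, c in zip(df.itertuples(index=False), call):
        contiguous = (
            c
            and c == run_call
            and row.chrom == run_chrom
            and row.start == run_end
        )
        if contiguous:
            run_end = row.end
            run_n += 1
        else:
            flush()
            run_call, run_chrom, run_n = c, row.chrom, 1
            run_start, run_end = row.start, row.end
    flush()
    return pd.DataFrame(segs, columns=SEGMENT_COLUMNS)


def flag_copy_neutral(events: pd.DataFrame, segments: pd.DataFrame) -> pd.DataFrame:
    """Set ``copy_neutral`` = event does not fall in any gain/loss segment.

    Events in windows the caller left uncalled (or on chromosomes with no
    segments at all) count as copy-neutral: absence of evidence of CNV.  The
    boundary convention is half-open against the event coordinate: an event
    whose position equals a segment's ``end`` lies outside it.
    """
    out = events.copy()
    if len(out) == 0 or len(segments) == 0:
        out["copy_neutral"] = True
        return out
    neutral = np.ones(len(out), dtype=bool)
    pos = out["pos"].to_numpy(dtype=np.int64)
    chrom = out["chrom"].astype(str).to_numpy()
    for seg in segments.itertuples(index=False):
        hit = (chrom == str(seg.chrom)) & (pos >= seg.start) & (pos < seg.end)
        neutral &= ~hit
    out["copy_neutral"] = neutral
    return out
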