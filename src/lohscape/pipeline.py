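"""End-to-end cohort pipeline: call, CNV-flag, summarize, report."""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from lohscape import calling, cnv, io_formats, stats
from lohscape.core import DIALECTS

log = logging.getLogger(__name__)

MANIFEST_COLUMNS = ["sample_id", "group", "sex", "control", "tumor"]


def read_manifest(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest lacks columns {missing}")
    if df["sample_id"].duplicated().any():
        raise ValueError("manifest sample_ids must be unique")
    for _, row in df.iterrows():
        for col in ("control", "tumor"):
            if not Path(row[col]).exists():
                raise FileNotFoundError(f"{col} file missing for {row['sample_id']}: {row[col]}")
    return df


def process_pair(
    control_source,
    tumor_source,
    sample_id: str,
    dialect_name: str = "aluscan",
    window_size: int = 500_000,
    z_crit: float = 1.96,
    min_run: int = 2,
    min_sites: int = 10,
) -> tuple[calling.PairCallResult, pd.DataFrame, pd.DataFrame]:
    """Call one pair and flag events against its CNV segments.

    Returns (call result with copy_neutral set, windows, segments).
    """
    dialect = DIALECTS[dialect_name]
    control, tumor = io_formats.read_paired_sites(control_source, tumor_source)
    result = calling.call_pair_tables(control, tumor, dialect, sample_id=sample_id)
    windows = cnv.bin_depths(control, tumor, window_size=window_size, min_sites=min_sites, z_crit=z_crit)
    segments = cnv.call_cnv(windows, z_crit=z_crit, min_run=min_run)
    result.events = cnv.flag_copy_neutral(result.events, segments)
    return result, windows, segments


def run_pipeline(
    manifest: Union[str, Path, pd.DataFrame],
    dialect: str = "aluscan",
    out_dir: Optional[Union[str, Path]] = None,
    window_size: int = 500_000,
    z_crit: float = 1.96,
    min_run: int = 2,
    min_sites: int = 10,
) -> dict:
    """Cohort report: per-sample raw and copy-neutral rate rows plus sample
    and aggregate averages per group and overall, and the LOH preference
    profile.  Deterministic for a fixed manifest and configuration."""
    mf = manifest if isinstance(manifest, pd.DataFrame) else read_manifest(manifest)
    results = []
    summaries = []
    for row in mf.itertuples(index=False):
        log.info("processing %s", row.sample_id)
        result, _, segments = process_pair(
            row.control, row.tumor, row.sample_id, dialect,
            window_size=window_size, z_crit=z_crit, min_run=min_run, min_sites=min_sites,
        )
        results.append(result)
        for variant in ("raw", "copy_neutral"):
            summaries.append(stats.compute_rates(result, variant=variant, group=row.group))

    frame = stats.summaries_to_frame(summaries)
    all_events = pd.concat([r.events for r in results], ignore_index=True)
    profile = stats.preference_profile(all_events)

    averages = []
    for variant in ("raw", "copy_neutral"):
        sub = frame[frame["variant"] == variant]
        for scope, grp in [("all", sub)] + [(g, sub[sub["group"] == g]) for g in sub["group"].unique()]:
            if len(grp) == 0:
                continue
            av = stats.sample_average(grp)
            row = {"scope": scope, "variant": variant, "kind": "sample_average", "n": av.n}
            row.update({k: av.mean[k] for k in av.mean.index})
            averages.append(row)
            agg = stats.aggregate_average(grp, variant=variant)
            arow = {"scope": scope, "variant": variant, "kind": "aggregate_average", "n": len(grp)}
            arow.update({k: getattr(agg, k) for k in stats.RATE_FIELDS})
            averages.append(arow)
    averages_df = pd.DataFrame(averages)

    report = {
        "samples": frame,
        "averages": averages_df,
        "preference_counts": profile.counts,
        "results": results,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        frame.to_csv(out / "sample_rates.tsv", sep="\t", index=False)
        averages_df.to_csv(out / "cohort_averages.tsv", sep="\t", index=False)
        profile.counts.to_csv(out / "preference_profile.tsv", sep="\t")
        io_formats.write_events(all_events, out / "events.tsv", out / "events.bed")
        with open(out / "report.json", "w") as fh:
            json.dump(
                {
                    "dialect": dialect,
                    "cnv": {"window_size": window_size, "z_crit": z_crit, "min_run": min_run, "min_sites": min_sites},
                    "n_samples": int(len(mf)),
                },
                fh,
                indent=2,
            )
    return report
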