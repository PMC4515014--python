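"""Per-sample and cohort mutation-rate statistics.

Every rate is the percentage of control-side denominator sites of the
relevant genotype class that underwent the relevant change:

    R_Mm      = 100 * (LOH_to_MM + LOH_to_mm + HET_SWITCH) / n_Mm
    R_LOH     = 100 * (LOH_to_MM + LOH_to_mm) / n_Mm
    R_Mm->MM  = 100 * LOH_to_MM / n_Mm
    R_Mm->mm  = 100 * LOH_to_mm / n_Mm
    R_MM      = 100 * (GOH_M + HOM_SWITCH from MM) / n_MM
    R_GOH-M   = 100 * GOH_M / n_MM
    R_mm      = 100 * (GOH_m + HOM_SWITCH from mm) / n_mm
    R_GOH-m   = 100 * GOH_m / n_mm
    MM/mm     = R_Mm->MM / R_Mm->mm           (absent when R_Mm->mm = 0)

so R_LOH = R_Mm->MM + R_Mm->mm holds exactly by construction.  Two cohort
averages are distinguished: the *sample average* (unweighted mean +- SD of
per-sample rates, ratios averaged as per-sample ratios) and the *aggregate
average* (pooled event counts over pooled denominators).

A reference cohort of 30 published tumor-control rate rows (five each of
gastric, glioma, leukemia, liver, primary lung and lung-to-brain metastatic
cancers profiled by inter-Alu capture sequencing) ships with the package
for benchmarking the averaging operations; see :func:`load_reference_cohort`.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields
from importlib import resources
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

from lohscape.calling import PairCallResult
from lohscape.core import ChangeClass, EventKind, all_contexts

RATE_FIELDS = [
    "freq_MM",
    "freq_Mm",
    "freq_mm",
    "r_MM",
    "r_goh_M",
    "r_mm",
    "r_goh_m",
    "r_Mm",
    "r_loh",
    "r_Mm_to_MM",
    "r_Mm_to_mm",
    "mm_ratio",
]


@dataclass
class RateSummary:
    """One row of the per-sample rate report (all rates in percent)."""

    sample_id: str
    variant: str = "raw"
    group: str = ""
    total_positions: int = 0
    n_MM: int = 0
    n_Mm: int = 0
    n_mm: int = 0
    n_loh_to_MM: int = 0
    n_loh_to_mm: int = 0
    n_het_switch: int = 0
    n_goh_M: int = 0
    n_goh_m: int = 0
    n_hom_switch_MM: int = 0
    n_hom_switch_mm: int = 0
    freq_MM: float = np.nan
    freq_Mm: float = np.nan
    freq_mm: float = np.nan
    r_MM: float = np.nan
    r_goh_M: float = np.nan
    r_mm: float = np.nan
    r_goh_m: float = np.nan
    r_Mm: float = np.nan
    r_loh: float = np.nan
    r_Mm_to_MM: float = np.nan
    r_Mm_to_mm: float = np.nan
    mm_ratio: float = np.nan

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


def _rate(count: int, denom: int) -> float:
    """Percent rate; absent (NaN) when the denominator is zero."""
    return 100.0 * count / denom if denom > 0 else np.nan


def compute_rates(
    result: PairCallResult,
    variant: str = "raw",
    group: str = "",
) -> RateSummary:
    """Genotype frequencies and mutation rates for one tumor-control pair.

    ``variant="copy_neutral"`` counts only events flagged copy-neutral
    (CNV-overlapping events removed); the denominators are unchanged, so
    copy-neutral rates are never larger than raw rates.
    """
    if variant not in ("raw", "copy_neutral"):
        raise ValueError("variant must be 'raw' or 'copy_neutral'")
    ev = result.events
    if variant == "copy_neutral" and len(ev):
        ev = ev[ev["copy_neutral"]]

    def n(kind: EventKind, control_class: Optional[str] = None) -> int:
        if len(ev) == 0:
            return 0
        mask = ev["kind"] == kind.value
        if control_class is not None:
            mask &= ev["control_class"] == control_class
        return int(mask.sum())

    s = RateSummary(
        sample_id=result.sample_id,
        variant=variant,
        group=group,
        total_positions=result.n_co_callable,
        n_MM=result.n_MM,
        n_Mm=result.n_Mm,
        n_mm=result.n_mm,
        n_loh_to_MM=n(EventKind.LOH_TO_MM),
        n_loh_to_mm=n(EventKind.LOH_TO_mm),
        n_het_switch=n(EventKind.HET_SWITCH),
        n_goh_M=n(EventKind.GOH_M),
        n_goh_m=n(EventKind.GOH_m),
        n_hom_switch_MM=n(EventKind.HOM_SWITCH, "MM"),
        n_hom_switch_mm=n(EventKind.HOM_SWITCH, "mm"),
    )
    return _fill_rates(s)


def _fill_rates(s: RateSummary) -> RateSummary:
    total = s.total_positions
    s.freq_MM = _rate(s.n_MM, total)
    s.freq_Mm = _rate(s.n_Mm, total)
    s.freq_mm = _rate(s.n_mm, total)
    s.r_MM = _rate(s.n_goh_M + s.n_hom_switch_MM, s.n_MM)
    s.r_goh_M = _rate(s.n_goh_M, s.n_MM)
    s.r_mm = _rate(s.n_goh_m + s.n_hom_switch_mm, s.n_mm)
    s.r_goh_m = _rate(s.n_goh_m, s.n_mm)
    s.r_Mm = _rate(s.n_loh_to_MM + s.n_loh_to_mm + s.n_het_switch, s.n_Mm)
    s.r_Mm_to_MM = _rate(s.n_loh_to_MM, s.n_Mm)
    s.r_Mm_to_mm = _rate(s.n_loh_to_mm, s.n_Mm)
    # defined as the sum of its partition so the conservation identity is exact
    s.r_loh = s.r_Mm_to_MM + s.r_Mm_to_mm
    s.mm_ratio = (
        s.r_Mm_to_MM / s.r_Mm_to_mm
        if s.n_loh_to_mm > 0 and s.n_Mm > 0
        else np.nan
    )
    return s


def summaries_to_frame(summaries: Iterable[RateSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.to_dict() for s in summaries])


@dataclass
class CohortAverage:
    """Unweighted per-sample means and sample SDs of each rate."""

    mean: pd.Series
    sd: pd.Series
    n: int


def _as_frame(summaries: Union[pd.DataFrame, Sequence[RateSummary]]) -> pd.DataFrame:
    if isinstance(summaries, pd.DataFrame):
        return summaries
    return summaries_to_frame(summaries)


def sample_average(
    summaries: Union[pd.DataFrame, Sequence[RateSummary]],
    fields: Sequence[str] = tuple(RATE_FIELDS),
) -> CohortAverage:
    """Mean and sample SD of each rate across samples (ratio of-ratios
    averaged as per-sample values, matching the sample-average convention)."""
    df = _as_frame(summaries)
    if len(df) == 0:
        raise ValueError("sample_average requires at least one summary")
    cols = [f for f in fields if f in df.columns]
    sub = df[cols].astype(float)
    mean = sub.mean()
    sd = sub.std(ddof=1) if len(df) > 1 else pd.Series(np.nan, index=cols)
    return CohortAverage(mean=mean, sd=sd, n=len(df))


def aggregate_average(
    summaries: Union[pd.DataFrame, Sequence[RateSummary]],
    sample_id: str = "aggregate",
    variant: str = "raw",
) -> RateSummary:
    """Pooled-count rates: summed event counts over summed denominators."""
    df = _as_frame(summaries)
    if len(df) == 0:
        raise ValueError("aggregate_average requires at least one summary")
    count_cols = [
        "total_positions",
        "n_MM",
        "n_Mm",
        "n_mm",
        "n_loh_to_MM",
        "n_loh_to_mm",
        "n_het_switch",
        "n_goh_M",
        "n_goh_m",
        "n_hom_switch_MM",
        "n_hom_switch_mm",
    ]
    pooled = RateSummary(sample_id=sample_id, variant=variant)
    for col in count_cols:
        setattr(pooled, col, int(df[col].sum()))
    return _fill_rates(pooled)


@dataclass
class PreferenceProfile:
    """12-context x {to_MM, to_mm} LOH outcome counts with marginals."""

    counts: pd.DataFrame
    marginals: pd.DataFrame
    m_pref_ratio: pd.Series

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def ti_tv_ratio(self) -> float:
        ti = self.marginals.loc[ChangeClass.TRANSITION.value].sum()
        tv = self.marginals.loc[ChangeClass.TRANSVERSION.value].sum()
        return float(ti / tv) if tv > 0 else np.inf


def preference_profile(events: pd.DataFrame) -> PreferenceProfile:
    """Tabulate LOH events by heterozygote context and homozygous outcome.

    ``m_pref_ratio`` is the per-context preference for the reference-allele
    outcome: count(to_MM) / count(to_mm), infinite when no to_mm events.
    """
    contexts = all_contexts()
    counts = pd.DataFrame(0, index=pd.Index(contexts, name="context"), columns=["to_MM", "to_mm"])
    if len(events):
        loh = events[events["kind"].isin([EventKind.LOH_TO_MM.value, EventKind.LOH_TO_mm.value])]
        for ctx, kind in zip(loh["mm_context"], loh["kind"]):
            col = "to_MM" if kind == EventKind.LOH_TO_MM.value else "to_mm"
            counts.loc[ctx, col] += 1
    klass = pd.Series(
        [
            ChangeClass.TRANSITION.value
            if frozenset({c[0], c[1].upper()}) in ({frozenset("AG"), frozenset("CT")})
            else ChangeClass.TRANSVERSION.value
            for c in contexts
        ],
        index=counts.index,
    )
    marginals = counts.groupby(klass).sum()
    marginals.index.name = "change_class"
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = counts["to_MM"] / counts["to_mm"]
    return PreferenceProfile(counts=counts, marginals=marginals, m_pref_ratio=ratio)


@dataclass
class GroupComparison:
    """Welch two-sample t-test between per-sample rates of two groups."""

    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    t: float
    df: float
    p_value: float
    test: str = "welch_t"


def compare_groups(
    summaries: Union[pd.DataFrame, Sequence[RateSummary]],
    group_col: str = "group",
    value_col: str = "r_loh",
    groups: Optional[tuple[str, str]] = None,
) -> GroupComparison:
    """Two-sided Welch (unequal-variance) t-test on a per-sample rate.

    The unequal-variance form is appropriate because solid tumors show an
    order of magnitude more spread in LOH rates than leukemias.
    """
    df = _as_frame(summaries)
    if groups is None:
        uniq = list(pd.unique(df[group_col]))
        if len(uniq) != 2:
            raise ValueError(f"expected exactly 2 groups, found {uniq}")
        groups = (uniq[0], uniq[1])
    a = df.loc[df[group_col] == groups[0], value_col].astype(float).to_numpy()
    b = df.loc[df[group_col] == groups[1], value_col].astype(float).to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 samples")
    res = sps.ttest_ind(a, b, equal_var=False)
    return GroupComparison(
        group_a=groups[0],
        group_b=groups[1],
        n_a=len(a),
        n_b=len(b),
        mean_a=float(np.mean(a)),
        mean_b=float(np.mean(b)),
        sd_a=float(np.std(a, ddof=1)),
        sd_b=float(np.std(b, ddof=1)),
        t=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
    )


def load_reference_cohort() -> pd.DataFrame:
    """The bundled 30-sample reference cohort, rates converted to percent.

    Columns ``r_MM`` and ``r_goh_M`` are stored on a 1e-3 % scale and
    ``freq_mm``/``freq_Mm`` on a 1e-2 % scale in the TSV (the scales on
    which they are conventionally printed); the loader converts everything
    to plain percent and adds a ``group_class`` column (solid vs leukemia).
    """
    with resources.files("lohscape.data").joinpath("cohort_rates.tsv").open() as fh:
        raw = pd.read_csv(fh, sep="\t")
    df = pd.DataFrame(
        {
            "sample_id": raw["sample"],
            "group": raw["group"],
            "sex": raw["sex"],
            "total_mb": raw["total_mb"],
            "freq_MM": raw["freq_MM_pct"],
            "freq_mm": raw["freq_mm_e2pct"] * 1e-2,
            "freq_Mm": raw["freq_Mm_e2pct"] * 1e-2,
            "r_MM": raw["r_MM_e3pct"] * 1e-3,
            "r_goh_M": raw["r_goh_M_e3pct"] * 1e-3,
            "r_mm": raw["r_mm_pct"],
            "r_goh_m": raw["r_goh_m_pct"],
            "r_Mm": raw["r_Mm_pct"],
            "r_loh": raw["r_loh_pct"],
            "r_Mm_to_MM": raw["r_Mm_to_MM_pct"],
            "r_Mm_to_mm": raw["r_Mm_to_mm_pct"],
            "mm_ratio": raw["mm_ratio"],
        }
    )
    df["group_class"] = np.where(df["group"] == "leukemia", "leukemia", "solid")
    return df
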