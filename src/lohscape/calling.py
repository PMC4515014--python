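"""Dialect genotype filtering and paired LOH/GOH event classification.

Two equivalent code paths are provided: a scalar path over
:class:`~lohscape.core.SiteObservation` objects (`call_genotype`,
`classify_pair`, `call_all`) that transcribes the filtering rules one
condition at a time, and a vectorized path over site tables
(`call_table`, `call_pair_tables`) used for cohort-scale data.  The test
suite holds the two paths to exact agreement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from lohscape.core import (
    ChangeClass,
    EventKind,
    FilterDialect,
    GenotypeCall,
    GenotypeClass,
    Locus,
    MutationEvent,
    SiteObservation,
    UNCALLABLE_CALL,
    classify_change,
    mm_context_label,
)

# integer genotype-class codes used by the vectorized path
MM, HET, HOM_ALT, UNC = 0, 1, 2, 3
CLASS_OF_CODE = {
    MM: GenotypeClass.MM,
    HET: GenotypeClass.Mm,
    HOM_ALT: GenotypeClass.mm,
    UNC: GenotypeClass.UNCALLABLE,
}

EVENT_COLUMNS = [
    "sample_id",
    "chrom",
    "pos",
    "ref",
    "control_class",
    "tumor_class",
    "control_m",
    "tumor_m",
    "kind",
    "mm_context",
    "change_class",
    "copy_neutral",
]


def _strand_ok(obs: SiteObservation, dialect: FilterDialect) -> bool:
    if dialect.sb_max is not None:
        return obs.sb is not None and obs.sb < dialect.sb_max
    return obs.fs is not None and obs.fs <= dialect.fs_max


def call_genotype(obs: SiteObservation, dialect: FilterDialect) -> GenotypeCall:
    """Apply one dialect's filters to a single observation.

    The non-reference fraction is taken over informative reads
    (ad_ref + ad_alt).  Homozygous calls demand a fraction of exactly 0
    (reference) or 1 (non-reference) with no tolerance: this strictness is
    what protects LOH calls against tumor-impurity remnant reads.  Missing
    annotations required by the dialect fail the filter rather than pass it.
    """
    if obs.depth < dialect.min_depth:
        return UNCALLABLE_CALL
    informative = obs.ad_ref + obs.ad_alt
    if informative == 0:
        return UNCALLABLE_CALL
    frac = obs.ad_alt / informative

    if frac == 0.0:
        if dialect.qd_hom_ref is not None:
            if obs.qd is None or obs.qd < dialect.qd_hom_ref:
                return UNCALLABLE_CALL
        return GenotypeCall(GenotypeClass.MM)

    if obs.locus.alt_base is None:
        return UNCALLABLE_CALL

    if frac == 1.0:
        if obs.qd is not None and obs.qd >= dialect.qd_hom_nonref and _strand_ok(obs, dialect):
            return GenotypeCall(GenotypeClass.mm, obs.locus.alt_base)
        return UNCALLABLE_CALL

    if dialect.het_af_lo <= frac <= dialect.het_af_hi:
        if obs.qd is not None and obs.qd >= dialect.qd_het and _strand_ok(obs, dialect):
            return GenotypeCall(GenotypeClass.Mm, obs.locus.alt_base)
    return UNCALLABLE_CALL


@dataclass(frozen=True)
class PairedSite:
    """Co-located control and tumor calls at one locus."""

    locus: Locus
    control: GenotypeCall
    tumor: GenotypeCall

    @property
    def co_callable(self) -> bool:
        return self.control.callable and self.tumor.callable


def classify_pair(site: PairedSite, sample_id: str = "") -> Optional[MutationEvent]:
    """Classify a co-callable pair into the six-way event taxonomy.

    Returns ``None`` for an unchanged genotype.  Raises if either member is
    UNCALLABLE (such sites must never reach classification).
    """
    if not site.co_callable:
        raise ValueError("classify_pair requires a co-callable site")
    c, t = site.control, site.tumor
    cg, tg = c.gclass, t.gclass
    kind: Optional[EventKind] = None

    if cg is GenotypeClass.Mm:
        if tg is GenotypeClass.MM:
            kind = EventKind.LOH_TO_MM
        elif tg is GenotypeClass.mm:
            kind = EventKind.LOH_TO_mm if t.m_base == c.m_base else EventKind.HET_SWITCH
        elif tg is GenotypeClass.Mm and t.m_base != c.m_base:
            kind = EventKind.HET_SWITCH
    elif cg is GenotypeClass.MM:
        if tg is GenotypeClass.Mm:
            kind = EventKind.GOH_M
        elif tg is GenotypeClass.mm:
            kind = EventKind.HOM_SWITCH
    elif cg is GenotypeClass.mm:
        if tg is GenotypeClass.Mm:
            kind = EventKind.GOH_m
        elif tg is GenotypeClass.MM:
            kind = EventKind.HOM_SWITCH
        elif tg is GenotypeClass.mm and t.m_base != c.m_base:
            kind = EventKind.HOM_SWITCH

    if kind is None:
        return None
    context_m = t.m_base if t.m_base is not None else c.m_base
    context = mm_context_label(site.locus.ref_base, context_m)
    return MutationEvent(
        locus=site.locus,
        sample_id=sample_id,
        kind=kind,
        control_call=c,
        tumor_call=t,
        mm_context=context,
        change_class=classify_change(site.locus.ref_base, context_m),
    )


@dataclass
class PairCallResult:
    """Sufficient statistics from calling one tumor-control pair.

    ``n_MM``/``n_Mm``/``n_mm`` are control-side genotype counts over
    co-callable sites and are the denominators of every downstream rate.
    ``events`` is a flat table (one row per classified change);
    ``retained_het`` lists co-callable sites that stayed heterozygous with
    the same minor allele (needed to delimit LOH fragment runs).
    """

    sample_id: str
    dialect: str
    n_co_callable: int
    n_MM: int
    n_Mm: int
    n_mm: int
    events: pd.DataFrame
    retained_het: pd.DataFrame
    per_chrom: pd.DataFrame
    pairs: Optional[list] = field(default=None, repr=False)


def call_all(
    stream: Iterable[tuple[Locus, SiteObservation, SiteObservation]],
    dialect: FilterDialect,
    sample_id: str = "",
) -> PairCallResult:
    """Scalar pipeline over a sorted paired stream.

    Calls both members at every co-present position, keeps co-callable sites
    only, and accumulates denominators and events.
    """
    pairs: list[PairedSite] = []
    rows: list[dict] = []
    retained: list[dict] = []
    counts = {GenotypeClass.MM: 0, GenotypeClass.Mm: 0, GenotypeClass.mm: 0}
    per_chrom: dict[str, dict[str, int]] = {}

    for locus, obs_c, obs_t in stream:
        site = PairedSite(locus, call_genotype(obs_c, dialect), call_genotype(obs_t, dialect))
        pairs.append(site)
        if not site.co_callable:
            continue
        counts[site.control.gclass] += 1
        pc = per_chrom.setdefault(
            locus.chrom, {"n_MM": 0, "n_Mm": 0, "n_mm": 0, "n_co": 0}
        )
        pc["n_co"] += 1
        pc[f"n_{site.control.gclass.value}"] += 1
        event = classify_pair(site, sample_id)
        if event is None:
            if site.control.gclass is GenotypeClass.Mm:
                retained.append({"chrom": locus.chrom, "pos": locus.pos})
        else:
            rows.append(
                {
                    "sample_id": sample_id,
                    "chrom": locus.chrom,
                    "pos": locus.pos,
                    "ref": locus.ref_base,
                    "control_class": site.control.gclass.value,
                    "tumor_class": site.tumor.gclass.value,
                    "control_m": site.control.m_base or "",
                    "tumor_m": site.tumor.m_base or "",
                    "kind": event.kind.value,
                    "mm_context": event.mm_context,
                    "change_class": event.change_class.value,
                    "copy_neutral": True,
                }
            )

    events = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    retained_df = pd.DataFrame(retained, columns=["chrom", "pos"])
    per_chrom_df = (
        pd.DataFrame.from_dict(per_chrom, orient="index")
        .rename_axis("chrom")
        .reset_index()
        if per_chrom
        else pd.DataFrame(columns=["chrom", "n_MM", "n_Mm", "n_mm", "n_co"])
    )
    return PairCallResult(
        sample_id=sample_id,
        dialect=dialect.name,
        n_co_callable=sum(counts.values()),
        n_MM=counts[GenotypeClass.MM],
        n_Mm=counts[GenotypeClass.Mm],
        n_mm=counts[GenotypeClass.mm],
        events=events,
        retained_het=retained_df,
        per_chrom=per_chrom_df,
        pairs=pairs,
    )


# ---------------------------------------------------------------------------
# vectorized path


def call_table(table: pd.DataFrame, dialect: FilterDialect) -> np.ndarray:
    """Vectorized genotype calling; returns integer class codes (0=MM, 1=Mm,
    2=mm, 3=UNCALLABLE) aligned with ``table`` rows."""
    depth = table["depth"].to_numpy(dtype=np.int64)
    ad_ref = table["ad_ref"].to_numpy(dtype=np.int64)
    ad_alt = table["ad_alt"].to_numpy(dtype=np.int64)
    if (depth < 0).any() or (ad_ref + ad_alt > depth).any():
        raise ValueError("invalid observation: negative depth or AD sum > depth")
    qd = table["qd"].to_numpy(dtype=float) if "qd" in table else np.full(len(table), np.nan)
    has_alt = table["alt"].fillna("").astype(str).str.len().to_numpy() > 0

    informative = ad_ref + ad_alt
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(informative > 0, ad_alt / np.maximum(informative, 1), np.nan)
    base_ok = (depth >= dialect.min_depth) & (informative > 0)

    if dialect.sb_max is not None:
        sb = table["sb"].to_numpy(dtype=float) if "sb" in table else np.full(len(table), np.nan)
        strand_ok = ~np.isnan(sb) & (sb < dialect.sb_max)
    else:
        fs = table["fs"].to_numpy(dtype=float) if "fs" in table else np.full(len(table), np.nan)
        strand_ok = ~np.isnan(fs) & (fs <= dialect.fs_max)
    qd_ok_het = ~np.isnan(qd) & (qd >= dialect.qd_het)
    qd_ok_hom = ~np.isnan(qd) & (qd >= dialect.qd_hom_nonref)
    if dialect.qd_hom_ref is not None:
        hom_ref_ok = ~np.isnan(qd) & (qd >= dialect.qd_hom_ref)
    else:
        hom_ref_ok = np.ones(len(table), dtype=bool)

    codes = np.full(len(table), UNC, dtype=np.int8)
    codes[base_ok & (frac == 0.0) & hom_ref_ok] = MM
    codes[base_ok & (frac == 1.0) & has_alt & qd_ok_hom & strand_ok] = HOM_ALT
    is_het = (
        base_ok
        & (frac >= dialect.het_af_lo)
        & (frac <= dialect.het_af_hi)
        & has_alt
        & qd_ok_het
        & strand_ok
    )
    codes[is_het] = HET
    return codes


_TI_SET = {frozenset({"A", "G"}), frozenset({"C", "T"})}


def _change_classes(ref: np.ndarray, m: np.ndarray) -> np.ndarray:
    out = np.empty(len(ref), dtype=object)
    for i in range(len(ref)):
        out[i] = (
            ChangeClass.TRANSITION.value
            if frozenset({ref[i], m[i]}) in _TI_SET
            else ChangeClass.TRANSVERSION.value
        )
    return out


def call_pair_tables(
    control: pd.DataFrame,
    tumor: pd.DataFrame,
    dialect: FilterDialect,
    sample_id: str = "",
) -> PairCallResult:
    """Vectorized calling and classification of an aligned site-table pair.

    Both tables must describe the same loci in the same order (the output of
    :func:`lohscape.io_formats.read_paired_sites` or of the generator).
    """
    for col in ("chrom", "pos", "ref"):
        if not np.array_equal(control[col].to_numpy(), tumor[col].to_numpy()):
            raise ValueError(f"control/tumor tables disagree on {col}")

    cc = call_table(control, dialect)
    tc = call_table(tumor, dialect)
    co = (cc != UNC) & (tc != UNC)

    chrom = control["chrom"].astype(str).to_numpy()
    pos = control["pos"].to_numpy(dtype=np.int64)
    ref = control["ref"].astype(str).to_numpy()
    ca = control["alt"].fillna("").astype(str).to_numpy()
    ta = tumor["alt"].fillna("").astype(str).to_numpy()
    same_m = ca == ta

    kind = np.full(len(control), "", dtype=object)
    kind[co & (cc == HET) & (tc == MM)] = EventKind.LOH_TO_MM.value
    kind[co & (cc == HET) & (tc == HOM_ALT) & same_m] = EventKind.LOH_TO_mm.value
    kind[co & (cc == HET) & (tc == HOM_ALT) & ~same_m] = EventKind.HET_SWITCH.value
    kind[co & (cc == HET) & (tc == HET) & ~same_m] = EventKind.HET_SWITCH.value
    kind[co & (cc == MM) & (tc == HET)] = EventKind.GOH_M.value
    kind[co & (cc == HOM_ALT) & (tc == HET)] = EventKind.GOH_m.value
    kind[co & (cc == MM) & (tc == HOM_ALT)] = EventKind.HOM_SWITCH.value
    kind[co & (cc == HOM_ALT) & (tc == MM)] = EventKind.HOM_SWITCH.value
    kind[co & (cc == HOM_ALT) & (tc == HOM_ALT) & ~same_m] = EventKind.HOM_SWITCH.value
    is_event = kind != ""

    tumor_has_m = (tc == HET) | (tc == HOM_ALT)
    context_m = np.where(tumor_has_m, ta, ca)

    idx = np.flatnonzero(is_event)
    class_names = np.array([c.value for c in CLASS_OF_CODE.values()], dtype=object)
    ev_ref = ref[idx]
    ev_m = context_m[idx]
    events = pd.DataFrame(
        {
            "sample_id": sample_id,
            "chrom": chrom[idx],
            "pos": pos[idx],
            "ref": ev_ref,
            "control_class": class_names[cc[idx]],
            "tumor_class": class_names[tc[idx]],
            "control_m": ca[idx],
            "tumor_m": ta[idx],
            "kind": kind[idx],
            "mm_context": pd.Series(ev_ref, dtype=object).str.cat(
                pd.Series(ev_m, dtype=object).str.lower()
            )
            if len(idx)
            else pd.Series([], dtype=object),
            "change_class": _change_classes(ev_ref, ev_m),
            "copy_neutral": True,
        },
        columns=EVENT_COLUMNS,
    )

    retained_mask = co & (cc == HET) & (tc == HET) & same_m
    retained = pd.DataFrame({"chrom": chrom[retained_mask], "pos": pos[retained_mask]})

    per_chrom = (
        pd.DataFrame(
            {
                "chrom": chrom[co],
                "n_MM": (cc[co] == MM).astype(int),
                "n_Mm": (cc[co] == HET).astype(int),
                "n_mm": (cc[co] == HOM_ALT).astype(int),
                "n_co": 1,
            }
        )
        .groupby("chrom", as_index=False, sort=True)
        .sum()
    )

    return PairCallResult(
        sample_id=sample_id,
        dialect=dialect.name,
        n_co_callable=int(co.sum()),
        n_MM=int((cc[co] == MM).sum()),
        n_Mm=int((cc[co] == HET).sum()),
        n_mm=int((cc[co] == HOM_ALT).sum()),
        events=events,
        retained_het=retained,
        per_chrom=per_chrom,
    )
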