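"""Genotype filtering and paired-event classification.

The decision-table oracle below is coded independently of the production
classifier: it works on explicit allele multisets rather than genotype
class codes, so agreement between the two is a real cross-check.
"""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lohscape.calling import (
    PairedSite,
    call_all,
    call_genotype,
    call_pair_tables,
    call_table,
    classify_pair,
)
from lohscape.core import (
    ALUSCAN,
    WGS,
    GenotypeCall,
    GenotypeClass,
    Locus,
    SiteObservation,
)

L = Locus("1", 1000, "A", "G")


def obs(depth, ad_alt, qd=30.0, sb=-1.0, fs=0.0, locus=L):
    return SiteObservation(locus, depth=depth, ad_ref=depth - ad_alt, ad_alt=ad_alt, qd=qd, sb=sb, fs=fs)


class TestCallGenotype:
    @pytest.mark.parametrize(
        "dialect,o,expected",
        [
            # below minimum depth in either member: not analyzed
            (ALUSCAN, obs(7, 3), GenotypeClass.UNCALLABLE),
            # 50 % non-reference within the [35, 65] band, QD and SB pass
            (ALUSCAN, obs(10, 5, qd=10.0, sb=-0.5), GenotypeClass.Mm),
            # 25 % non-reference: below the het band, not 0 or 100 %
            (ALUSCAN, obs(8, 2), GenotypeClass.UNCALLABLE),
            # hom-ref at depth 8, no QD requirement in the capture dialect
            (ALUSCAN, obs(8, 0, qd=None, sb=None), GenotypeClass.MM),
            # hom non-ref requires QD >= 20
            (ALUSCAN, obs(10, 10, qd=25.0, sb=-1.0), GenotypeClass.mm),
            (ALUSCAN, obs(10, 10, qd=19.0, sb=-1.0), GenotypeClass.UNCALLABLE),
            # SB filter: pass requires sb < -0.01; missing SB fails
            (ALUSCAN, obs(10, 5, qd=10.0, sb=0.5), GenotypeClass.UNCALLABLE),
            (ALUSCAN, obs(10, 5, qd=10.0, sb=None), GenotypeClass.UNCALLABLE),
            # wgs hom-ref requires QD >= 1
            (WGS, obs(20, 0, qd=0.5), GenotypeClass.UNCALLABLE),
            (WGS, obs(20, 0, qd=2.0), GenotypeClass.MM),
            # wgs het band is [25, 75] with FS <= 12
            (WGS, obs(20, 6, qd=10.0, fs=3.0), GenotypeClass.Mm),
            (WGS, obs(20, 6, qd=10.0, fs=20.0), GenotypeClass.UNCALLABLE),
            (WGS, obs(14, 7, qd=10.0, fs=3.0), GenotypeClass.UNCALLABLE),
        ],
    )
    def test_filter_rules(self, dialect, o, expected):
        assert call_genotype(o, dialect).gclass is expected

    def test_hom_calls_are_exact(self):
        # a single discordant read disqualifies both homozygous classes
        assert call_genotype(obs(100, 1), ALUSCAN).gclass is GenotypeClass.UNCALLABLE
        assert call_genotype(obs(100, 99, qd=30.0), ALUSCAN).gclass is GenotypeClass.UNCALLABLE

    @given(depth=st.integers(8, 200), ad_alt=st.integers(0, 200))
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_het_call_implies_minimum_alt_evidence(self, depth, ad_alt):
        """At depth >= 8 a heterozygous call requires >= ceil(0.35 * depth)
        non-reference reads, hence at least three."""
        ad_alt = min(ad_alt, depth)
        call = call_genotype(obs(depth, ad_alt), ALUSCAN)
        if call.gclass is GenotypeClass.Mm:
            assert ad_alt >= math.ceil(0.35 * depth) >= 3


# ---------------------------------------------------------------------------
# independent decision-table oracle over allele multisets


def oracle_kind(control, tumor):
    """Event kind from explicit allele pairs, or None.

    A genotype is represented as a sorted pair of bases; 'A' is the
    reference at the test locus.
    """
    ref = "A"

    def alleles(call):
        if call.gclass is GenotypeClass.MM:
            return (ref, ref)
        if call.gclass is GenotypeClass.Mm:
            return tuple(sorted((ref, call.m_base)))
        return (call.m_base, call.m_base)

    ac, at = alleles(control), alleles(tumor)
    het_c, het_t = ac[0] != ac[1], at[0] != at[1]
    if ac == at:
        return None
    if het_c and not het_t:
        # heterozygote resolved to a homozygote
        if at[0] == ref:
            return "LOH_to_MM"
        if at[0] in ac:
            return "LOH_to_mm"
        return "HET_SWITCH"  # homozygote for an allele absent from control
    if het_c and het_t:
        return "HET_SWITCH"
    if not het_c and het_t:
        return "GOH_M" if ac[0] == ref else "GOH_m"
    return "HOM_SWITCH"


def all_calls():
    yield GenotypeCall(GenotypeClass.MM)
    for m in "CGT":
        yield GenotypeCall(GenotypeClass.Mm, m)
        yield GenotypeCall(GenotypeClass.mm, m)


class TestClassifyPair:
    def test_agrees_with_oracle_on_all_constructible_pairs(self):
        n_checked = 0
        for c, t in itertools.product(all_calls(), repeat=2):
            site = PairedSite(L, c, t)
            event = classify_pair(site)
            got = None if event is None else event.kind.value
            assert got == oracle_kind(c, t), f"{c} -> {t}"
            n_checked += 1
        assert n_checked == 49

    def test_taxonomy_is_exhaustive_and_exclusive(self):
        # every co-callable pair maps to exactly one kind or to no-event
        outcomes = [classify_pair(PairedSite(L, c, t)) for c, t in itertools.product(all_calls(), repeat=2)]
        n_events = sum(1 for e in outcomes if e is not None)
        n_null = sum(1 for e in outcomes if e is None)
        assert n_events + n_null == 49
        # identical genotypes are exactly the no-event cases
        assert n_null == 7

    @pytest.mark.parametrize(
        "c,t,kind",
        [
            (GenotypeCall(GenotypeClass.Mm, "G"), GenotypeCall(GenotypeClass.MM), "LOH_to_MM"),
            (GenotypeCall(GenotypeClass.Mm, "G"), GenotypeCall(GenotypeClass.mm, "G"), "LOH_to_mm"),
            (GenotypeCall(GenotypeClass.MM), GenotypeCall(GenotypeClass.Mm, "T"), "GOH_M"),
            (GenotypeCall(GenotypeClass.mm, "G"), GenotypeCall(GenotypeClass.Mm, "G"), "GOH_m"),
            (GenotypeCall(GenotypeClass.Mm, "G"), GenotypeCall(GenotypeClass.Mm, "T"), "HET_SWITCH"),
            (GenotypeCall(GenotypeClass.MM), GenotypeCall(GenotypeClass.mm, "C"), "HOM_SWITCH"),
        ],
    )
    def test_named_examples(self, c, t, kind):
        event = classify_pair(PairedSite(L, c, t))
        assert event is not None and event.kind.value == kind

    def test_no_event_for_identical_genotypes(self):
        assert classify_pair(PairedSite(L, GenotypeCall(GenotypeClass.MM), GenotypeCall(GenotypeClass.MM))) is None

    def test_uncallable_member_rejected(self):
        from lohscape.core import UNCALLABLE_CALL

        with pytest.raises(ValueError):
            classify_pair(PairedSite(L, UNCALLABLE_CALL, GenotypeCall(GenotypeClass.MM)))


class TestCallAll:
    def _stream(self):
        sites = []
        for i in range(10):
            pos = 100 + i * 10
            if i == 0:
                locus = Locus("1", pos, "A", "G")  # Mm -> MM : the LOH
                c = obs(20, 10, locus=locus)
                t = obs(20, 0, locus=locus)
            elif i == 1:
                locus = Locus("1", pos, "C", "T")  # retained heterozygote
                c = obs(20, 10, locus=locus)
                t = obs(20, 10, locus=locus)
            elif i == 2:
                locus = Locus("1", pos, "G", "A")  # hom non-ref, unchanged
                c = obs(20, 20, locus=locus)
                t = obs(20, 20, locus=locus)
            else:
                locus = Locus("1", pos, "T", None)
                c = obs(20, 0, locus=locus)
                t = obs(20, 0, locus=locus)
            sites.append((locus, c, t))
        return sites

    def test_denominators_and_events(self):
        res = call_all(self._stream(), ALUSCAN, sample_id="s")
        assert (res.n_MM, res.n_Mm, res.n_mm) == (7, 2, 1)
        assert res.n_co_callable == 10
        assert list(res.events["kind"]) == ["LOH_to_MM"]
        assert len(res.retained_het) == 1

    def test_empty_stream(self):
        res = call_all([], ALUSCAN)
        assert res.n_co_callable == 0 and len(res.events) == 0

    def test_tumor_uncallable_site_excluded_from_denominators(self):
        locus = Locus("1", 100, "A", "G")
        stream = [(locus, obs(20, 10, locus=locus), obs(7, 3, locus=locus))]
        res = call_all(stream, ALUSCAN)
        assert res.n_co_callable == 0 and res.n_Mm == 0


class TestVectorizedEquivalence:
    def _random_table(self, rng, n=400):
        depth = rng.integers(0, 40, n)
        ad_alt = (depth * rng.random(n)).astype(int)
        ad_alt[rng.random(n) < 0.3] = 0
        full = rng.random(n) < 0.2
        ad_alt[full] = depth[full]
        return pd.DataFrame(
            {
                "sample_id": "s",
                "chrom": "1",
                "pos": np.arange(1, n + 1) * 10,
                "ref": "A",
                "alt": rng.choice(["G", "T", "C", ""], n),
                "depth": depth,
                "ad_ref": depth - ad_alt,
                "ad_alt": ad_alt,
                "qd": rng.choice([np.nan, 0.5, 5.0, 25.0, 40.0], n),
                "sb": rng.choice([np.nan, -2.0, -0.005, 0.3], n),
                "fs": rng.choice([np.nan, 0.0, 5.0, 30.0], n),
            }
        )

    @pytest.mark.parametrize("dialect", [ALUSCAN, WGS], ids=["aluscan", "wgs"])
    def test_call_table_matches_scalar_calls(self, dialect):
        rng = np.random.default_rng(42)
        table = self._random_table(rng)
        codes = call_table(table, dialect)
        for i, row in table.iterrows():
            locus = Locus(row.chrom, int(row.pos), row.ref, row.alt or None)
            o = SiteObservation(
                locus,
                depth=int(row.depth),
                ad_ref=int(row.ad_ref),
                ad_alt=int(row.ad_alt),
                qd=None if np.isnan(row.qd) else row.qd,
                sb=None if np.isnan(row.sb) else row.sb,
                fs=None if np.isnan(row.fs) else row.fs,
            )
            scalar = call_genotype(o, dialect)
            vec = {0: GenotypeClass.MM, 1: GenotypeClass.Mm, 2: GenotypeClass.mm, 3: GenotypeClass.UNCALLABLE}[codes[i]]
            assert scalar.gclass is vec, f"row {i}: {row.to_dict()}"

    def test_pair_tables_match_scalar_pipeline(self, small_cohort):
        sid, sex, control, tumor, truth = small_cohort[0]
        sub = slice(0, 4000)
        c, t = control.iloc[sub].reset_index(drop=True), tumor.iloc[sub].reset_index(drop=True)
        vec = call_pair_tables(c, t, ALUSCAN, sample_id=sid)

        stream = []
        for rc, rt in zip(c.itertuples(index=False), t.itertuples(index=False)):
            # locus alt differs per sample; classification uses each side's alt
            def mk(row):
                locus = Locus(row.chrom, int(row.pos), row.ref, row.alt or None)
                return SiteObservation(
                    locus, depth=int(row.depth), ad_ref=int(row.ad_ref), ad_alt=int(row.ad_alt),
                    qd=row.qd, sb=row.sb, fs=row.fs,
                )
            oc, ot = mk(rc), mk(rt)
            stream.append((oc.locus, oc, ot))
        # scalar path shares the tumor locus for the tumor call
        from lohscape.calling import call_genotype as cg

        n_events = 0
        for (locus, oc, ot) in stream:
            cc = cg(oc, ALUSCAN)
            tc = cg(ot, ALUSCAN)
            if cc.callable and tc.callable:
                if classify_pair(PairedSite(locus, cc, tc)) is not None:
                    n_events += 1
        assert n_events == len(vec.events)


class TestLohEvidenceProperty:
    def test_lost_allele_has_zero_reads(self, small_cohort, called_cohort):
        """Every LOH event's tumor observation shows 0 reads of the lost allele."""
        checked = 0
        for (sid, sex, control, tumor, truth), res in zip(small_cohort, called_cohort):
            loh = res.events[res.events["kind"].isin(["LOH_to_MM", "LOH_to_mm"])]
            merged = loh.merge(tumor, on=["chrom", "pos"])
            to_mm_mask = merged["kind"] == "LOH_to_MM"
            assert (merged.loc[to_mm_mask, "ad_alt"] == 0).all()
            assert (merged.loc[~to_mm_mask, "ad_ref"] == 0).all()
            checked += len(merged)
        assert checked > 0
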