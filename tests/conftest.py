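import pandas as pd
import pytest

from lohscape.calling import call_pair_tables
from lohscape.core import ALUSCAN
from lohscape.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def dense_cfg():
    """Small, heterozygote-dense configuration for fast unit tests.

    Densities are boosted relative to the generator defaults so that a few
    hundred thousand sites produce enough events of every kind; rates and
    biases stay at their defaults.
    """
    return SimConfig(
        seed=101,
        n_samples=4,
        n_positions=120_000,
        freq_Mm=4e-3,
        freq_mm=2.8e-3,
        goh_M_rate=2e-4,
    )


@pytest.fixture(scope="session")
def small_cohort(dense_cfg):
    """(sample_id, sex, control, tumor, truth) tuples for 4 simulated pairs."""
    return simulate_cohort(dense_cfg)


@pytest.fixture(scope="session")
def called_cohort(small_cohort):
    """PairCallResult per simulated pair (aluscan dialect)."""
    return [
        call_pair_tables(control, tumor, ALUSCAN, sample_id=sid)
        for sid, sex, control, tumor, truth in small_cohort
    ]


@pytest.fixture(scope="session")
def cohort_sexes(small_cohort):
    return {sid: sex for sid, sex, *_ in small_cohort}


def make_events(rows):
    """Minimal event table from (sample_id, chrom, pos, ref, m, kind,
    control_class, tumor_class) tuples; used to drive stats/landscape ops."""
    from lohscape.core import classify_change

    recs = []
    for sample_id, chrom, pos, ref, m, kind, cclass, tclass in rows:
        recs.append(
            {
                "sample_id": sample_id,
                "chrom": chrom,
                "pos": pos,
                "ref": ref,
                "control_class": cclass,
                "tumor_class": tclass,
                "control_m": m,
                "tumor_m": m,
                "kind": kind,
                "mm_context": ref + m.lower(),
                "change_class": classify_change(ref, m).value,
                "copy_neutral": True,
            }
        )
    return pd.DataFrame(recs)
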