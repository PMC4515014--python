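"""Seeded generator of paired control/tumor site tables with known truth.

The generator emulates the statistical structure of Mb-scale paired capture
sequencing of a tumor and its matched control: control genotypes are drawn
from reference-oriented priors (MM ~ 99.96 %, Mm ~ 2.4e-2 %, mm ~ 1.7e-2 %
of sites), the tumor genome is derived from the control by an
interhomolog-recombination-style LOH process applied in coherent tracts
around seed heterozygous sites (partitioned between homozygous-major and
homozygous-minor outcomes), plus independent GOH and switch processes, and
read evidence is emitted with negative-binomial depth, binomial allele
counts mixed by tumor purity, and quality/strand annotations drawn from
distributions that pass the dialect filters with probability >= 0.99.

A separate uniform per-allele point-mutation process
(:func:`simulate_point_mutation_null`) provides the null model against
which the LOH-specific mechanism is contrasted: under random point
mutation, heterozygous-to-homozygous and homozygous-to-heterozygous
mutation rates are of the same order, whereas the tract process yields
R_LOH thousands of times larger than R_GOH-M.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from lohscape.io_formats import SITE_COLUMNS

# hg19-scale chromosome lengths (bp), autosomes + X
GENOME_HG19: dict[str, int] = {
    "1": 249_250_621, "2": 243_199_373, "3": 198_022_430, "4": 191_154_276,
    "5": 180_915_260, "6": 171_115_067, "7": 159_138_663, "8": 146_364_022,
    "9": 141_213_431, "10": 135_534_747, "11": 135_006_516, "12": 133_851_895,
    "13": 115_169_878, "14": 107_349_540, "15": 102_531_392, "16": 90_354_753,
    "17": 81_195_210, "18": 78_077_248, "19": 59_128_983, "20": 63_025_520,
    "21": 48_129_895, "22": 51_304_566, "X": 155_270_560,
}

_BASE_CODES = np.array(["A", "C", "G", "T"])
# transition partner by base code: A<->G, C<->T
_TI_PARTNER = np.array([2, 3, 0, 1])
# the two transversion targets per base code
_TV_TARGETS = np.array([[1, 3], [0, 2], [1, 3], [0, 2]])

CLASS_NAMES = np.array(["MM", "Mm", "mm"])


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class CnvSegmentSpec:
    """A simulated copy-number segment scaling tumor depth by ``fold``."""

    chrom: str
    start: int  # 0-based half-open
    end: int
    fold: float


@dataclass
class SimConfig:
    """Generator configuration; defaults are cohort-average scale values.

    ``loh_rate`` is the per-heterozygous-site tract-seeding probability (at
    the default sparse site density each tract contains a single Mm site,
    so it equals the marginal LOH probability); ``p_MM`` the probability an
    LOH tract resolves to the homozygous-major genotype; ``ti_bias`` the
    transition:transversion odds used for minor-allele and de-novo GOH
    allele draws.
    """

    seed: int = 0
    n_samples: int = 30
    n_positions: int = 1_000_000
    freq_Mm: float = 2.4e-4
    freq_mm: float = 1.7e-4
    mean_depth: float = 100.0
    depth_dispersion: float = 40.0
    loh_rate: float = 0.086
    p_MM: float = 0.84
    tract_length_bp: int = 50_000
    ti_bias: float = 2.0
    goh_M_rate: float = 1.5e-5
    goh_m_rate: float = 0.021
    het_switch_rate: float = 0.0056
    purity: float = 1.0
    cnv_segments: tuple[CnvSegmentSpec, ...] = ()
    genome: dict[str, int] = field(default_factory=lambda: dict(GENOME_HG19))
    # annotation emission
    qd_het_mean: float = 30.0
    qd_het_sd: float = 5.0
    qd_hom_mean: float = 35.0
    qd_hom_sd: float = 4.0
    qd_ref_mean: float = 20.0
    qd_ref_sd: float = 5.0
    sb_mean: float = -2.0
    sb_sd: float = 0.7
    fs_scale: float = 2.0
    fail_rate: float = 0.002
    exact_emission: bool = False

    @property
    def freq_MM(self) -> float:
        return 1.0 - self.freq_Mm - self.freq_mm

    def validate(self) -> None:
        rates = {
            "freq_Mm": self.freq_Mm, "freq_mm": self.freq_mm,
            "loh_rate": self.loh_rate, "p_MM": self.p_MM,
            "goh_M_rate": self.goh_M_rate, "goh_m_rate": self.goh_m_rate,
            "het_switch_rate": self.het_switch_rate, "fail_rate": self.fail_rate,
        }
        for name, val in rates.items():
            if not 0.0 <= val <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {val}")
        if self.freq_MM < 0.0:
            raise ConfigError("genotype priors exceed 1: freq_Mm + freq_mm > 1")
        if abs(self.freq_MM + self.freq_Mm + self.freq_mm - 1.0) > 1e-9:
            raise ConfigError("genotype priors must sum to 1")
        if not 0.0 < self.purity <= 1.0:
            raise ConfigError("purity must be in (0, 1]")
        if self.n_positions <= 0 or self.tract_length_bp <= 0:
            raise ConfigError("n_positions and tract_length_bp must be positive")
        if self.mean_depth <= 0 or self.depth_dispersion <= 0:
            raise ConfigError("depth parameters must be positive")
        if self.ti_bias <= 0:
            raise ConfigError("ti_bias must be positive")


def _sample_rng(cfg: SimConfig, sample_id: str, salt: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        [cfg.seed & 0x7FFFFFFF, zlib.crc32(sample_id.encode()) & 0x7FFFFFFF, salt]
    )


def _draw_minor(rng: np.random.Generator, ref_codes: np.ndarray, ti_bias: float) -> np.ndarray:
    """Draw a minor-allele code per site: transition partner with odds
    ``ti_bias`` against the two transversions combined."""
    n = len(ref_codes)
    u = rng.random(n)
    p_ti = ti_bias / (1.0 + ti_bias)
    m = _TI_PARTNER[ref_codes].copy()
    tv = u >= p_ti
    pick = rng.integers(0, 2, size=n)
    m[tv] = _TV_TARGETS[ref_codes[tv], pick[tv]]
    return m


def _positions(rng: np.random.Generator, cfg: SimConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Site coordinates: chromosomes weighted by length, positions uniform,
    sorted and de-duplicated.  Returns (chrom_idx, pos, chrom_names)."""
    names = np.array(list(cfg.genome.keys()))
    lengths = np.array(list(cfg.genome.values()), dtype=float)
    counts = rng.multinomial(cfg.n_positions, lengths / lengths.sum())
    chrom_idx, pos = [], []
    for i, n in enumerate(counts):
        if n == 0:
            continue
        p = np.unique(rng.integers(1, int(lengths[i]) + 1, size=n))
        chrom_idx.append(np.full(len(p), i, dtype=np.int16))
        pos.append(p)
    return np.concatenate(chrom_idx), np.concatenate(pos), names


def _emit(
    rng: np.random.Generator,
    cfg: SimConfig,
    frac: np.ndarray,
    fold: np.ndarray,
    gt: np.ndarray,
) -> dict[str, np.ndarray]:
    """Read-level evidence for one sample given expected alt fractions."""
    n = len(frac)
    mu = cfg.mean_depth * fold
    if cfg.exact_emission:
        depth = np.rint(mu).astype(np.int64)
        ad_alt = np.rint(depth * frac).astype(np.int64)
        qd = np.where(gt == 0, cfg.qd_ref_mean, np.where(gt == 1, cfg.qd_het_mean, cfg.qd_hom_mean))
        sb = np.full(n, cfg.sb_mean)
        fs = np.zeros(n)
    else:
        k = cfg.depth_dispersion
        depth = rng.negative_binomial(k, k / (k + mu), size=n).astype(np.int64)
        ad_alt = rng.binomial(depth, frac)
        qd = np.where(
            gt == 0,
            rng.normal(cfg.qd_ref_mean, cfg.qd_ref_sd, n),
            np.where(
                gt == 1,
                rng.normal(cfg.qd_het_mean, cfg.qd_het_sd, n),
                rng.normal(cfg.qd_hom_mean, cfg.qd_hom_sd, n),
            ),
        )
        qd = np.clip(qd, 0.05, None)
        sb = rng.normal(cfg.sb_mean, cfg.sb_sd, n)
        fs = rng.exponential(cfg.fs_scale, n)
        bad = rng.random(n) < cfg.fail_rate
        qd[bad] = rng.uniform(0.0, 3.0, bad.sum())
        sb[bad] = rng.uniform(0.0, 1.0, bad.sum())
        fs[bad] = rng.uniform(13.0, 60.0, bad.sum())
    return {"depth": depth, "ad_alt": ad_alt, "ad_ref": depth - ad_alt, "qd": qd, "sb": sb, "fs": fs}


def _site_frame(
    sample_id: str,
    chrom: np.ndarray,
    pos: np.ndarray,
    ref: np.ndarray,
    alt: np.ndarray,
    emitted: dict[str, np.ndarray],
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": sample_id,
            "chrom": chrom,
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "depth": emitted["depth"],
            "ad_ref": emitted["ad_ref"],
            "ad_alt": emitted["ad_alt"],
            "qd": emitted["qd"],
            "sb": emitted["sb"],
            "fs": emitted["fs"],
        },
        columns=SITE_COLUMNS,
    )


def _frac_of(gt: np.ndarray) -> np.ndarray:
    return np.where(gt == 0, 0.0, np.where(gt == 1, 0.5, 1.0))


def _alt_letters(m_code: np.ndarray, has_m: np.ndarray) -> np.ndarray:
    alt = np.where(has_m, _BASE_CODES[np.clip(m_code, 0, 3)], "")
    return alt.astype(object)


def simulate_pair(
    cfg: SimConfig,
    sample_id: str = "s1",
    sex: str = "M",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate one paired (control, tumor, truth) site-table triple.

    Determinism: the output is a pure function of (cfg, sample_id).
    """
    cfg.validate()
    rng = _sample_rng(cfg, sample_id)

    chrom_idx, pos, chrom_names = _positions(rng, cfg)
    n = len(pos)
    ref = rng.integers(0, 4, size=n)

    gt_c = rng.choice(3, size=n, p=[cfg.freq_MM, cfg.freq_Mm, cfg.freq_mm]).astype(np.int8)
    m_c = np.full(n, -1, dtype=np.int8)
    has_m_c = gt_c > 0
    m_c[has_m_c] = _draw_minor(rng, ref[has_m_c], cfg.ti_bias)

    gt_t = gt_c.copy()
    m_t = m_c.copy()

    # --- LOH in coherent tracts around seed heterozygous sites
    het_idx = np.flatnonzero(gt_c == 1)
    is_seed = rng.random(len(het_idx)) < cfg.loh_rate
    seed_to_mm_draw = rng.random(len(het_idx)) >= cfg.p_MM  # per-seed outcome
    half = cfg.tract_length_bp // 2
    converted = np.zeros(len(het_idx), dtype=bool)
    to_mm = np.zeros(len(het_idx), dtype=bool)
    for ci in np.unique(chrom_idx[het_idx]):
        sel = np.flatnonzero(chrom_idx[het_idx] == ci)
        seeds = sel[is_seed[sel]]
        if len(seeds) == 0:
            continue
        spos = pos[het_idx[seeds]]
        hpos = pos[het_idx[sel]]
        j = np.clip(np.searchsorted(spos, hpos), 0, len(spos) - 1)
        d_right = np.abs(spos[j] - hpos)
        d_left = np.abs(spos[np.maximum(j - 1, 0)] - hpos)
        nearest = np.where(d_left < d_right, np.maximum(j - 1, 0), j)
        dist = np.abs(spos[nearest] - hpos)
        hit = dist <= half
        converted[sel[hit]] = True
        to_mm[sel[hit]] = seed_to_mm_draw[seeds][nearest[hit]]
    conv_idx = het_idx[converted]
    gt_t[conv_idx] = np.where(to_mm[converted], 2, 0)
    m_t[conv_idx] = np.where(to_mm[converted], m_c[conv_idx], -1)

    # --- het switches among unconverted heterozygotes
    un_idx = het_idx[~converted]
    switch = un_idx[rng.random(len(un_idx)) < cfg.het_switch_rate]
    for i in switch:
        options = [b for b in range(4) if b != ref[i] and b != m_c[i]]
        weights = np.array(
            [cfg.ti_bias if b == _TI_PARTNER[ref[i]] else 1.0 for b in options]
        )
        m_t[i] = rng.choice(options, p=weights / weights.sum())

    # --- GOH processes
    mm_idx = np.flatnonzero(gt_c == 0)
    goh_M = mm_idx[rng.random(len(mm_idx)) < cfg.goh_M_rate]
    gt_t[goh_M] = 1
    m_t[goh_M] = _draw_minor(rng, ref[goh_M], cfg.ti_bias)

    hom_idx = np.flatnonzero(gt_c == 2)
    goh_m = hom_idx[rng.random(len(hom_idx)) < cfg.goh_m_rate]
    gt_t[goh_m] = 1  # minor allele retained

    # --- CNV fold and emission
    fold = np.ones(n)
    in_cnv = np.zeros(n, dtype=bool)
    name_to_idx = {c: i for i, c in enumerate(chrom_names)}
    for seg in cfg.cnv_segments:
        ci = name_to_idx.get(str(seg.chrom))
        if ci is None:
            continue
        mask = (chrom_idx == ci) & (pos - 1 >= seg.start) & (pos - 1 < seg.end)
        fold[mask] = seg.fold
        in_cnv |= mask

    f_c = _frac_of(gt_c)
    f_t = cfg.purity * _frac_of(gt_t) + (1.0 - cfg.purity) * f_c

    chrom_col = chrom_names[chrom_idx]
    ref_col = _BASE_CODES[ref]
    alt_c = _alt_letters(m_c, m_c >= 0)
    # tumor alt: own minor allele, else control's where remnant reads can occur
    m_eff_t = np.where(m_t >= 0, m_t, np.where((f_t > 0), m_c, -1)).astype(np.int8)
    alt_t = _alt_letters(m_eff_t, m_eff_t >= 0)

    control = _site_frame(
        sample_id, chrom_col, pos, ref_col, alt_c,
        _emit(_sample_rng(cfg, sample_id, 1), cfg, f_c, np.ones(n), gt_c),
    )
    tumor = _site_frame(
        sample_id, chrom_col, pos, ref_col, alt_t,
        _emit(_sample_rng(cfg, sample_id, 2), cfg, f_t, fold, gt_t),
    )

    kind = _truth_kinds(gt_c, gt_t, m_c, m_t)
    truth = pd.DataFrame(
        {
            "chrom": chrom_col,
            "pos": pos,
            "ref": ref_col,
            "control_class": CLASS_NAMES[gt_c],
            "tumor_class": CLASS_NAMES[gt_t],
            "control_m": _alt_letters(m_c, m_c >= 0),
            "tumor_m": _alt_letters(m_t, m_t >= 0),
            "kind": kind,
            "in_cnv": in_cnv,
            "sex": sex,
        }
    )
    return control, tumor, truth


def _truth_kinds(gt_c, gt_t, m_c, m_t) -> np.ndarray:
    kind = np.full(len(gt_c), "", dtype=object)
    same_m = m_c == m_t
    kind[(gt_c == 1) & (gt_t == 0)] = "LOH_to_MM"
    kind[(gt_c == 1) & (gt_t == 2) & same_m] = "LOH_to_mm"
    kind[(gt_c == 1) & (gt_t == 2) & ~same_m] = "HET_SWITCH"
    kind[(gt_c == 1) & (gt_t == 1) & ~same_m] = "HET_SWITCH"
    kind[(gt_c == 0) & (gt_t == 1)] = "GOH_M"
    kind[(gt_c == 2) & (gt_t == 1)] = "GOH_m"
    kind[(gt_c == 0) & (gt_t == 2)] = "HOM_SWITCH"
    kind[(gt_c == 2) & (gt_t == 0)] = "HOM_SWITCH"
    kind[(gt_c == 2) & (gt_t == 2) & ~same_m] = "HOM_SWITCH"
    return kind


def simulate_cohort(
    cfg: SimConfig,
    sample_prefix: str = "s",
) -> list[tuple[str, str, pd.DataFrame, pd.DataFrame, pd.DataFrame]]:
    """Generate ``cfg.n_samples`` pairs; sexes alternate M/F.

    Returns a list of (sample_id, sex, control, tumor, truth).
    """
    out = []
    for i in range(cfg.n_samples):
        sid = f"{sample_prefix}{i + 1:02d}"
        sex = "F" if i % 3 == 2 else "M"
        control, tumor, truth = simulate_pair(cfg, sid, sex=sex)
        out.append((sid, sex, control, tumor, truth))
    return out


def simulate_point_mutation_null(
    cfg: SimConfig,
    r: float,
    sample_id: str = "null1",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Uniform per-allele point-mutation tumor model (no tract process).

    Each of the two allele copies mutates independently with probability
    ``r`` to a target base drawn with transition odds ``cfg.ti_bias``.  If
    both copies mutate to two distinct non-reference bases (probability
    r^2, negligible under the r << 1 precondition) the site is emitted as
    heterozygous with one of the mutant bases as alt.
    """
    if not 0.0 <= r < 0.5:
        raise ConfigError("per-allele rate r must be in [0, 0.5)")
    cfg.validate()
    rng = _sample_rng(cfg, sample_id, 7)

    chrom_idx, pos, chrom_names = _positions(rng, cfg)
    n = len(pos)
    ref = rng.integers(0, 4, size=n)
    gt_c = rng.choice(3, size=n, p=[cfg.freq_MM, cfg.freq_Mm, cfg.freq_mm]).astype(np.int8)
    m_c = np.full(n, -1, dtype=np.int8)
    has_m = gt_c > 0
    m_c[has_m] = _draw_minor(rng, ref[has_m], cfg.ti_bias)

    a1 = np.where(gt_c == 2, m_c, ref).astype(np.int8)  # copy 1: m for mm, else M
    a2 = np.where(gt_c == 0, ref, m_c).astype(np.int8)  # copy 2: m unless MM

    for a in (a1, a2):
        mut = rng.random(n) < r
        if mut.any():
            a[mut] = _draw_minor(rng, a[mut].astype(np.int64), cfg.ti_bias)

    gt_t = np.empty(n, dtype=np.int8)
    m_t = np.full(n, -1, dtype=np.int8)
    hom = a1 == a2
    gt_t[hom] = np.where(a1[hom] == ref[hom], 0, 2)
    m_t[hom & (a1 != ref)] = a1[hom & (a1 != ref)]
    het = ~hom
    m_het = np.where(a1[het] != ref[het], a1[het], a2[het])
    gt_t[het] = 1
    m_t[het] = m_het

    f_c = _frac_of(gt_c)
    f_t = cfg.purity * _frac_of(gt_t) + (1.0 - cfg.purity) * f_c
    chrom_col = chrom_names[chrom_idx]
    ref_col = _BASE_CODES[ref]
    control = _site_frame(
        sample_id, chrom_col, pos, ref_col, _alt_letters(m_c, m_c >= 0),
        _emit(_sample_rng(cfg, sample_id, 8), cfg, f_c, np.ones(n), gt_c),
    )
    m_eff_t = np.where(m_t >= 0, m_t, np.where(f_t > 0, m_c, -1)).astype(np.int8)
    tumor = _site_frame(
        sample_id, chrom_col, pos, ref_col, _alt_letters(m_eff_t, m_eff_t >= 0),
        _emit(_sample_rng(cfg, sample_id, 9), cfg, f_t, np.ones(n), gt_t),
    )
    truth = pd.DataFrame(
        {
            "chrom": chrom_col,
            "pos": pos,
            "ref": ref_col,
            "control_class": CLASS_NAMES[gt_c],
            "tumor_class": CLASS_NAMES[gt_t],
            "control_m": _alt_letters(m_c, m_c >= 0),
            "tumor_m": _alt_letters(m_t, m_t >= 0),
            "kind": _truth_kinds(gt_c, gt_t, m_c, m_t),
            "in_cnv": False,
            "sex": "M",
        }
    )
    return control, tumor, truth
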