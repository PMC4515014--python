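# Methods

## Genotype model and event taxonomy

Every site is oriented on the reference genome: the reference base is the
major allele M, any differing base a minor allele m, and genotypes are MM,
Mm, mm relative to that orientation.  Only biallelic single-base
substitutions are modelled; indels and non-ACGT alleles are dropped at
parse time, and a site whose control and tumor calls involve two different
minor alleles is classified as a *switch*, not as LOH/GOH.

The six-way event taxonomy over co-callable (control, tumor) pairs:

| control → tumor             | event        |
|-----------------------------|--------------|
| Mm → MM                     | LOH_to_MM    |
| Mm → mm (same m)            | LOH_to_mm    |
| MM → Mm                     | GOH_M        |
| mm → Mm                     | GOH_m        |
| Mm → Mm/mm (different m)    | HET_SWITCH   |
| MM↔mm, mm → m'm'            | HOM_SWITCH   |
| identical genotype          | no event     |

is exhaustive and mutually exclusive (the test suite verifies this by
enumeration against an independent allele-multiset oracle).  `mm → Mm` is
classified GOH_m regardless of whether the tumor heterozygote carries the
same minor allele; in the biallelic emission model the minor allele is in
practice retained.  Transition contexts are {A,G} and {C,T}; of the 12
ordered heterozygote contexts (`Ag`, `Ct`, …) exactly 4 are transitions.

## Filtering dialects

Filters are applied per sample and a site enters analysis only when *both*
members of the pair are callable ("co-callable"); all rate denominators
count co-callable sites by their control-side genotype.

* `aluscan` (inter-Alu capture): depth ≥ 8 in both samples; hom-ref
  requires 0 non-reference reads (no QD floor); hom-non-ref requires 100 %
  non-reference reads, QD ≥ 20 and SB < −0.01; het requires a 35–65 %
  non-reference fraction, QD ≥ 4 and SB < −0.01.  At depth ≥ 8 a het call
  therefore implies ≥ ⌈0.35·d⌉ ≥ 3 non-reference reads.
* `wgs`: depth ≥ 15; hom-ref additionally requires QD ≥ 1; het band is
  25–75 %; the strand filter is FS ≤ 12 instead of SB.

Design choices: allele fractions are computed over informative reads
(ad_ref + ad_alt); homozygous calls tolerate exactly zero mismatching reads
(this strictness is what converts tumor impurity into UNCALLABLE sites
rather than false LOH calls); annotations a dialect requires but the input
lacks *fail* the filter; the dialect is explicit configuration, never
auto-detected.  The SB inequality is applied literally ("more negative =
cleaner", pass iff sb < −0.01).

## Rates and averages

Each rate is `100 × (events of the relevant kinds) / (control-side
denominator)`; R_Mm additionally counts heterozygote switches, and R_MM /
R_mm count homozygote switches originating from MM / mm.  R_LOH is defined
as the sum R_Mm→MM + R_Mm→mm so the conservation identity is exact in
floating point.  A zero denominator yields an absent (NaN) rate, never 0;
the MM/mm partition ratio is absent when no Mm→mm events exist.

Two cohort estimators are kept distinct: the *sample average* (unweighted
mean ± sample SD of per-sample rates; ratio columns averaged as per-sample
ratios) and the *aggregate average* (summed event counts over summed
denominators).  They differ whenever per-sample denominators differ, so
both are reported.  The solid-vs-leukemia contrast uses Welch's
unequal-variance two-sided t-test on per-sample R_LOH — chosen because the
two groups differ in spread by an order of magnitude; on the bundled
reference cohort (25 solid vs 5 leukemia rows) it gives p ≈ 2.8 × 10⁻⁴.

The copy-neutral variant of every rate counts only events outside called
CNV segments, with unchanged denominators, hence is never larger than the
raw variant.

## CNV calling

Per-site depths are summed into fixed windows (default 500 kb), tumor sums
rescaled by the ratio of global median per-site depths so library sizes
cancel, and each window's ratio w = T/C is mapped to
z = (μ_c·w − μ_t)/√(σ_c²·w² + σ_t²) — the Geary–Hinkley transformation of
a ratio of approximately normal variables, standard normal under the null.
Windows with |z| ≥ z_crit (default 1.96) are gain/loss candidates; runs of
≥ min_run (default 2) consecutive same-call windows become segments, and
windows with < 10 sites are uncalled.  Events in uncalled windows count as
copy-neutral (absence of evidence of CNV).

Null parameters: μ is the genome-wide median of window sums; σ is estimated
robustly as 1.4826 × MAD of the window sums (floored at the Poisson value
√μ).  A pure Poisson σ² = μ model was considered and rejected: capture
depth is overdispersed (the generator emits negative-binomial depths), and
a Poisson σ makes the null statistic anticonservative by a factor of ~2,
flooding the caller with false windows.  The MAD estimate reduces to √μ on
Poisson data — the null rejection rate at |z| ≥ 1.96 is 5 % ± 1 % over
10 000 simulated Poisson windows — and widens appropriately otherwise.

Boundary convention: a segment is 0-based half-open and an event whose
position equals the segment `end` coordinate lies outside it.

## Synthetic generator

`SimConfig` defaults emulate the cohort-average conditions of Mb-scale
paired inter-Alu capture data:

| parameter        | default  | meaning                                        |
|------------------|----------|------------------------------------------------|
| freq_Mm, freq_mm | 2.4e-4, 1.7e-4 | control genotype priors (MM is the rest) |
| loh_rate         | 0.086    | tract-seed probability per Mm site             |
| p_MM             | 0.84     | probability an LOH tract resolves to MM        |
| tract_length_bp  | 50 000   | gene-conversion tract span                     |
| ti_bias          | 2.0      | transition:transversion odds for m draws       |
| goh_M_rate       | 1.5e-5   | MM → Mm probability                            |
| goh_m_rate       | 0.021    | mm → Mm probability                            |
| het_switch_rate  | 0.0056   | Mm → different-m probability                   |
| mean_depth       | 100      | negative-binomial depth mean (dispersion 40)   |
| purity           | 1.0      | tumor cell fraction in the tumor sample        |

LOH is applied in coherent tracts: seed Mm sites are drawn at `loh_rate`,
every Mm site within half a tract length of a seed converts, and the
MM-vs-mm outcome is drawn once per seed — this makes fragment-run analysis
meaningful (at default site density a tract contains a single Mm site, so
`loh_rate` is also the marginal conversion probability).  Depth is
negative-binomial, allele counts binomial at the purity-mixed expected
fraction, and QD/SB/FS are drawn from documented distributions (normals
and an exponential with a 0.2 % contamination of failing values) chosen so
true genotypes pass the dialect filters with probability ≥ 0.99 — the
depth/dispersion defaults were raised until that contract held, since a
lower pass rate makes the retained-het denominator leak and biases
recovered R_LOH upward.  Purity defaults to 1.0: the 100 %-homozygosity
rule converts impure LOH sites into UNCALLABLE, which is exercised in
tests at purity 0.6 rather than baked into the default conditions.
`cnv_segments` defaults to empty (CNV-associated events are a small
minority of the emulated conditions); CNV scenarios pass explicit segments.
An `exact_emission` mode emits deterministic depths and annotations so that
pipeline output equals the truth table site for site.

The point-mutation null mutates each allele copy independently at rate r
with the same transition bias and no tract process.  Its R_LOH/R_GOH-M
ratio is of order one (LOH requires hitting one specific base, GOH any
change), in categorical contrast to the tract model's ratio in the
thousands.  When both copies mutate to two distinct non-reference bases
(probability r², ~1 site per 10⁶ at r = 10⁻³) the site is emitted as a
heterozygote with one mutant base as alt — a documented approximation.

What the generator does **not** emulate: capture non-uniformity across
chromosomes (site density is uniform per bp), linkage between neighboring
sites other than LOH tract coherence, mechanistic GATK annotation
semantics, male hemizygous X (X is simulated like an autosome; the
density analysis restricts X to female samples regardless), and read-level
artifacts.  Passing tests therefore demonstrate correctness of the
statistical machinery under the stated model, not robustness to every
real-data pathology.

## Landscape definitions

* **Fragment run**: maximal run of consecutive LOH events on one chromosome
  with no co-callable retained-heterozygous site strictly inside; length =
  last − first + 1 (an isolated event has length 1 bp).  This is a declared
  reconstruction — "fragment" has no universal definition — and the length
  histogram keeps a dedicated ≤ 1 Mb bin plus log-spaced bins above.
* **Interstitial**: a run is interstitial iff it touches neither the first
  nor the last analyzed position of its chromosome and, when a cytoband
  track is supplied, overlaps neither the first nor the last band.
* **Densities**: pooled across samples per chromosome, as LOH per Mm site
  analyzed and LOH per co-callable bp; X uses female samples only, Y is
  excluded.
* **Correlations**: Pearson r between per-autosome pooled totals of LOH,
  GOH-M and GOH-m (22 points); absent when a vector has zero variance.
* **Recurrent genes**: a gene is reported when events of the queried kinds
  hit it in ≥ 3 distinct samples (configurable); counts are split by
  to-MM vs to-mm outcome, and events in overlapping genes count for each.

## Problem sizes

Verification runs are desk-scale by design: recovery cohorts use 10–12
samples of 4–5 × 10⁵ sites at the default priors (≈ 10³ heterozygous
denominator sites pooled), unit tests use denser heterozygote priors on
smaller tables, the Geary–Hinkley null uses 10⁴ windows of 20 Poisson
sites, and CNV recovery uses a 50 Mb single-chromosome genome at 1 site /
10 kb with a 5 Mb 2× gain.  Tolerances on stochastic recoveries are 3
Monte-Carlo standard errors computed from the realized counts.

## Known limitations

* Windowed CNV calling has no breakpoint refinement and a single paired
  mode (no reference template built from panels of controls); allele-
  specific copy number is out of scope.
* The het-band filter slightly favors LOH sites over retained heterozygotes
  in the co-callable denominator (hom calls are easier to pass than het
  calls); with the default emission this bias is < 2 % relative and far
  below the Monte-Carlo tolerance, but it grows if depth is lowered.
* Phasing, haplotype reconstruction and somatic VAF modelling beyond the
  threshold rules are out of scope.
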