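# Methods

## Tier model

Candidate calls from a UMI-based amplicon panel carry two depth scales:
raw reads and molecular (UMI-consensus-family) counts. The filter's
premise is that molecular counts, not raw reads, carry the evidence at
ultra-low allele fraction: a handful of independent template molecules
supporting a known resistance hotspot is real signal even at 0.03% MAF.

Rules evaluate in a fixed order; the first hard reject wins and is named
in the verdict.

1. **Blacklist** — recurrent-artifact regions reject unconditionally.
2. **Germline** — SNV/MNP calls at AF ≥ `germline_af_min` (0.40) are
   treated as germline and rejected. This threshold is a design choice
   of this package: cfDNA is dominated by wild-type DNA, so somatic
   variants essentially never reach 40% while heterozygous germline
   variants cluster near 50%. Indels are exempted because amplicon
   indel AFs are noisier.
3. **Molecular floor** — fewer than `mol_alt_min` (2) supporting
   molecules is unquantifiable; exempt for fusions/CNVs, which the panel
   calls from other evidence.
4. **Noise test** — for SNV/indel/MNP, a one-sided binomial test of
   `mol_alt` against `Binomial(mol_depth, assay_error_rate)` with
   `assay_error_rate` = 10⁻⁴ and α = 0.01. The underlying tool
   accounts for "the overall error of the NGS assay" without naming a
   test; we fix this one so behaviour is deterministic and documented.
   At molecular depth 1670 this means 3 molecules are needed
   (P(X ≥ 2) = 0.013 > 0.01); at depth 250, 2 suffice.
5. **Commercial tier** — AF ≥ `commercial_af_min` (0.5%) and read depth
   ≥ 1000: what the stock pipeline reliably reports. The 0.5% value is
   an empirical reporting floor, not the chemistry's LOD.
6. **Rescue tier** — AF ≥ `valk_af_min` (0.03%), molecular depth ≥ 300,
   and locus in the hotspot whitelist, by default the ALK kinase domain
   expressed in protein space (codons 1123–1278) so that no genome-build
   coordinates are hard-coded.
7. Everything else that survived the rejects is **raw-only**: present in
   the candidate table, below every reporting bar.

Fusions and CNVs passing their class rules (breakpoint reads ≥ 20; fold
change ≥ 2.0 or ≤ 0.5) are assigned the commercial tier: the vendor
pipeline reports them directly and AF-based tiers are meaningless for
them. The per-sample "fraction of bases at target depth" metric acts as
a QC warning (`sample_qc_warnings`), never as a per-variant gate — with
no evidence either way, warning is the conservative reading.

The exact cutoffs 0.5% and 0.03% are calibrated so that the embedded
twelve-variant ALK fixture reproduces its recorded tiers: the lowest
rescued AF on record is 0.03%, the lowest raw-only 0.02%. All thresholds
are overridable via a flat `key=value` config file.

## Cohort fixture

The embedded cohort emulates 28 samples (26 plasma, 2 CSF) from 24
patients. Twelve ALK kinase-domain variants, eight non-ALK resistance
variants and three CNVs carry their individually recorded values
(AF, drug, line, tier, orthogonal dPCR MAF, input mass). Molecular
counts were never recorded, so a frozen recipe supplies them:
`mol_depth` = 1670 (the cohort median molecular coverage, rounded), and
`mol_alt = max(round(af·mol_depth), k_min)` where `k_min` is the
smallest count clearing the floor and noise rules. Three rows recorded
as raw-only despite an AF at or above the rescue floor are given
`mol_depth` = 250: below the 300 molecular-depth floor, the only
recorded variable that can separate them from same-AF rescued rows.

The remaining 37 rows are synthetic filler, constrained so the cohort's
aggregates land on the recorded values — 61 detected variants (48 SNV,
10 indel, 3 CNV) in 14 genes across 24 mutated samples, mean 2.18 per
sample, median MAF 0.39% (range 0.02–5.09%), three fully negative
patients. The filler rows' identities (which TP53 codon, which sample
gets which AF) are inventions; nothing downstream depends on them beyond
the aggregates. Genomic coordinates throughout are placeholders on the
correct chromosome; identity is (gene, protein change), which is also
the concordance key since dPCR assays are designed per protein change.

The two method-agreement cross-tables are reconstructions, not
transcriptions: the discovery-cohort table (tp=8, fp=2, fn=4, tn=25) is
the unique small-integer 2×2 whose PPA/NPA/ORA and exact CIs match the
reported 67% (35–90) / 93% (75–99) / 85% (69–94) at printed precision;
the validation table (tp=3, fp=1, fn=0, tn=50) is pinned exactly by the
29% lower bound, which is the Clopper–Pearson lower limit for 3/3 —
this bound is also what identifies the CI method as Clopper–Pearson
(Wald and Wilson give different limits). Exact recomputation gives
lower bounds of 75.7% and 69.5% where 75 and 69 were printed, so the
source's lower-bound rounding is evidently a floor; tests assert point
estimates at printed precision and bounds within one percentage point.

## dPCR quantification

Channel occupancies use the Poisson correction λ = −ln(1 − n_pos/n_valid)
with channel positives counted inclusive of double positives
(co-encapsulation). MAF = λ_mut/(λ_mut + λ_wt); a `naive=True` switch
reproduces the plain positive-partition ratio. At wild-type occupancy
≈ 0.05 the correction shifts MAF by ≈ occupancy/2 ≈ 2.5% relative —
small but not negligible, which is why the corrected form is the
default. Copies/mL of plasma propagate through an explicit chain
(chip volume → PCR mix concentration → full reaction → eluate → plasma)
recorded in the call's audit dict. The geometry defaults (20,000
partitions × 0.755 nL, 14.5/18 µL loaded, 8.55 µL template, 50 µL
eluate, 2 mL plasma) are instrument-typical placeholders, all
configurable per lab — absolute copy numbers are only as good as these
constants, whereas MAF is a ratio and independent of them.

Positivity is MAF ≥ 0.1% AND wild-type ≥ 300 copies/mL, both bounds
inclusive; the wild-type condition prevents calling positives on chips
with too little amplifiable input.

## Calibration

LOD = 3.3·σ/S and LOQ = 10·σ/S with σ the standard error of the
intercept from the OLS of observed on expected MAF (response on
concentration) and S the slope; the 3.3/10 multipliers are the ICH
Q2(R1) constants. Whether replicates should be averaged per level
before regressing is unrecorded; the default regresses all points and
`aggregate_levels=True` exposes the alternative. Detection limits are
unit-consistent: percent in, percent out. Published per-assay LODs for
this chemistry fall around 0.05–0.23%, a plausibility band our simulated
series reproduce in order of magnitude; they are not test targets
because the underlying raw dilution data is unpublished.

## Simulators and what a green test establishes

`generate_table` states a world: 52 panel genes, molecular depth
~Poisson(1670.8), read depth ~Normal(21261, 15%), per-locus background
error log-normal with log₁₀ mean −4.0 and sd 0.3 (median 0.01%, typical
of UMI-consensus chemistry with a claimed 0.1% LOD). Germline decoys
sit at AF ≈ 0.5, artifacts inside the blacklist regions. Spike-ins are
validated at generation time against their expected tier and their
molecular counts are raised to the minimum detectable count when the
binomial draw falls short — so spike-in recovery tests establish that
the plumbing is correct, not that the filter would find weakly supported
variants in real data. Conversely the null-table specificity test
(< 1% of loci surviving, none above raw-only, over 50 seeds) is a real
statistical property of the stated error model, computed a priori at
0.38% expected survival. The simulators do not model UMI family-size
structure, strand artifacts, GC-dependent depth, or contamination; a
green suite says nothing about those.

`generate_dpcr_chip` assigns each template molecule to a uniform random
partition per channel, which reproduces double-positive statistics
without modelling droplet volume variation. All generators are
deterministic in (seed, sample index).

## Numerical choices

- Clopper–Pearson via Beta quantiles; k=0 and k=n return exact 0/1
  bounds rather than quantiles of degenerate Betas.
- Agreement statistics with zero denominators are `None`, never 0.
- Binomial noise p-values via the survival function at k−1
  (P(X ≥ k)); molecular depth 0 counts as noise.
- The TSV dialect declares its AF unit in a `#af_unit=` directive
  (default percent, the unit clinical tables print); AFs are fractions
  internally. Percent round-trips are float-stable after one parse;
  the fraction dialect is bit-exact.
- Region files: BED lines (first field `chr*`) are 0-based half-open
  and converted on load; protein-space lines are 1-based inclusive
  codons. Overlapping entries merge per label.
- Tie-break: rules evaluate in the order listed; the first hard reject
  wins; a call eligible for two tiers gets the higher one.

## Known limitations

- The cohort fixture's filler variants and all genomic coordinates are
  synthetic; only aggregate statistics are meaningful.
- The copies/mL chain constants are placeholders to be set per lab.
- CHIP (clonal-hematopoiesis) classification, fusion calling from
  reads, and survival analysis are out of scope.
- The rescue whitelist ships with the ALK kinase domain only; other
  targets require a user-supplied region file.
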