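"""Synthetic inputs: the embedded study cohort and seeded simulators.

Everything the test suite and the worked examples need is generated here
without downloads: the 28-sample cohort fixture with its orthogonal dPCR
reference, reconstructed method-agreement cross-tables, and seeded
generators for nonfiltered variant tables, dPCR chips and dilution
series.

The simulators state a world rather than fit one: molecular coverage
1670.8 and read coverage 21,261 match the cohort medians, the panel
spans 52 genes, and the background per-locus error is log-normal with
median 0.01% (log10 mean -4.0, sd 0.3) — a typical UMI-consensus error
profile for an assay whose claimed LOD is 0.1% MAF.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binom

from . import _cohort_data as D
from .concordance import CrossTable
from .dpcr import DpcrResult
from .calibration import DilutionSeries
from .filtering import FilterConfig, RegionSet, Tier, classify_variant, codon_of
from .io import SampleTable, VariantCall, VariantClass

__all__ = [
    "SimConfig",
    "min_detectable_mol_alt",
    "table2_fixture",
    "cohort_fixture",
    "dpcr_reference_rows",
    "alk_cohort_cross_table",
    "valencia_cross_table",
    "generate_table",
    "generate_dpcr_chip",
    "generate_dilution_series",
    "DEFAULT_SIM_BLACKLIST",
    "PANEL_GENES",
]

# 52-gene pan-cancer liquid-biopsy panel scale (synthetic gene roster)
PANEL_GENES = (
    "AKT1", "ALK", "APC", "AR", "ARAF", "BRAF", "CCND1", "CCND2", "CCND3",
    "CDK4", "CDK6", "CDKN2A", "CHEK2", "CTNNB1", "DDR2", "EGFR", "ERBB2",
    "ERBB3", "ESR1", "FBXW7", "FGFR1", "FGFR2", "FGFR3", "FGFR4", "GNA11",
    "GNAQ", "GNAS", "HRAS", "IDH1", "IDH2", "KIT", "KRAS", "MAP2K1",
    "MAP2K2", "MET", "MTOR", "MYC", "MYCN", "NRAS", "NTRK1", "NTRK3",
    "PDGFRA", "PIK3CA", "PTEN", "RAF1", "RET", "ROS1", "SF3B1", "SMAD4",
    "SMO", "TP53", "VHL",
)

# recurrent-artifact loci used by the simulator's blacklist decoys
DEFAULT_SIM_BLACKLIST = RegionSet(genomic=(
    ("chr17", 7577000, 7577050, "tp53_homopolymer_artifact"),
    ("chr7", 55249000, 55249060, "egfr_polyA_artifact"),
))

HAPLOID_COPIES_PER_NG = 303.0  # ~3.3 pg per haploid human genome


def min_detectable_mol_alt(mol_depth: int, config: FilterConfig) -> int:
    """Smallest molecular alt count clearing the floor and the noise test."""
    k = max(config.mol_alt_min, 1)
    while float(binom.sf(k - 1, max(mol_depth, 1), config.assay_error_rate)) \
            >= config.noise_alpha:
        k += 1
        if k > max(mol_depth, 1):
            raise ValueError(f"no detectable count at mol_depth {mol_depth}")
    return k


def _recipe_counts(af: float, mol_depth: int, read_depth: int,
                   config: FilterConfig) -> tuple[int, int]:
    """Frozen molecular/read count recipe for fixture rows.

    mol_alt = max(round(af * mol_depth), smallest count that survives the
    default filter); read_alt proportional to AF, at least 1.
    """
    mol_alt = max(round(af * mol_depth), min_detectable_mol_alt(mol_depth, config))
    read_alt = min(max(round(af * read_depth), 1), read_depth)
    return mol_alt, read_alt


def _alk_call(sample_id: str, row, config: FilterConfig) -> VariantCall:
    _, cdna, prot, _drug, _line, _tier, maf_pct, _dpcr, _ng, mol_depth = row
    af = maf_pct / 100.0
    chrom, base = D.GENE_LOCATIONS["ALK"]
    cdna_pos = int("".join(ch for ch in cdna.split(">")[0] if ch.isdigit()))
    ref, alt = cdna[-3], cdna[-1]
    read_depth = D.MEDIAN_READ_COV_PLASMA
    mol_alt, read_alt = _recipe_counts(af, mol_depth, read_depth, config)
    return VariantCall(
        sample_id=sample_id, chrom=chrom, pos=base + cdna_pos, ref=ref, alt=alt,
        variant_class=VariantClass.SNV, gene="ALK", protein_change=prot,
        af=af, read_depth=read_depth, read_alt_count=read_alt,
        mol_depth=mol_depth, mol_alt_count=mol_alt,
    )


def cohort_fixture(config: FilterConfig | None = None) -> list[SampleTable]:
    """Build the full 28-sample cohort (26 plasma + 2 CSF) fixture."""
    config = config or FilterConfig()
    calls: dict[str, list[VariantCall]] = {s: [] for s, _, _ in D.SAMPLES}
    specimen = {s: spec for s, _, spec in D.SAMPLES}

    for row in D.ALK_ROWS:
        calls[row[0]].append(_alk_call(row[0], row, config))

    for sample, gene, chrom, pos, ref, alt, vclass, prot, maf_pct, cosm \
            in D.OTHER_SMALL_ROWS:
        af = maf_pct / 100.0
        read_depth = (D.MEDIAN_READ_COV_CSF if specimen[sample] == "CSF"
                      else D.MEDIAN_READ_COV_PLASMA)
        mol_depth = 1670
        mol_alt, read_alt = _recipe_counts(af, mol_depth, read_depth, config)
        calls[sample].append(VariantCall(
            sample_id=sample, chrom=chrom, pos=pos, ref=ref, alt=alt,
            variant_class=VariantClass(vclass), gene=gene, protein_change=prot,
            af=af, read_depth=read_depth, read_alt_count=read_alt,
            mol_depth=mol_depth, mol_alt_count=mol_alt, hotspot_id=cosm,
        ))

    for sample, gene, chrom, pos, fold in D.CNV_ROWS:
        calls[sample].append(VariantCall(
            sample_id=sample, chrom=chrom, pos=pos, ref="", alt="",
            variant_class=VariantClass.CNV, gene=gene, af=0.0,
            read_depth=D.MEDIAN_READ_COV_PLASMA, cnv_ratio=fold,
        ))

    filler_index: dict[str, int] = {}
    for sample, gene, vclass, prot, maf_pct in D.FILLER_ROWS:
        af = maf_pct / 100.0
        chrom, base = D.GENE_LOCATIONS[gene]
        i = filler_index[gene] = filler_index.get(gene, 0) + 1
        pos = base + 1000 + 10 * i
        ref, alt = ("C", "T") if vclass == "SNV" else ("CA", "C")
        read_depth = (D.MEDIAN_READ_COV_CSF if specimen[sample] == "CSF"
                      else D.MEDIAN_READ_COV_PLASMA)
        mol_depth = 1670
        mol_alt, read_alt = _recipe_counts(af, mol_depth, read_depth, config)
        calls[sample].append(VariantCall(
            sample_id=sample, chrom=chrom, pos=pos, ref=ref, alt=alt,
            variant_class=VariantClass(vclass), gene=gene, protein_change=prot,
            af=af, read_depth=read_depth, read_alt_count=read_alt,
            mol_depth=mol_depth, mol_alt_count=mol_alt,
        ))

    tables = []
    for sample, _patient, spec in D.SAMPLES:
        is_csf = spec == "CSF"
        tables.append(SampleTable(
            sample_id=sample, specimen=spec, calls=calls[sample],
            run_stats={
                "mapped_reads": D.MAPPED_READS_CSF if is_csf else D.MAPPED_READS_PLASMA,
                "median_read_cov": (D.MEDIAN_READ_COV_CSF if is_csf
                                    else D.MEDIAN_READ_COV_PLASMA),
                "median_mol_cov": D.MEDIAN_MOL_COV,
            }))
    return tables


def dpcr_reference_rows(plasma_ml: float = 2.0) -> list[dict]:
    """Orthogonal dPCR reference for the twelve ALK fixture rows.

    Wild-type input (copies/mL) is derived from the recorded total dPCR
    input mass assuming ~303 haploid copies per ng over ``plasma_ml`` of
    plasma; positivity follows the MAF >= 0.1% / wt >= 300 copies-per-mL
    rule.
    """
    rows = []
    for sample, _cdna, prot, _drug, _line, _tier, _ngs, maf_dpcr, input_ng, _md \
            in D.ALK_ROWS:
        wt = input_ng * HAPLOID_COPIES_PER_NG / plasma_ml
        rows.append({
            "sample": sample, "gene": "ALK", "protein_change": prot,
            "maf_percent": maf_dpcr, "wt_copies_per_ml": round(wt, 1),
            "positive": maf_dpcr >= 0.1 and wt >= 300.0,
        })
    return rows


def table2_fixture(config: FilterConfig | None = None
                   ) -> tuple[list[SampleTable], list[dict]]:
    """The cohort fixture plus its matching dPCR reference rows."""
    return cohort_fixture(config), dpcr_reference_rows()


def expected_alk_tiers() -> list[tuple[str, str, Tier]]:
    """(sample, protein_change, recorded filter tier) for the 12 ALK rows."""
    return [(r[0], r[2], Tier(r[5])) for r in D.ALK_ROWS]


def alk_cohort_cross_table() -> CrossTable:
    """Synthetic reconstruction of the discovery-cohort 2x2 table.

    The published cross-table itself is not available; these counts are
    the unique small-integer 2x2 table whose PPA/NPA/ORA and
    Clopper-Pearson intervals match the reported 67% (35-90), 93%
    (75-99) and 85% (69-94) at the printed precision.
    """
    return CrossTable(tp=8, fp=2, fn=4, tn=25)


def valencia_cross_table() -> CrossTable:
    """Synthetic reconstruction of the 54-sample validation-cohort table.

    Uniquely determined by the reported 100% (29-100), 98% (90-100), 98%
    (90-100): the 29% PPA lower bound is the exact lower limit for 3/3.
    """
    return CrossTable(tp=3, fp=1, fn=0, tn=50)


@dataclass(frozen=True)
class SimConfig:
    """Stated world of the nonfiltered-table simulator.

    Depths match the cohort medians; the panel spans 52 genes with
    ``amplicon_count`` interrogated loci; background error per locus is
    log-normal (log10 mean/sd below).  ``spike_ins`` are
    (gene, protein_change, af_fraction, expected_tier) tuples injected
    with molecular counts that make the expected tier attainable under
    ``filter_config`` — incompatible spike-ins fail fast at generation.
    """

    seed: int = 0
    n_samples: int = 1
    amplicon_count: int = 52
    mol_depth_mean: float = 1670.8
    read_depth_median: int = 21261
    error_af_log10_mean: float = -4.0
    error_af_log10_sd: float = 0.3
    spike_ins: tuple = ()
    germline_rate: float = 0.0
    blacklist_artifact_rate: float = 0.0
    filter_config: FilterConfig = field(default_factory=FilterConfig)

    def __post_init__(self):
        for name in ("germline_rate", "blacklist_artifact_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.mol_depth_mean <= 0 or self.read_depth_median <= 0:
            raise ValueError("depths must be > 0")


_TIER_ORDER = {t.name: t for t in Tier}


def _validate_spike_in(gene, prot, af, expected, config: FilterConfig):
    expected = Tier(expected)
    whitelisted = config.whitelist.contains(VariantCall(
        sample_id="x", chrom="chrN", pos=1, ref="A", alt="T",
        variant_class=VariantClass.SNV, gene=gene, protein_change=prot, af=af,
        read_depth=1, read_alt_count=0, mol_depth=1, mol_alt_count=0))
    if expected is Tier.COMMERCIAL and af < config.commercial_af_min:
        raise ValueError(f"spike-in {gene} {prot}: af {af:g} below commercial floor")
    if expected is Tier.VALK_RESCUED:
        if not config.valk_af_min <= af < config.commercial_af_min:
            raise ValueError(f"spike-in {gene} {prot}: af {af:g} outside rescue band")
        if not whitelisted:
            raise ValueError(f"spike-in {gene} {prot}: locus not whitelisted")
    if expected is Tier.RAW_ONLY and af >= config.commercial_af_min:
        raise ValueError(f"spike-in {gene} {prot}: af {af:g} would be COMMERCIAL")
    if expected is Tier.RAW_ONLY and whitelisted and af >= config.valk_af_min:
        raise ValueError(f"spike-in {gene} {prot}: af {af:g} would be rescued")
    return expected


def generate_table(config: SimConfig, sample_index: int = 0) -> SampleTable:
    """One synthetic nonfiltered variant table, byte-deterministic in seed."""
    rng = np.random.default_rng([config.seed, sample_index])
    fc = config.filter_config
    sample_id = f"SIM{sample_index:03d}"
    calls: list[VariantCall] = []

    genes = [PANEL_GENES[i % len(PANEL_GENES)] for i in range(config.amplicon_count)]
    for i, gene in enumerate(genes):
        mol_depth = int(rng.poisson(config.mol_depth_mean))
        read_depth = max(int(rng.normal(config.read_depth_median,
                                        config.read_depth_median * 0.15)), 1000)
        chrom, base = D.GENE_LOCATIONS.get(gene, (f"chr{1 + i % 22}", 10_000_000))
        pos = base + 5000 + 37 * i

        r = rng.random()
        if r < config.blacklist_artifact_rate:
            # recurrent artifact: placed inside a blacklist region, visible AF
            bchrom, bstart, _bend, _ = DEFAULT_SIM_BLACKLIST.genomic[
                i % len(DEFAULT_SIM_BLACKLIST.genomic)]
            af = float(10 ** rng.normal(-3.2, 0.3))
            mol_alt = max(int(rng.binomial(mol_depth, af)), fc.mol_alt_min)
            chrom, pos = bchrom, bstart + i % 20
        elif r < config.blacklist_artifact_rate + config.germline_rate:
            af = float(np.clip(rng.normal(0.5, 0.03), 0.40, 1.0))
            mol_alt = int(rng.binomial(mol_depth, af))
        else:
            af_err = float(10 ** rng.normal(config.error_af_log10_mean,
                                            config.error_af_log10_sd))
            mol_alt = int(rng.binomial(mol_depth, af_err))
            if mol_alt == 0:
                continue  # not a candidate call
            af = mol_alt / mol_depth
        read_alt = min(max(round(af * read_depth), 1), read_depth)
        calls.append(VariantCall(
            sample_id=sample_id, chrom=chrom, pos=pos, ref="C", alt="T",
            variant_class=VariantClass.SNV, gene=gene, af=min(af, 1.0),
            read_depth=read_depth, read_alt_count=read_alt,
            mol_depth=mol_depth, mol_alt_count=min(mol_alt, mol_depth),
        ))

    for gene, prot, af, expected in config.spike_ins:
        expected = _validate_spike_in(gene, prot, af, expected, fc)
        mol_depth = max(int(rng.poisson(config.mol_depth_mean)), fc.mol_depth_min)
        mol_alt = int(rng.binomial(mol_depth, af))
        if expected is not Tier.REJECTED:
            mol_alt = max(mol_alt, min_detectable_mol_alt(mol_depth, fc))
        read_depth = max(int(rng.normal(config.read_depth_median,
                                        config.read_depth_median * 0.15)),
                         fc.read_depth_min)
        chrom, base = D.GENE_LOCATIONS.get(gene, ("chrN", 1_000_000))
        codon = codon_of(prot) or 1
        call = VariantCall(
            sample_id=sample_id, chrom=chrom, pos=base + 3 * codon, ref="G",
            alt="A", variant_class=VariantClass.SNV, gene=gene,
            protein_change=prot, af=af, read_depth=read_depth,
            read_alt_count=min(max(round(af * read_depth), 1), read_depth),
            mol_depth=mol_depth, mol_alt_count=min(mol_alt, mol_depth),
        )
        got = classify_variant(call, fc).tier
        if got is not expected:
            raise ValueError(f"spike-in {gene} {prot} at af {af:g} classified "
                             f"{got.name}, expected {expected.name}")
        calls.append(call)

    return SampleTable(
        sample_id=sample_id, specimen="plasma", calls=calls,
        run_stats={"mapped_reads": 9_775_623,
                   "median_read_cov": config.read_depth_median,
                   "median_mol_cov": config.mol_depth_mean})


def generate_dpcr_chip(maf_true: float, total_copies: int, n_valid: int,
                       seed: int = 0) -> DpcrResult:
    """Simulate one two-channel chip by multinomial co-encapsulation."""
    if not 0 <= maf_true <= 1:
        raise ValueError("maf_true must be in [0, 1]")
    if n_valid < 1:
        raise ValueError("n_valid must be >= 1")
    if total_copies / n_valid >= 1:
        raise ValueError("occupancy >= 1: too many copies for the chip")
    rng = np.random.default_rng(seed)
    mut_copies = int(rng.binomial(total_copies, maf_true))
    wt_copies = total_copies - mut_copies

    def positives(copies: int) -> np.ndarray:
        hits = rng.integers(0, n_valid, size=copies)
        return np.bincount(hits, minlength=n_valid) > 0

    mut_mask = positives(mut_copies)
    wt_mask = positives(wt_copies)
    return DpcrResult(
        n_mut_pos=int(mut_mask.sum()), n_wt_pos=int(wt_mask.sum()),
        n_double_pos=int((mut_mask & wt_mask).sum()),
        n_valid=n_valid, n_partitions=max(n_valid, 20000),
    )


def generate_dilution_series(assay: str = "sim-assay",
                             levels: tuple[float, ...] = (0.01, 0.005, 0.001, 0.0005),
                             replicates: int = 3,
                             slope: float = 1.0,
                             intercept: float = 0.0,
                             noise_sd: float = 1e-4,
                             seed: int = 0,
                             input_ng: float = 7.0) -> DilutionSeries:
    """Seeded linear dilution series with additive Gaussian response noise.

    Defaults mirror the assay-validation design: four mutant levels
    (1%, 0.5%, 0.1%, 0.05%) in wild-type background at 7 ng input.
    """
    rng = np.random.default_rng(seed)
    points = []
    for level in levels:
        for rep in range(1, replicates + 1):
            obs = intercept + slope * level + rng.normal(0, noise_sd)
            points.append((level, float(np.clip(obs, 0.0, 1.0)), rep))
    return DilutionSeries(assay=assay, points=tuple(points), input_ng=input_ng)
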