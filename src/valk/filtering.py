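"""The tier engine: rescue filtering of ultra-low-MAF candidate calls.

Commercial liquid-biopsy pipelines rarely report point mutations below
~0.5% allele fraction even though the chemistry's LOD is ~0.1%.  This
module re-screens every candidate call from the nonfiltered table and
assigns one of four tiers:

``COMMERCIAL``
    would be reported by the stock vendor filter (AF and read depth high),
``VALK_RESCUED``
    below the commercial AF cutoff but rescued: adequate molecular (UMI)
    depth, AF above the assay floor, and located in a whitelisted
    resistance-hotspot region (by default the ALK kinase domain,
    codons 1123-1278),
``RAW_ONLY``
    survives the hard rejects but meets neither reporting bar,
``REJECTED``
    blacklisted locus, apparent germline, below the molecular-count
    floor, or statistically indistinguishable from background assay error
    (one-sided binomial test of the molecular alt count against
    mol_depth x assay_error_rate).

Rules evaluate in a fixed order; the first hard reject wins, and every
verdict carries machine-readable reasons for audit.
"""

from __future__ import annotations

import enum
import logging
import re
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path

from scipy.stats import binom

from .io import SampleTable, VariantCall, VariantClass

__all__ = [
    "Tier",
    "FilterVerdict",
    "RegionSet",
    "FilterConfig",
    "DEFAULT_WHITELIST",
    "classify_variant",
    "run_filter",
    "load_region_set",
    "load_filter_config",
    "codon_of",
]

logger = logging.getLogger(__name__)


class Tier(str, enum.Enum):
    """Filter tiers, ordered REJECTED < RAW_ONLY < VALK_RESCUED < COMMERCIAL."""

    REJECTED = "REJECTED"
    RAW_ONLY = "RAW_ONLY"
    VALK_RESCUED = "VALK_RESCUED"
    COMMERCIAL = "COMMERCIAL"

    @property
    def rank(self) -> int:
        return ("REJECTED", "RAW_ONLY", "VALK_RESCUED", "COMMERCIAL").index(self.name)


@dataclass(frozen=True)
class FilterVerdict:
    tier: Tier
    reasons: tuple[str, ...]

    def __post_init__(self):
        if self.tier is Tier.REJECTED and not self.reasons:
            raise ValueError("REJECTED verdicts must carry a reason")


_PROT_CODON = re.compile(r"p\.(?:[A-Za-z*]{1,3})(\d+)")


def codon_of(protein_change: str) -> int | None:
    """First affected codon of an HGVS-style protein change, or None."""
    m = _PROT_CODON.search(protein_change or "")
    return int(m.group(1)) if m else None


@dataclass(frozen=True)
class RegionSet:
    """Genomic and/or protein-space regions, 1-based inclusive.

    ``genomic`` entries are (chrom, start, end, label); ``protein``
    entries are (gene, codon_start, codon_end, label).  Protein-space
    entries let hotspot lists avoid hard-coding genome-build coordinates.
    """

    genomic: tuple[tuple[str, int, int, str], ...] = ()
    protein: tuple[tuple[str, int, int, str], ...] = ()

    def __post_init__(self):
        for _, start, end, _ in (*self.genomic, *self.protein):
            if start > end:
                raise ValueError(f"region start {start} > end {end}")

    def __bool__(self) -> bool:
        return bool(self.genomic or self.protein)

    def contains(self, call: VariantCall) -> bool:
        for chrom, start, end, _ in self.genomic:
            if call.chrom == chrom and start <= call.pos <= end:
                return True
        codon = codon_of(call.protein_change)
        if codon is not None:
            for gene, cstart, cend, _ in self.protein:
                if call.gene == gene and cstart <= codon <= cend:
                    return True
        return False

    @staticmethod
    def merged(genomic=(), protein=()) -> "RegionSet":
        """Build a RegionSet, merging overlapping entries per label/space."""
        return RegionSet(genomic=_merge(genomic), protein=_merge(protein))


def _merge(entries):
    by_key: dict[tuple[str, str], list[list[int]]] = {}
    for space, start, end, label in entries:
        ivals = by_key.setdefault((space, label), [])
        ivals.append([start, end])
    out = []
    for (space, label), ivals in by_key.items():
        ivals.sort()
        merged = [ivals[0]]
        for start, end in ivals[1:]:
            if start <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], end)
            else:
                merged.append([start, end])
        out.extend((space, s, e, label) for s, e in merged)
    return tuple(sorted(out))


# ALK kinase domain in protein space: rescue-eligible hotspot region.
DEFAULT_WHITELIST = RegionSet(protein=(("ALK", 1123, 1278, "alk_kinase_domain"),))


@dataclass(frozen=True)
class FilterConfig:
    """All tunable thresholds of the tier engine.

    AF thresholds are fractions.  ``commercial_af_min`` (0.5%) reflects
    the empirical reporting floor of the stock pipeline;
    ``valk_af_min`` (0.03%) is the lowest AF the rescue tier will
    consider.  ``assay_error_rate`` parameterises the per-molecule
    background error against which molecular alt counts are tested
    (one-sided binomial, significance ``noise_alpha``).
    """

    commercial_af_min: float = 0.005
    valk_af_min: float = 0.0003
    mol_alt_min: int = 2
    mol_depth_min: int = 300
    read_depth_min: int = 1000
    germline_af_min: float = 0.40
    cnv_gain_min: float = 2.0
    cnv_loss_max: float = 0.5
    fusion_read_min: int = 20
    assay_error_rate: float = 0.0001
    noise_alpha: float = 0.01
    whitelist: RegionSet = DEFAULT_WHITELIST
    blacklist: RegionSet = RegionSet()

    def __post_init__(self):
        if not 0 <= self.valk_af_min <= self.commercial_af_min < self.germline_af_min <= 1:
            raise ValueError("require 0 <= valk_af_min <= commercial_af_min"
                             " < germline_af_min <= 1")
        if self.mol_alt_min < 1:
            raise ValueError("mol_alt_min must be >= 1")
        if not self.cnv_loss_max < 1 < self.cnv_gain_min:
            raise ValueError("require cnv_loss_max < 1 < cnv_gain_min")


_SMALL = (VariantClass.SNV, VariantClass.INDEL, VariantClass.MNP)


def noise_pvalue(mol_alt: int, mol_depth: int, error_rate: float) -> float:
    """P(X >= mol_alt) under X ~ Binomial(mol_depth, error_rate)."""
    if mol_depth <= 0:
        return 1.0
    # survival function at k-1 gives P(X >= k)
    return float(binom.sf(mol_alt - 1, mol_depth, error_rate))


def classify_variant(call: VariantCall, config: FilterConfig) -> FilterVerdict:
    """Assign a tier to one call.  See the module docstring for the rules."""
    reasons: list[str] = []

    # (0) hard rejects, first hit wins
    if config.blacklist.contains(call):
        return FilterVerdict(Tier.REJECTED, ("blacklist",))
    if call.variant_class in (VariantClass.SNV, VariantClass.MNP) \
            and call.af >= config.germline_af_min:
        return FilterVerdict(
            Tier.REJECTED, (f"germline: af {call.af:g} >= {config.germline_af_min:g}",))
    if call.variant_class not in (VariantClass.FUSION, VariantClass.CNV) \
            and call.mol_alt_count < config.mol_alt_min:
        return FilterVerdict(
            Tier.REJECTED,
            (f"mol_alt_floor: {call.mol_alt_count} < {config.mol_alt_min}",))
    if call.variant_class in _SMALL:
        p = noise_pvalue(call.mol_alt_count, call.mol_depth, config.assay_error_rate)
        if p >= config.noise_alpha:
            return FilterVerdict(
                Tier.REJECTED,
                (f"noise: binomial p {p:.3g} >= alpha {config.noise_alpha:g}",))
        reasons.append(f"noise_test: p {p:.3g} < {config.noise_alpha:g}")

    # class-specific reporting rules for structural call types
    if call.variant_class is VariantClass.CNV:
        if call.cnv_ratio >= config.cnv_gain_min:
            return FilterVerdict(
                Tier.COMMERCIAL,
                (f"cnv_gain: fold {call.cnv_ratio:g} >= {config.cnv_gain_min:g}",))
        if call.cnv_ratio <= config.cnv_loss_max:
            return FilterVerdict(
                Tier.COMMERCIAL,
                (f"cnv_loss: fold {call.cnv_ratio:g} <= {config.cnv_loss_max:g}",))
        return FilterVerdict(
            Tier.REJECTED, (f"cnv_within_normal: fold {call.cnv_ratio:g}",))
    if call.variant_class is VariantClass.FUSION:
        if call.read_alt_count >= config.fusion_read_min:
            return FilterVerdict(
                Tier.COMMERCIAL,
                (f"fusion_reads: {call.read_alt_count} >= {config.fusion_read_min}",))
        return FilterVerdict(
            Tier.REJECTED,
            (f"fusion_reads: {call.read_alt_count} < {config.fusion_read_min}",))

    # (1) commercial reporting bar
    if call.af >= config.commercial_af_min and call.read_depth >= config.read_depth_min:
        reasons.insert(0, f"af {call.af:g} >= commercial_af_min {config.commercial_af_min:g}")
        return FilterVerdict(Tier.COMMERCIAL, tuple(reasons))

    # (2) rescue bar: AF floor + molecular depth + hotspot whitelist
    if call.af >= config.valk_af_min and call.mol_depth >= config.mol_depth_min \
            and config.whitelist.contains(call):
        reasons.insert(0, f"af {call.af:g} >= valk_af_min {config.valk_af_min:g};"
                          f" mol_depth {call.mol_depth} >= {config.mol_depth_min};"
                          " whitelist")
        return FilterVerdict(Tier.VALK_RESCUED, tuple(reasons))

    # (3) survives hard rejects only
    reasons.insert(0, "below_reporting_thresholds")
    return FilterVerdict(Tier.RAW_ONLY, tuple(reasons))


def run_filter(table: SampleTable, config: FilterConfig | None = None
               ) -> list[tuple[VariantCall, FilterVerdict]]:
    """Classify every call of a sample table, preserving order."""
    config = config or FilterConfig()
    out = [(call, classify_variant(call, config)) for call in table.calls]
    counts = Counter(v.tier.name for _, v in out)
    logger.info("sample %s: %s", table.sample_id,
                ", ".join(f"{t}={counts.get(t, 0)}" for t in
                          ("COMMERCIAL", "VALK_RESCUED", "RAW_ONLY", "REJECTED")))
    return out


def sample_qc_warnings(table: SampleTable, *, min_median_mol_cov: float = 300
                       ) -> list[str]:
    """Per-sample QC: warn (never reject) on thin molecular coverage."""
    warnings_ = []
    cov = table.run_stats.get("median_mol_cov")
    if cov is not None and cov < min_median_mol_cov:
        warnings_.append(f"median molecular coverage {cov:g} below "
                         f"{min_median_mol_cov:g}; rescue tier unreliable")
    return warnings_


def load_region_set(path) -> RegionSet:
    """Load a region file mixing BED and protein-space lines.

    Lines whose first field starts with ``chr`` are 4-column BED
    (0-based half-open, converted to 1-based inclusive on load); any
    other line is protein-space: ``GENE codon_start codon_end label``.
    Overlapping entries are merged per label.
    """
    genomic, protein = [], []
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 4:
            raise ValueError(f"line {lineno}: expected 4 fields, got {len(fields)}")
        name, start_s, end_s, label = fields[:4]
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise ValueError(f"line {lineno}: non-integer coordinates") from None
        if name.lower().startswith("chr"):
            if start >= end:
                raise ValueError(f"line {lineno}: BED start {start} >= end {end}")
            genomic.append((name, start + 1, end, label))
        else:
            if start > end:
                raise ValueError(f"line {lineno}: codon start {start} > end {end}")
            protein.append((name, start, end, label))
    return RegionSet.merged(genomic=genomic, protein=protein)


_REGION_KEYS = ("whitelist", "blacklist")


def load_filter_config(path) -> FilterConfig:
    """Read a flat ``key=value`` config file mirroring FilterConfig fields.

    ``whitelist``/``blacklist`` values are paths to region files, resolved
    relative to the config file.
    """
    base = Path(path).parent
    config = FilterConfig()
    kwargs = {}
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"line {lineno}: expected key=value")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key in _REGION_KEYS:
            kwargs[key] = load_region_set(base / value)
        elif key in ("mol_alt_min", "mol_depth_min", "read_depth_min", "fusion_read_min"):
            kwargs[key] = int(value)
        elif hasattr(config, key):
            kwargs[key] = float(value)
        else:
            raise ValueError(f"line {lineno}: unknown key {key!r}")
    return replace(config, **kwargs)
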