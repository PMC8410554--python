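"""Cohort-level descriptive summaries of filtered liquid-biopsy profiles.

A variant counts as *detected* when its filter tier is anything but
REJECTED — the rescued and raw tiers are part of the reported landscape,
which is what makes the per-cohort detection metrics (variants per
sample, median MAF, fraction of plasma samples with an ALK mutation,
genes hit, sample-level co-mutation counts) comparable across filter
configurations.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np

from .filtering import FilterVerdict, Tier
from .io import SampleTable, VariantCall, VariantClass

__all__ = ["CohortSummary", "summarize", "gene_count"]

DETECTED_TIERS = (Tier.COMMERCIAL, Tier.VALK_RESCUED, Tier.RAW_ONLY)


@dataclass
class CohortSummary:
    n_samples: int
    n_plasma: int
    n_csf: int
    n_variants: int
    mean_variants_per_sample: float | None
    median_maf: float | None
    counts_by_class: dict[str, int]
    counts_by_gene: dict[str, int]
    samples_with_alk_mut: int
    fraction_plasma_with_alk_mut: float | None
    comutation: dict[tuple[str, str], int] = field(default_factory=dict)
    counts_by_tier: dict[str, int] = field(default_factory=dict)


def summarize(cohort: Sequence[tuple[SampleTable, Sequence[tuple[VariantCall, FilterVerdict]]]]
              ) -> CohortSummary:
    """Summarise a cohort of (sample table, verdicts) pairs.

    REJECTED calls are excluded everywhere.  ``median_maf`` is the median
    AF of detected non-CNV variants (CNVs have no allele fraction).  The
    ALK fraction uses plasma samples as its denominator.  An empty cohort
    yields zeros with the ratios flagged undefined (None).
    """
    n_samples = len(cohort)
    n_plasma = sum(1 for t, _ in cohort if t.specimen == "plasma")
    n_csf = n_samples - n_plasma

    detected: list[tuple[str, str, VariantCall]] = []  # (sample, specimen, call)
    tier_counts: Counter = Counter()
    for table, verdicts in cohort:
        for call, verdict in verdicts:
            tier_counts[verdict.tier.name] += 1
            if verdict.tier in DETECTED_TIERS:
                detected.append((table.sample_id, table.specimen, call))

    n_variants = len(detected)
    mafs = [c.af for _, _, c in detected if c.variant_class is not VariantClass.CNV]
    by_class = Counter(c.variant_class.value for _, _, c in detected)
    by_gene = Counter(c.gene for _, _, c in detected)

    alk_samples = {s for s, _, c in detected if c.gene == "ALK"}
    alk_plasma = {s for s, spec, c in detected if c.gene == "ALK" and spec == "plasma"}

    genes_per_sample: dict[str, set[str]] = {}
    for s, _, c in detected:
        genes_per_sample.setdefault(s, set()).add(c.gene)
    comut: Counter = Counter()
    for genes in genes_per_sample.values():
        for a, b in combinations(sorted(genes), 2):
            comut[(a, b)] += 1

    return CohortSummary(
        n_samples=n_samples,
        n_plasma=n_plasma,
        n_csf=n_csf,
        n_variants=n_variants,
        mean_variants_per_sample=(n_variants / n_samples) if n_samples else None,
        median_maf=float(np.median(mafs)) if mafs else None,
        counts_by_class=dict(by_class),
        counts_by_gene=dict(by_gene),
        samples_with_alk_mut=len(alk_samples),
        fraction_plasma_with_alk_mut=(len(alk_plasma) / n_plasma) if n_plasma else None,
        comutation=dict(comut),
        counts_by_tier=dict(tier_counts),
    )


def gene_count(summary: CohortSummary) -> int:
    """Number of genes with at least one detected variant of any class."""
    return sum(1 for count in summary.counts_by_gene.values() if count > 0)
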