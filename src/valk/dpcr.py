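"""Digital-PCR quantification: Poisson partition statistics and positivity.

A chip partitions the PCR mix into ~20,000 ~0.755 nL reactions.  The mean
template occupancy per partition is recovered from the fraction of
positive partitions by the Poisson correction λ = −ln(1 − p).  Mutant
allele fraction is the ratio of mutant template molecules to total
(mutant + wild-type) template molecules; absolute concentrations are
propagated back through the loading chain to copies per mL of plasma.

A sample is called positive when MAF ≥ 0.1% AND the wild-type input is at
least 300 copies/mL — the second condition guards against calling
positivity on chips with too little amplifiable template.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "DpcrResult",
    "DpcrCall",
    "lambda_per_partition",
    "maf_from_partitions",
    "call_positive",
    "quantify",
]


@dataclass(frozen=True)
class DpcrResult:
    """Raw partition counts and geometry for one two-channel chip.

    ``n_mut_pos`` / ``n_wt_pos`` count partitions positive in each
    channel inclusive of double positives (co-encapsulation of both
    templates), so ``n_mut_pos + n_wt_pos - n_double_pos <= n_valid``.
    Geometry defaults: 20,000 partitions of 0.755 nL; 14.5 of 18 µL of
    the PCR reaction loaded; 8.55 µL of eluate templated per reaction.
    """

    n_mut_pos: int
    n_wt_pos: int
    n_valid: int
    n_partitions: int = 20000
    n_double_pos: int = 0
    partition_volume_nl: float = 0.755
    reaction_volume_ul: float = 18.0
    loaded_fraction: float = 14.5 / 18.0
    template_volume_ul: float = 8.55
    elution_volume_ul: float = 50.0
    plasma_ml: float = 2.0

    def __post_init__(self):
        if min(self.n_mut_pos, self.n_wt_pos, self.n_double_pos) < 0:
            raise ValueError("partition counts must be >= 0")
        if not (self.n_mut_pos + self.n_wt_pos - self.n_double_pos
                <= self.n_valid <= self.n_partitions):
            raise ValueError("require n_mut_pos + n_wt_pos - n_double_pos"
                             " <= n_valid <= n_partitions")
        for name in ("partition_volume_nl", "reaction_volume_ul",
                     "loaded_fraction", "template_volume_ul",
                     "elution_volume_ul", "plasma_ml"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class DpcrCall:
    """Quantification of one chip: MAF, absolute copies, positivity."""

    maf: float | None
    mut_copies_per_ml: float
    wt_copies_per_ml: float
    positive: bool | None = None
    reasons: list[str] = field(default_factory=list)
    audit: dict = field(default_factory=dict)


class SaturationError(ValueError):
    """All valid partitions positive: occupancy too high to quantify."""


def lambda_per_partition(n_pos: int, n_valid: int) -> float:
    """Mean template copies per partition: λ = −ln(1 − n_pos/n_valid)."""
    if n_valid <= 0:
        raise ValueError("n_valid must be > 0")
    if not 0 <= n_pos <= n_valid:
        raise ValueError("require 0 <= n_pos <= n_valid")
    if n_pos == n_valid:
        raise SaturationError("all partitions positive; chip saturated")
    return -math.log1p(-n_pos / n_valid)


def maf_from_partitions(result: DpcrResult, *, naive: bool = False) -> DpcrCall:
    """MAF and copies/mL of plasma for one chip.

    With ``naive=True`` the MAF is the plain positive-partition ratio
    (no Poisson correction) — what a plain reading of "mutant molecules /
    total molecules" gives at low occupancy.
    """
    lam_mut = lambda_per_partition(result.n_mut_pos, result.n_valid)
    lam_wt = lambda_per_partition(result.n_wt_pos, result.n_valid)

    if naive:
        total_pos = result.n_mut_pos + result.n_wt_pos
        maf = None if total_pos == 0 else result.n_mut_pos / total_pos
    else:
        total = lam_mut + lam_wt
        maf = None if total == 0 else lam_mut / total

    # copies detected on chip -> concentration in the PCR mix -> copies in
    # the full reaction -> copies in the eluate -> per mL of plasma.
    chip_volume_ul = result.n_valid * result.partition_volume_nl * 1e-3
    scale = (result.reaction_volume_ul / chip_volume_ul) \
        * (result.elution_volume_ul / result.template_volume_ul) \
        / result.plasma_ml

    def copies_per_ml(lam: float) -> float:
        return lam * result.n_valid * scale

    audit = {
        "lambda_mut": lam_mut,
        "lambda_wt": lam_wt,
        "chip_volume_ul": chip_volume_ul,
        "reaction_volume_ul": result.reaction_volume_ul,
        "loaded_fraction": result.loaded_fraction,
        "eluate_per_reaction": result.elution_volume_ul / result.template_volume_ul,
        "plasma_ml": result.plasma_ml,
        "poisson_corrected": not naive,
    }
    reasons = [] if maf is not None else ["no_template"]
    return DpcrCall(maf=maf, mut_copies_per_ml=copies_per_ml(lam_mut),
                    wt_copies_per_ml=copies_per_ml(lam_wt),
                    reasons=reasons, audit=audit)


def call_positive(call: DpcrCall, maf_threshold: float = 0.001,
                  wt_copies_threshold: float = 300.0) -> DpcrCall:
    """Apply the positivity rule (both thresholds inclusive).

    positive ⟺ MAF ≥ ``maf_threshold`` AND wild-type input ≥
    ``wt_copies_threshold`` copies/mL; each failing rule is named.
    """
    if call.maf is None:
        raise ValueError("maf undefined (no template); cannot call positivity")
    reasons = list(call.reasons)
    ok = True
    if call.maf < maf_threshold:
        ok = False
        reasons.append("maf_below_threshold")
    if call.wt_copies_per_ml < wt_copies_threshold:
        ok = False
        reasons.append("insufficient_wt_input")
    if ok:
        reasons.append("maf_and_wt_input_pass")
    call.positive = ok
    call.reasons = reasons
    return call


def quantify(result: DpcrResult, *, naive: bool = False,
             maf_threshold: float = 0.001,
             wt_copies_threshold: float = 300.0) -> DpcrCall:
    """Convenience: quantify a chip and apply the positivity rule."""
    call = maf_from_partitions(result, naive=naive)
    if call.maf is None:
        call.positive = False
        return call
    return call_positive(call, maf_threshold, wt_copies_threshold)
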