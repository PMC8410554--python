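"""Agreement of the rescue filter against dPCR as an imperfect reference.

Because dPCR is an orthogonal but imperfect reference standard (not
ground truth), agreement is reported as positive / negative percentage
agreement and the overall rate of agreement (PPA / NPA / ORA) rather
than sensitivity / specificity, each with a Clopper-Pearson exact
binomial confidence interval.

Evaluation units are (sample, gene, protein change) keys: dPCR assays
are designed per protein change, so identity is defined in protein
space, not genomic coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Iterable

from scipy.stats import beta

__all__ = [
    "CrossTable",
    "AgreementStats",
    "clopper_pearson",
    "build_cross_table",
    "agreement_stats",
]


@dataclass
class CrossTable:
    """2x2 agreement counts of a test method against a reference."""

    tp: int
    fp: int
    fn: int
    tn: int
    keys: dict[str, list[Hashable]] = field(default_factory=dict)

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("cross-table counts must be >= 0")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class AgreementStats:
    """PPA/NPA/ORA point estimates with exact CIs; None when undefined."""

    ppa: float | None
    npa: float | None
    ora: float | None
    ppa_ci: tuple[float, float] | None
    npa_ci: tuple[float, float] | None
    ora_ci: tuple[float, float] | None
    alpha: float = 0.05


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial confidence interval for k successes in n trials.

    Lower bound is the alpha/2 quantile of Beta(k, n-k+1) (0 when k=0);
    upper bound is the 1-alpha/2 quantile of Beta(k+1, n-k) (1 when k=n).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError(f"k must be in [0, {n}], got {k}")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    low = 0.0 if k == 0 else float(beta.ppf(alpha / 2, k, n - k + 1))
    high = 1.0 if k == n else float(beta.ppf(1 - alpha / 2, k + 1, n - k))
    return low, high


def build_cross_table(test_calls: Iterable[tuple], ref_calls: Iterable[tuple]
                      ) -> CrossTable:
    """Cross-tabulate test vs reference positivity over shared keys.

    Each element is ``(key..., positive)`` — any hashable key tuple with a
    trailing boolean.  The two sets must cover exactly the same keys;
    duplicate or asymmetric keys raise.
    """
    def to_map(calls, side):
        out = {}
        for item in calls:
            *key, positive = item
            key = tuple(key)
            if key in out:
                raise ValueError(f"duplicate {side} key: {key}")
            out[key] = bool(positive)
        return out

    test = to_map(test_calls, "test")
    ref = to_map(ref_calls, "reference")
    only_test = sorted(set(test) - set(ref))
    only_ref = sorted(set(ref) - set(test))
    if only_test or only_ref:
        raise ValueError(f"asymmetric key sets; only in test: {only_test}; "
                         f"only in reference: {only_ref}")

    cells: dict[str, list] = {"tp": [], "fp": [], "fn": [], "tn": []}
    for key in test:
        cell = {(True, True): "tp", (True, False): "fp",
                (False, True): "fn", (False, False): "tn"}[(test[key], ref[key])]
        cells[cell].append(key)
    return CrossTable(tp=len(cells["tp"]), fp=len(cells["fp"]),
                      fn=len(cells["fn"]), tn=len(cells["tn"]), keys=cells)


def agreement_stats(table: CrossTable, alpha: float = 0.05) -> AgreementStats:
    """PPA = tp/(tp+fn), NPA = tn/(tn+fp), ORA = (tp+tn)/n.

    A statistic with a zero denominator is reported as None (undefined),
    never as zero.
    """
    if table.n < 1:
        return AgreementStats(None, None, None, None, None, None, alpha)

    def stat(k, n):
        if n == 0:
            return None, None
        return k / n, clopper_pearson(k, n, alpha)

    ppa, ppa_ci = stat(table.tp, table.tp + table.fn)
    npa, npa_ci = stat(table.tn, table.tn + table.fp)
    ora, ora_ci = stat(table.tp + table.tn, table.n)
    return AgreementStats(ppa, npa, ora, ppa_ci, npa_ci, ora_ci, alpha)
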