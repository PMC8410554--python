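"""Reading and writing of per-sample variant tables.

The input is a frozen, documented tab-separated dialect modelled on the
"nonfiltered" candidate-call export of UMI-based amplicon panels: one row
per candidate variant, carrying both raw-read and molecular (UMI-family)
depths and counts.  Columns required by the dialect::

    sample chrom pos ref alt class gene protein_change af read_depth
    read_alt mol_depth mol_alt hotspot_id cnv_ratio flags

Comment lines start with ``#``; one of them must declare the AF unit,
``#af_unit=percent`` or ``#af_unit=fraction`` (default percent, the unit
clinical reports print).  Extra columns are carried through as raw flags.

Outputs are an RFC-4180 CSV of rescued calls and a VCF 4.2 export whose
FILTER column carries the filter tier.
"""

from __future__ import annotations

import csv
import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "VariantClass",
    "VariantCall",
    "SampleTable",
    "DialectError",
    "RowError",
    "TableParseError",
    "REQUIRED_COLUMNS",
    "parse_variant_table",
    "write_variant_table",
    "write_rescued_csv",
    "export_vcf",
]

REQUIRED_COLUMNS = (
    "sample", "chrom", "pos", "ref", "alt", "class", "gene",
    "protein_change", "af", "read_depth", "read_alt", "mol_depth",
    "mol_alt", "hotspot_id", "cnv_ratio", "flags",
)


class VariantClass(str, enum.Enum):
    SNV = "SNV"
    INDEL = "INDEL"
    MNP = "MNP"
    FUSION = "FUSION"
    CNV = "CNV"


class DialectError(ValueError):
    """The file does not conform to the table dialect (e.g. missing column)."""


class RowError(ValueError):
    """A single data row failed parsing or its invariants."""

    def __init__(self, row_index: int, message: str):
        self.row_index = row_index
        super().__init__(f"row {row_index}: {message}")


class TableParseError(ValueError):
    """Aggregate of row-level errors raised in strict mode."""

    def __init__(self, errors: Sequence[RowError]):
        self.errors = list(errors)
        super().__init__("; ".join(str(e) for e in errors))


@dataclass(frozen=True)
class VariantCall:
    """One candidate variant from a sample's nonfiltered table.

    ``af`` is always a fraction in [0, 1] internally, whatever unit the
    source file used.  ``mol_depth``/``mol_alt_count`` are UMI consensus
    families covering / supporting the locus; ``read_depth``/
    ``read_alt_count`` are raw reads.  CNV rows have empty ref/alt and a
    gene-level fold change in ``cnv_ratio``.
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    variant_class: VariantClass
    gene: str
    protein_change: str = ""
    af: float = 0.0
    read_depth: int = 0
    read_alt_count: int = 0
    mol_depth: int = 0
    mol_alt_count: int = 0
    hotspot_id: str = ""
    cnv_ratio: float | None = None
    raw_flags: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not 0.0 <= self.af <= 1.0:
            raise ValueError(f"af must be in [0, 1], got {self.af}")
        if self.read_alt_count > self.read_depth:
            raise ValueError("read_alt_count exceeds read_depth")
        if self.mol_alt_count > self.mol_depth:
            raise ValueError("mol_alt_count exceeds mol_depth")
        if min(self.read_depth, self.read_alt_count,
               self.mol_depth, self.mol_alt_count) < 0:
            raise ValueError("depths and counts must be non-negative")
        is_cnv = self.variant_class is VariantClass.CNV
        if is_cnv != (self.cnv_ratio is not None):
            raise ValueError("cnv_ratio present iff variant_class is CNV")
        if is_cnv and (self.ref or self.alt):
            raise ValueError("CNV rows must have empty ref/alt")
        if not is_cnv and not (self.ref and self.alt):
            raise ValueError("non-CNV rows require ref and alt alleles")
        if self.cnv_ratio is not None and self.cnv_ratio <= 0:
            raise ValueError("cnv_ratio must be positive")


@dataclass
class SampleTable:
    """All candidate calls of one sample plus sequencing-run statistics."""

    sample_id: str
    specimen: str = "plasma"  # "plasma" or "CSF"
    calls: list[VariantCall] = field(default_factory=list)
    run_stats: dict = field(default_factory=dict)
    bad_rows: list[RowError] = field(default_factory=list)

    def __post_init__(self):
        if self.specimen not in ("plasma", "CSF"):
            raise ValueError(f"specimen must be 'plasma' or 'CSF', got {self.specimen!r}")
        for c in self.calls:
            if c.sample_id != self.sample_id:
                raise ValueError("all calls must share the table's sample_id")
        for v in self.run_stats.values():
            if v < 0:
                raise ValueError("run_stats values must be >= 0")


def _read_header_directives(path: Path) -> dict[str, str]:
    directives = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                directives[key.strip()] = value.strip()
    return directives


def parse_variant_table(path, sample_id: str, *, specimen: str | None = None,
                        strict: bool = True) -> SampleTable:
    """Parse one nonfiltered variant table into a :class:`SampleTable`.

    Numeric cells use a locale-independent decimal point.  Rows that fail
    parsing or the :class:`VariantCall` invariants raise a
    :class:`TableParseError` listing the offending row numbers when
    ``strict`` (the default); with ``strict=False`` they are collected on
    ``SampleTable.bad_rows`` instead of being silently dropped.  The
    specimen defaults to a ``#specimen=`` header directive, else plasma.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    directives = _read_header_directives(path)
    if specimen is None:
        specimen = directives.get("specimen", "plasma")
    af_unit = directives.get("af_unit", "percent")
    if af_unit not in ("percent", "fraction"):
        raise DialectError(f"unknown af_unit {af_unit!r}")
    af_scale = 0.01 if af_unit == "percent" else 1.0

    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str,
                         keep_default_na=False)
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty variant table", stacklevel=2)
        return SampleTable(sample_id=sample_id, specimen=specimen)

    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DialectError(f"missing required column(s): {', '.join(missing)}")
    extra_cols = [c for c in df.columns if c not in REQUIRED_COLUMNS]

    calls: list[VariantCall] = []
    errors: list[RowError] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rec = dict(zip(df.columns, row))
        try:
            calls.append(_row_to_call(rec, sample_id, af_scale, extra_cols))
        except (ValueError, KeyError) as exc:
            errors.append(RowError(i, str(exc)))
    if errors and strict:
        raise TableParseError(errors)

    run_stats = {}
    for key in ("mapped_reads", "median_read_cov", "median_mol_cov"):
        if key in directives:
            run_stats[key] = float(directives[key])
    return SampleTable(sample_id=sample_id, specimen=specimen, calls=calls,
                       run_stats=run_stats, bad_rows=errors)


def _row_to_call(rec: dict, sample_id: str, af_scale: float,
                 extra_cols: Sequence[str]) -> VariantCall:
    def num(col, conv):
        cell = rec[col].strip()
        try:
            return conv(cell)
        except ValueError:
            raise ValueError(f"unparseable {col} value {cell!r}") from None

    vclass = VariantClass(rec["class"].strip())
    cnv_cell = rec["cnv_ratio"].strip()
    cnv_ratio = float(cnv_cell) if cnv_cell else None
    flags = {t for t in rec["flags"].replace(",", ";").split(";") if t.strip()}
    flags.update(f"{c}={rec[c]}" for c in extra_cols if rec[c].strip())
    return VariantCall(
        sample_id=sample_id,
        chrom=rec["chrom"].strip(),
        pos=num("pos", int),
        ref=rec["ref"].strip(),
        alt=rec["alt"].strip(),
        variant_class=vclass,
        gene=rec["gene"].strip(),
        protein_change=rec["protein_change"].strip(),
        af=num("af", float) * af_scale,
        read_depth=num("read_depth", int),
        read_alt_count=num("read_alt", int),
        mol_depth=num("mol_depth", int),
        mol_alt_count=num("mol_alt", int),
        hotspot_id=rec["hotspot_id"].strip(),
        cnv_ratio=cnv_ratio,
        raw_flags=frozenset(flags),
    )


def write_variant_table(table: SampleTable, path, *, af_unit: str = "percent") -> None:
    """Write a :class:`SampleTable` back out in the input TSV dialect."""
    if af_unit not in ("percent", "fraction"):
        raise ValueError(f"unknown af_unit {af_unit!r}")
    scale = 100.0 if af_unit == "percent" else 1.0
    lines = [f"#af_unit={af_unit}", f"#specimen={table.specimen}"]
    for key in ("mapped_reads", "median_read_cov", "median_mol_cov"):
        if key in table.run_stats:
            lines.append(f"#{key}={table.run_stats[key]!r}")
    lines.append("\t".join(REQUIRED_COLUMNS))
    for c in table.calls:
        lines.append("\t".join([
            c.sample_id, c.chrom, str(c.pos), c.ref, c.alt,
            c.variant_class.value, c.gene, c.protein_change,
            repr(c.af * scale), str(c.read_depth), str(c.read_alt_count),
            str(c.mol_depth), str(c.mol_alt_count), c.hotspot_id,
            "" if c.cnv_ratio is None else repr(c.cnv_ratio),
            ";".join(sorted(c.raw_flags)),
        ]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


RESCUED_CSV_COLUMNS = ("sample", "locus", "gene", "protein_change", "class",
                       "af", "mol_depth", "mol_alt_count", "tier", "reasons")


def write_rescued_csv(verdicts: Iterable[tuple], path) -> None:
    """Write calls that passed any tier (everything but REJECTED) as CSV.

    One row per surviving call, deterministically ordered by
    (sample, chrom, pos, alt); ``reasons`` semicolon-joined.
    """
    rows = [(c, v) for c, v in verdicts if v.tier.value != "REJECTED"]
    rows.sort(key=lambda cv: (cv[0].sample_id, cv[0].chrom, cv[0].pos, cv[0].alt))
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(RESCUED_CSV_COLUMNS)
        for c, v in rows:
            writer.writerow([
                c.sample_id, f"{c.chrom}:{c.pos}", c.gene, c.protein_change,
                c.variant_class.value, repr(c.af), c.mol_depth,
                c.mol_alt_count, v.tier.value, ";".join(v.reasons),
            ])


_VCF_TIERS = ("COMMERCIAL", "VALK_RESCUED", "RAW_ONLY", "REJECTED")


def export_vcf(verdicts: Sequence[tuple], path) -> None:
    """Export verdicts as VCF 4.2; the FILTER column carries the tier.

    INFO keys: AF (allele fraction), MDP (molecular depth), MAC (molecular
    alt count), FC (gene fold change, CNV records only).  CNV calls become
    symbolic ``<CNV>`` records; a CNV row without a fold change is skipped
    with a warning.
    """
    import pysam

    header = pysam.VariantHeader()
    header.add_line('##fileformat=VCFv4.2')
    for tier in _VCF_TIERS:
        header.add_meta("FILTER", items=[("ID", tier),
                                         ("Description", f"Filter tier {tier}")])
    header.add_meta("INFO", items=[("ID", "AF"), ("Number", "A"), ("Type", "Float"),
                                   ("Description", "Variant allele fraction")])
    header.add_meta("INFO", items=[("ID", "MDP"), ("Number", "1"), ("Type", "Integer"),
                                   ("Description", "Molecular depth (UMI families)")])
    header.add_meta("INFO", items=[("ID", "MAC"), ("Number", "1"), ("Type", "Integer"),
                                   ("Description", "Molecular alt count (UMI families)")])
    header.add_meta("INFO", items=[("ID", "FC"), ("Number", "1"), ("Type", "Float"),
                                   ("Description", "Gene-level CNV fold change")])
    header.add_meta("ALT", items=[("ID", "CNV"), ("Description", "Copy number variant")])
    for chrom in sorted({c.chrom for c, _ in verdicts}):
        header.contigs.add(chrom)

    ordered = sorted(verdicts, key=lambda cv: (cv[0].chrom, cv[0].pos, cv[0].alt))
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for call, verdict in ordered:
            is_cnv = call.variant_class is VariantClass.CNV
            if is_cnv and call.cnv_ratio is None:
                warnings.warn(f"skipping CNV record without fold change: "
                              f"{call.gene} in {call.sample_id}", stacklevel=2)
                continue
            rec = vcf.new_record(
                contig=call.chrom, start=call.pos - 1,
                alleles=("N", "<CNV>") if is_cnv else (call.ref, call.alt),
            )
            rec.filter.add(verdict.tier.value)
            rec.info["AF"] = call.af
            rec.info["MDP"] = call.mol_depth
            rec.info["MAC"] = call.mol_alt_count
            if is_cnv:
                rec.info["FC"] = call.cnv_ratio
            vcf.write(rec)
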