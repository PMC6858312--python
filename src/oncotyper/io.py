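"""Readers and writers for the external formats the pipeline touches.

Somatic variants arrive as MAF-style tab-delimited tables, copy number as
either a gene-level log2-ratio matrix or a SEG segment table plus a BED-like
gene model, labels as a two-column TSV, and the assembled feature matrix is
round-tripped through a plain TSV.  All internal coordinates are 1-based
inclusive (the MAF convention); BED input is converted on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: MAF variant classifications treated as protein-altering by default.
#: The set is configurable in every reader that applies it.
DEFAULT_PROTEIN_ALTERING = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "Splice_Site",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Translation_Start_Site",
    }
)

_BASES = frozenset("ACGT")


class CohortFormatError(ValueError):
    """A file does not conform to the expected layout (missing column, bad header)."""


class RecordError(ValueError):
    """A single record is malformed; the message carries the 1-based line number."""


# Accepted header aliases, MAF names first.
_COLUMN_ALIASES = {
    "sample_id": ("Tumor_Sample_Barcode", "sample_id", "sample", "Sample"),
    "gene": ("Hugo_Symbol", "gene", "Gene", "gene_symbol"),
    "chrom": ("Chromosome", "chrom", "chr", "chromosome"),
    "pos": ("Start_Position", "Start_position", "pos", "position"),
    "ref_allele": ("Reference_Allele", "ref", "ref_allele"),
    "alt_allele": ("Tumor_Seq_Allele2", "alt", "alt_allele"),
    "variant_type": ("Variant_Type", "variant_type"),
    "variant_class": ("Variant_Classification", "variant_class"),
}
_CONTEXT_ALIASES = {
    "context5": ("context_5p", "context5", "Context_5p"),
    "context3": ("context_3p", "context3", "Context_3p"),
}


@dataclass(frozen=True, slots=True)
class VariantRecord:
    """One somatic variant call (SNV or short indel) for one sample."""

    sample_id: str
    gene: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    variant_type: str  # SNP | INS | DEL
    variant_class: str
    context5: Optional[str] = None  # 5' flanking base, if known
    context3: Optional[str] = None

    def validate(self, line: Optional[int] = None) -> None:
        where = f" (line {line})" if line is not None else ""
        if self.pos < 1:
            raise RecordError(f"position must be >= 1, got {self.pos}{where}")
        if self.variant_type == "SNP":
            if self.ref_allele not in _BASES or self.alt_allele not in _BASES:
                raise RecordError(
                    f"SNP alleles must be single bases in ACGT: "
                    f"{self.ref_allele!r}>{self.alt_allele!r}{where}"
                )
            if self.ref_allele == self.alt_allele:
                raise RecordError(f"SNP ref and alt alleles are identical{where}")


@dataclass(frozen=True)
class VariantTable:
    """An ordered collection of filtered variant records."""

    records: tuple[VariantRecord, ...]

    @property
    def samples(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.sample_id)
        return tuple(seen)

    @property
    def genes(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.gene)
        return tuple(seen)

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True, slots=True)
class SegmentRecord:
    """A copy-number segment with its mean log2 tumor/normal ratio."""

    sample_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    log2_ratio: float


@dataclass(frozen=True, slots=True)
class GeneInterval:
    gene: str
    chrom: str
    start: int  # 1-based inclusive
    end: int


@dataclass(frozen=True)
class LabelMap:
    """sample_id -> cancer-type label, with a deterministic (sorted) label order."""

    mapping: Mapping[str, str]

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(self.mapping)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.mapping.values())))

    def __len__(self) -> int:
        return len(self.mapping)

    def subset(self, samples: Iterable[str]) -> "LabelMap":
        keep = set(samples)
        return LabelMap({s: l for s, l in self.mapping.items() if s in keep})


def _resolve_columns(header: Sequence[str], aliases: dict, required: bool = True) -> dict:
    resolved = {}
    for canon, names in aliases.items():
        for name in names:
            if name in header:
                resolved[canon] = name
                break
        else:
            if required:
                raise CohortFormatError(
                    f"required column {canon!r} not found (accepted names: {', '.join(names)})"
                )
    return resolved


def read_variant_table(
    path: str | Path,
    keep_classes: Optional[Iterable[str]] = None,
) -> VariantTable:
    """Read an MAF-style variant table, keeping only protein-altering classes.

    Parameters
    ----------
    path
        Tab-delimited file whose header contains (aliases of) sample, gene,
        chrom, pos, ref, alt, variant_type and variant_class columns.
    keep_classes
        Variant classifications to retain; defaults to
        :data:`DEFAULT_PROTEIN_ALTERING`.

    Returns
    -------
    VariantTable with input order preserved and coordinates unchanged.
    """
    keep = frozenset(keep_classes) if keep_classes is not None else DEFAULT_PROTEIN_ALTERING
    df = pd.read_csv(path, sep="\t", dtype=str, comment=None)
    cols = _resolve_columns(list(df.columns), _COLUMN_ALIASES)
    ctx_cols = _resolve_columns(list(df.columns), _CONTEXT_ALIASES, required=False)

    records: list[VariantRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # 1-based, after the header
        row_d = dict(zip(df.columns, row))
        vclass = row_d[cols["variant_class"]]
        if vclass not in keep:
            continue
        raw_pos = row_d[cols["pos"]]
        try:
            pos = int(raw_pos)
        except (TypeError, ValueError):
            raise RecordError(f"unparseable position {raw_pos!r} at line {line}") from None

        def _ctx(key: str) -> Optional[str]:
            col = ctx_cols.get(key)
            if col is None:
                return None
            val = row_d[col]
            if val is None or (isinstance(val, float) and np.isnan(val)) or val == "":
                return None
            return str(val).upper()

        rec = VariantRecord(
            sample_id=str(row_d[cols["sample_id"]]),
            gene=str(row_d[cols["gene"]]),
            chrom=str(row_d[cols["chrom"]]),
            pos=pos,
            ref_allele=str(row_d[cols["ref_allele"]]).upper(),
            alt_allele=str(row_d[cols["alt_allele"]]).upper(),
            variant_type=str(row_d[cols["variant_type"]]).upper(),
            variant_class=str(vclass),
            context5=_ctx("context5"),
            context3=_ctx("context3"),
        )
        rec.validate(line=line)
        records.append(rec)
    return VariantTable(records=tuple(records))


def write_variant_table(table: VariantTable, path: str | Path) -> None:
    """Write a VariantTable as an MAF-style TSV (round-trips through read_variant_table)."""
    rows = [
        {
            "Tumor_Sample_Barcode": r.sample_id,
            "Hugo_Symbol": r.gene,
            "Chromosome": r.chrom,
            "Start_Position": r.pos,
            "Reference_Allele": r.ref_allele,
            "Tumor_Seq_Allele2": r.alt_allele,
            "Variant_Type": r.variant_type,
            "Variant_Classification": r.variant_class,
            "context_5p": r.context5 if r.context5 is not None else "",
            "context_3p": r.context3 if r.context3 is not None else "",
        }
        for r in table.records
    ]
    cols = [
        "Tumor_Sample_Barcode",
        "Hugo_Symbol",
        "Chromosome",
        "Start_Position",
        "Reference_Allele",
        "Tumor_Seq_Allele2",
        "Variant_Type",
        "Variant_Classification",
        "context_5p",
        "context_3p",
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_segment_table(path: str | Path) -> tuple[SegmentRecord, ...]:
    """Read a SEG-style table (sample, chrom, start, end, seg.mean); log2 values as-is."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 5:
        raise CohortFormatError(
            f"SEG file needs at least 5 columns (sample, chrom, start, end, seg.mean); "
            f"got {df.shape[1]}"
        )
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        sample, chrom, start_s, end_s, mean_s = (str(v) for v in row[:5])
        try:
            start, end, mean = int(start_s), int(end_s), float(mean_s)
        except ValueError:
            raise RecordError(f"unparseable segment at line {line}") from None
        if start > end:
            raise RecordError(f"segment start {start} > end {end} at line {line}")
        records.append(SegmentRecord(sample, chrom, start, end, mean))
    return tuple(records)


def read_gene_intervals(path: str | Path) -> tuple[GeneInterval, ...]:
    """Read a BED-like gene model (chrom, start, end, gene).

    BED coordinates are 0-based half-open and are converted to 1-based
    inclusive.  Duplicate gene symbols are merged to their spanning interval
    with a logged warning.
    """
    intervals: dict[str, GeneInterval] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise RecordError(f"BED line {line_no} has fewer than 4 fields")
            chrom, start_s, end_s, gene = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise RecordError(f"malformed interval at BED line {line_no}") from None
            if start >= end:
                raise RecordError(f"empty or inverted interval at BED line {line_no}")
            iv = GeneInterval(gene=gene, chrom=chrom, start=start + 1, end=end)
            prev = intervals.get(gene)
            if prev is not None:
                if prev.chrom != chrom:
                    raise RecordError(
                        f"gene {gene} appears on both {prev.chrom} and {chrom} (line {line_no})"
                    )
                logger.warning("duplicate interval for gene %s merged to spanning interval", gene)
                iv = GeneInterval(
                    gene=gene,
                    chrom=chrom,
                    start=min(prev.start, iv.start),
                    end=max(prev.end, iv.end),
                )
            intervals[gene] = iv
    return tuple(intervals.values())


def fetch_context(genome, chrom: str, pos: int) -> tuple[str, str]:
    """Look up the 5' and 3' flanking bases of a 1-based position.

    ``genome`` is any mapping from chromosome name to an indexable sequence
    (a :class:`pyfaidx.Fasta`, or a plain dict of strings).  At a contig
    boundary the missing flank is returned as ``'N'``; unknown chromosomes
    raise ``KeyError``.
    """
    try:
        seq = genome[chrom]
    except KeyError:
        raise KeyError(f"unknown chromosome {chrom!r} in reference") from None
    n = len(seq)
    if not 1 <= pos <= n:
        raise ValueError(f"position {pos} outside contig {chrom} (length {n})")

    def base(i: int) -> str:  # i is 0-based
        if i < 0 or i >= n:
            return "N"
        return str(seq[i : i + 1]).upper()

    return base(pos - 2), base(pos)


def read_label_table(path: str | Path) -> LabelMap:
    """Read a two-column sample/label TSV; a 'sample_id<TAB>label' header is optional."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise RecordError(f"label line {line_no} has fewer than 2 columns")
            sample, label = fields[0], fields[1]
            if line_no == 1 and sample.lower() in {"sample_id", "sample", "tumor_sample_barcode"}:
                continue
            if sample in mapping:
                raise CohortFormatError(f"duplicate sample_id {sample!r} at line {line_no}")
            mapping[sample] = label
    return LabelMap(mapping=mapping)


def write_label_table(labels: LabelMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tlabel\n")
        for sample, label in labels.mapping.items():
            fh.write(f"{sample}\t{label}\n")


def write_feature_matrix(matrix, path: str | Path) -> None:
    """Write a FeatureMatrix as TSV.

    The exome territory (Mb) is carried on a leading ``#territory_mb=`` comment
    so that write∘read is the identity on the schema.
    """
    df = matrix.to_dataframe()
    with open(path, "w") as fh:
        fh.write(f"#territory_mb={matrix.schema.territory_mb!r}\n")
        df.to_csv(fh, sep="\t", index_label="sample_id")


def read_feature_matrix(path: str | Path):
    """Read a feature-matrix TSV written by :func:`write_feature_matrix`."""
    from .features import FeatureMatrix, FeatureSchema, SPECTRUM_NAMES, SIGNATURE_NAMES, RATE_NAMES

    territory_mb = 38.0
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#territory_mb="):
            territory_mb = float(first.split("=", 1)[1])
            df = pd.read_csv(fh, sep="\t", index_col=0)
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t", index_col=0)

    cols = list(df.columns)
    try:
        rate_at = cols.index(RATE_NAMES[0])
    except ValueError:
        raise CohortFormatError(
            f"matrix header does not contain the rate column {RATE_NAMES[0]!r}; "
            "not a feature-matrix file"
        ) from None
    mut_genes = cols[:rate_at]
    expected_mid = list(RATE_NAMES) + list(SPECTRUM_NAMES) + list(SIGNATURE_NAMES)
    mid = cols[rate_at : rate_at + len(expected_mid)]
    if mid != expected_mid:
        raise CohortFormatError("matrix header does not match the rate/spectrum/signature schema")
    cnv_cols = cols[rate_at + len(expected_mid) :]
    bad = [c for c in cnv_cols if not c.startswith("cnv:")]
    if bad:
        raise CohortFormatError(f"unexpected trailing columns (not 'cnv:'-prefixed): {bad[:3]}")
    schema = FeatureSchema(
        mut_genes=tuple(mut_genes),
        cnv_genes=tuple(c[len("cnv:") :] for c in cnv_cols),
        territory_mb=territory_mb,
    )
    return FeatureMatrix(
        schema=schema,
        samples=tuple(str(s) for s in df.index),
        values=df.to_numpy(dtype=float),
    )


def read_cnv_matrix(path: str | Path) -> pd.DataFrame:
    """Read a gene-level log2 copy-ratio matrix (samples x genes, TSV)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_cnv_matrix(cnv: pd.DataFrame, path: str | Path) -> None:
    cnv.to_csv(path, sep="\t", index_label="sample_id")
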