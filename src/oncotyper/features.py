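"""Five-group somatic-alteration feature matrix.

Each tumor sample is described by the concatenation of five blocks:

* ``profile``    — per-gene counts of protein-altering SNVs and indels;
* ``rates``      — SNVs+indels per megabase, and the fraction of genes mutated;
* ``spectra``    — the six pyrimidine-referenced substitution classes
  (C>A, C>G, C>T, T>A, T>C, T>G) as per-sample proportions;
* ``signatures`` — the 96 trinucleotide-context substitution classes
  ({A,C,G,T} x 6 spectra x {A,C,G,T}) as per-sample proportions;
* ``scna``       — per-gene log2 tumor/normal copy ratios.

Purine-referenced SNVs are reverse-complemented into the pyrimidine frame
before spectrum/signature counting, so the representation is strand-invariant.
Indels contribute to the profile and rate blocks only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .io import GeneInterval, LabelMap, SegmentRecord, VariantTable, fetch_context

logger = logging.getLogger(__name__)

RATE_NAMES: tuple[str, ...] = ("snv_indel_per_mb", "mutated_gene_fraction")
SPECTRUM_NAMES: tuple[str, ...] = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
#: 96 keys "<5'><ref><3'>.<ref>><alt>", ordered by (5' base, spectrum, 3' base).
SIGNATURE_NAMES: tuple[str, ...] = tuple(
    f"{f5}{spec[0]}{f3}.{spec}" for f5 in "ACGT" for spec in SPECTRUM_NAMES for f3 in "ACGT"
)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
_BASES = frozenset("ACGT")

BLOCK_NAMES = ("profile", "rates", "spectra", "signatures", "scna")


def normalize_to_pyrimidine(
    ref: str, alt: str, context5: Optional[str], context3: Optional[str]
) -> tuple[str, Optional[str]]:
    """Map an SNV to its (spectrum, signature) names in the pyrimidine frame.

    Purine references (A/G) are complemented, and the flanks are swapped and
    complemented, so that e.g. ``(G>A, flanks T/C)`` becomes ``GCA.C>T``.
    Returns ``(spectrum, None)`` when a flank is missing or 'N'.
    """
    if ref not in _BASES or alt not in _BASES:
        raise ValueError(f"ref/alt must be single bases in ACGT, got {ref!r}>{alt!r}")
    if ref == alt:
        raise ValueError(f"ref and alt are identical: {ref!r}")
    if ref in "AG":
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        context5, context3 = (
            _COMPLEMENT.get(context3) if context3 else None,
            _COMPLEMENT.get(context5) if context5 else None,
        )
    spectrum = f"{ref}>{alt}"
    if context5 in _BASES and context3 in _BASES:
        return spectrum, f"{context5}{ref}{context3}.{spectrum}"
    return spectrum, None


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered feature-column layout: [profile | rates | spectra | signatures | scna]."""

    mut_genes: tuple[str, ...]
    cnv_genes: tuple[str, ...]
    territory_mb: float = 38.0

    @property
    def rate_names(self) -> tuple[str, ...]:
        return RATE_NAMES

    @property
    def spectrum_names(self) -> tuple[str, ...]:
        return SPECTRUM_NAMES

    @property
    def signature_names(self) -> tuple[str, ...]:
        return SIGNATURE_NAMES

    @property
    def columns(self) -> tuple[str, ...]:
        return (
            self.mut_genes
            + RATE_NAMES
            + SPECTRUM_NAMES
            + SIGNATURE_NAMES
            + tuple(f"cnv:{g}" for g in self.cnv_genes)
        )

    @property
    def dimension(self) -> int:
        return len(self.mut_genes) + 2 + 6 + 96 + len(self.cnv_genes)

    def block_slice(self, block: str) -> slice:
        gm, gc = len(self.mut_genes), len(self.cnv_genes)
        offsets = {
            "profile": (0, gm),
            "rates": (gm, gm + 2),
            "spectra": (gm + 2, gm + 8),
            "signatures": (gm + 8, gm + 104),
            "scna": (gm + 104, gm + 104 + gc),
        }
        if block not in offsets:
            raise KeyError(f"unknown feature block {block!r}; expected one of {BLOCK_NAMES}")
        lo, hi = offsets[block]
        return slice(lo, hi)


def build_schema(
    mut_genes: Iterable[str], cnv_genes: Iterable[str], territory_mb: float = 38.0
) -> FeatureSchema:
    """Build a deterministic schema: genes upper-cased, de-dup-checked and sorted."""
    if territory_mb <= 0:
        raise ValueError("territory_mb must be positive")

    def _norm(genes: Iterable[str], kind: str) -> tuple[str, ...]:
        normed = [g.upper() for g in genes]
        if not normed:
            raise ValueError(f"{kind} gene list is empty")
        seen: set[str] = set()
        for g in normed:
            if g in seen:
                raise ValueError(f"duplicate {kind} gene after case normalization: {g}")
            seen.add(g)
        return tuple(sorted(normed))

    return FeatureSchema(
        mut_genes=_norm(mut_genes, "mutation"),
        cnv_genes=_norm(cnv_genes, "copy-number"),
        territory_mb=float(territory_mb),
    )


@dataclass(frozen=True)
class FeatureMatrix:
    schema: FeatureSchema
    samples: tuple[str, ...]
    values: np.ndarray  # shape (n_samples, schema.dimension)

    def __post_init__(self):
        if self.values.shape != (len(self.samples), self.schema.dimension):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.samples)} samples x {self.schema.dimension} features"
            )

    def block(self, name: str) -> np.ndarray:
        return self.values[:, self.schema.block_slice(name)]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.samples), columns=list(self.schema.columns))

    def subset_samples(self, samples: Sequence[str]) -> "FeatureMatrix":
        index = {s: i for i, s in enumerate(self.samples)}
        rows = [index[s] for s in samples]
        return FeatureMatrix(self.schema, tuple(samples), self.values[rows])


def _sample_index(variants: VariantTable, samples: Optional[Sequence[str]]) -> dict[str, int]:
    if samples is None:
        samples = variants.samples
    return {s: i for i, s in enumerate(samples)}


def mutation_profile(
    variants: VariantTable, schema: FeatureSchema, samples: Optional[Sequence[str]] = None
) -> np.ndarray:
    """Per-sample counts of protein-altering SNVs and indels for each schema gene.

    Variants in genes absent from the schema are dropped (a counter is logged).
    """
    idx = _sample_index(variants, samples)
    gene_idx = {g: j for j, g in enumerate(schema.mut_genes)}
    out = np.zeros((len(idx), len(schema.mut_genes)))
    dropped = 0
    for r in variants.records:
        if r.sample_id not in idx:
            continue
        j = gene_idx.get(r.gene.upper())
        if j is None:
            dropped += 1
            continue
        out[idx[r.sample_id], j] += 1
    if dropped:
        logger.info("mutation_profile: %d variants in genes outside the schema were dropped", dropped)
    return out


def mutation_rates(
    variants: VariantTable, schema: FeatureSchema, samples: Optional[Sequence[str]] = None
) -> np.ndarray:
    """Two rates per sample: (SNVs+indels)/territory_mb and mutated-gene fraction."""
    profile = mutation_profile(variants, schema, samples)
    idx = _sample_index(variants, samples)
    totals = np.zeros(len(idx))
    for r in variants.records:
        i = idx.get(r.sample_id)
        if i is not None:
            totals[i] += 1
    rate1 = totals / schema.territory_mb
    rate2 = (profile > 0).sum(axis=1) / len(schema.mut_genes)
    return np.column_stack([rate1, rate2])


def mutation_spectra(
    variants: VariantTable, samples: Optional[Sequence[str]] = None
) -> np.ndarray:
    """Per-sample proportions over the six substitution classes (SNVs only)."""
    idx = _sample_index(variants, samples)
    spec_idx = {s: j for j, s in enumerate(SPECTRUM_NAMES)}
    counts = np.zeros((len(idx), 6))
    for r in variants.records:
        i = idx.get(r.sample_id)
        if i is None or r.variant_type != "SNP":
            continue
        spectrum, _ = normalize_to_pyrimidine(r.ref_allele, r.alt_allele, r.context5, r.context3)
        counts[i, spec_idx[spectrum]] += 1
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        props = np.where(totals > 0, counts / np.where(totals > 0, totals, 1), 0.0)
    return props


def mutation_signatures(
    variants: VariantTable,
    genome=None,
    samples: Optional[Sequence[str]] = None,
) -> np.ndarray:
    """Per-sample proportions over the 96 trinucleotide-context classes.

    SNVs must carry their flanking bases on the record, or a reference
    ``genome`` must be supplied for lookup.  SNVs with an 'N' flank are
    excluded from both numerator and denominator.
    """
    idx = _sample_index(variants, samples)
    sig_idx = {s: j for j, s in enumerate(SIGNATURE_NAMES)}
    counts = np.zeros((len(idx), 96))
    for r in variants.records:
        i = idx.get(r.sample_id)
        if i is None or r.variant_type != "SNP":
            continue
        c5, c3 = r.context5, r.context3
        if c5 is None or c3 is None:
            if genome is None:
                raise ValueError(
                    "SNV without flanking context and no reference genome supplied: "
                    f"{r.sample_id} {r.chrom}:{r.pos} {r.ref_allele}>{r.alt_allele}"
                )
            c5, c3 = fetch_context(genome, r.chrom, r.pos)
        _, signature = normalize_to_pyrimidine(r.ref_allele, r.alt_allele, c5, c3)
        if signature is not None:
            counts[i, sig_idx[signature]] += 1
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        props = np.where(totals > 0, counts / np.where(totals > 0, totals, 1), 0.0)
    return props


def scna_features(
    source,
    schema: FeatureSchema,
    samples: Optional[Sequence[str]] = None,
    strict: bool = False,
) -> np.ndarray:
    """Gene-level log2 copy-ratio block.

    ``source`` is either a samples x genes DataFrame (values passed through,
    schema genes missing from the matrix filled with 0.0) or a
    ``(segments, gene_model)`` pair, in which case each gene gets the
    length-weighted mean log2 ratio of its overlapping segments (1-based
    inclusive overlap), 0.0 if none overlap.

    Samples absent from the source are zero-filled with a warning, or raise
    when ``strict`` is set.
    """
    if isinstance(source, pd.DataFrame):
        if samples is None:
            samples = tuple(str(s) for s in source.index)
        upper_cols = {str(c).upper(): c for c in source.columns}
        out = np.zeros((len(samples), len(schema.cnv_genes)))
        missing_samples = [s for s in samples if s not in set(map(str, source.index))]
        if missing_samples:
            msg = f"{len(missing_samples)} samples missing from copy-number matrix"
            if strict:
                raise ValueError(msg + f": {missing_samples[:5]}")
            logger.warning("%s; filled with 0.0", msg)
        sub = source.reindex(index=list(samples))
        for j, gene in enumerate(schema.cnv_genes):
            col = upper_cols.get(gene)
            if col is not None:
                out[:, j] = np.nan_to_num(sub[col].to_numpy(dtype=float), nan=0.0)
        return out

    segments, gene_model = source
    if samples is None:
        seen: dict[str, None] = {}
        for s in segments:
            seen.setdefault(s.sample_id)
        samples = tuple(seen)
    genes: Sequence[GeneInterval] = list(gene_model)
    by_sample: dict[str, list[SegmentRecord]] = {}
    for seg in segments:
        by_sample.setdefault(seg.sample_id, []).append(seg)
    gene_pos = {g.gene.upper(): g for g in genes}
    out = np.zeros((len(samples), len(schema.cnv_genes)))
    missing = [s for s in samples if s not in by_sample]
    if missing:
        msg = f"{len(missing)} samples missing from segment table"
        if strict:
            raise ValueError(msg + f": {missing[:5]}")
        if missing:
            logger.warning("%s; filled with 0.0", msg)
    for i, sample in enumerate(samples):
        segs = by_sample.get(sample, [])
        for j, gene in enumerate(schema.cnv_genes):
            g = gene_pos.get(gene)
            if g is None:
                continue
            wsum = 0.0
            vsum = 0.0
            for seg in segs:
                if seg.chrom != g.chrom:
                    continue
                ov = min(seg.end, g.end) - max(seg.start, g.start) + 1
                if ov > 0:
                    wsum += ov
                    vsum += ov * seg.log2_ratio
            out[i, j] = vsum / wsum if wsum > 0 else 0.0
    return out


def assemble_matrix(
    variants: VariantTable,
    scna_source,
    labels: LabelMap,
    schema: FeatureSchema,
    genome=None,
) -> FeatureMatrix:
    """Concatenate the five blocks for every labeled sample, in schema order."""
    samples = labels.samples
    variant_samples = set(variants.samples)
    if isinstance(scna_source, pd.DataFrame):
        cn_samples = set(map(str, scna_source.index))
    else:
        cn_samples = {s.sample_id for s in scna_source[0]}
    orphans = [s for s in samples if s not in variant_samples and s not in cn_samples]
    if orphans:
        raise ValueError(
            f"{len(orphans)} labeled samples absent from both variant and copy-number "
            f"sources: {orphans[:5]}"
        )
    values = np.hstack(
        [
            mutation_profile(variants, schema, samples),
            mutation_rates(variants, schema, samples),
            mutation_spectra(variants, samples),
            mutation_signatures(variants, genome, samples),
            scna_features(scna_source, schema, samples),
        ]
    )
    return FeatureMatrix(schema=schema, samples=tuple(samples), values=values)
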