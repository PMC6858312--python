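"""Synthetic multi-class tumor cohorts with planted, recoverable signal.

The simulator emulates the statistical structure that makes somatic
alterations informative about cancer type: each simulated type has its own
driver genes (mutated far above background), its own 96-context substitution
signature, and its own set of copy-number-shifted genes.  Per-sample mutation
burden is lognormal.  Trinucleotide contexts are written directly onto the
variant records, so featurization needs no reference FASTA.

The generator is fully seeded: the same configuration and seed reproduce the
cohort byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Union

import numpy as np
import pandas as pd

from .features import SIGNATURE_NAMES
from .io import LabelMap, VariantRecord, VariantTable


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the cohort generator.

    ``background_mutation_rate`` is the median SNV count per sample;
    per-sample burden is lognormal around it with ``burden_lognormal_sigma``.
    ``driver_mutation_prob`` is the probability that any given SNV lands in
    one of its type's driver genes.  Type signatures are Dirichlet draws over
    the 96 contexts; small ``signature_dirichlet_alpha`` makes them spiky and
    type-distinct.
    """

    n_types: int = 3
    samples_per_type: Union[int, tuple[int, ...]] = 30
    n_mut_genes: int = 200
    n_cnv_genes: int = 100
    drivers_per_type: int = 4
    driver_mutation_prob: float = 0.35
    background_mutation_rate: float = 40.0
    burden_lognormal_sigma: float = 0.4
    signature_dirichlet_alpha: float = 0.05
    cna_genes_per_type: int = 10
    cna_log2_shift_mean: float = 0.5
    cna_log2_shift_sd: float = 0.35
    territory_mb: float = 38.0
    seed: int = 13

    def validate(self) -> None:
        counts = {
            "n_types": self.n_types,
            "n_mut_genes": self.n_mut_genes,
            "n_cnv_genes": self.n_cnv_genes,
            "drivers_per_type": self.drivers_per_type,
            "cna_genes_per_type": self.cna_genes_per_type,
        }
        for name, v in counts.items():
            if v < 1:
                raise ValueError(f"{name} must be >= 1, got {v}")
        sizes = self.per_type_sizes()
        if any(s < 1 for s in sizes):
            raise ValueError("samples_per_type entries must be >= 1")
        if len(sizes) != self.n_types:
            raise ValueError("samples_per_type list length must equal n_types")
        if not 0.0 <= self.driver_mutation_prob <= 1.0:
            raise ValueError("driver_mutation_prob must be a probability")
        if self.drivers_per_type * self.n_types > self.n_mut_genes:
            raise ValueError("drivers_per_type x n_types exceeds n_mut_genes")
        if self.cna_genes_per_type * self.n_types > self.n_cnv_genes:
            raise ValueError("cna_genes_per_type x n_types exceeds n_cnv_genes")
        if self.background_mutation_rate <= 0 or self.territory_mb <= 0:
            raise ValueError("rates and territory must be positive")

    def per_type_sizes(self) -> tuple[int, ...]:
        if isinstance(self.samples_per_type, int):
            return (self.samples_per_type,) * self.n_types
        return tuple(self.samples_per_type)


@dataclass(frozen=True)
class SimulationTruth:
    """What was planted: the ground truth downstream stages should recover."""

    drivers: dict[str, tuple[str, ...]]  # type -> driver genes
    signatures: dict[str, np.ndarray]  # type -> 96-dim probability vector
    signature_contexts: dict[str, tuple[str, ...]]  # type -> dominant context names
    cna_genes: dict[str, tuple[str, ...]]  # type -> copy-shifted genes

    @property
    def informative_features(self) -> tuple[str, ...]:
        """Union of all planted feature names, in schema naming."""
        names: dict[str, None] = {}
        for t in sorted(self.drivers):
            for g in self.drivers[t]:
                names.setdefault(g)
        for t in sorted(self.signature_contexts):
            for c in self.signature_contexts[t]:
                names.setdefault(c)
        for t in sorted(self.cna_genes):
            for g in self.cna_genes[t]:
                names.setdefault(f"cnv:{g}")
        return tuple(names)

    def to_json(self) -> str:
        payload = {
            "drivers": {t: list(v) for t, v in self.drivers.items()},
            "signatures": {t: list(map(float, v)) for t, v in self.signatures.items()},
            "signature_contexts": {t: list(v) for t, v in self.signature_contexts.items()},
            "cna_genes": {t: list(v) for t, v in self.cna_genes.items()},
        }
        return json.dumps(payload, indent=1)


def default_config(scale: str) -> SimulationConfig:
    """Canned configurations: ``tiny`` for unit-scale work, ``desk`` for full runs.

    tiny: 3 types x 30 samples, 200 mutation genes, 100 copy-number genes
    (feature dimension 404).  desk: 6 types x 200 samples, 2,000 mutation
    genes, 1,000 copy-number genes.
    """
    if scale == "tiny":
        return SimulationConfig()
    if scale == "desk":
        return SimulationConfig(
            n_types=6,
            samples_per_type=200,
            n_mut_genes=2000,
            n_cnv_genes=1000,
            drivers_per_type=5,
            driver_mutation_prob=0.5,
            background_mutation_rate=60.0,
            burden_lognormal_sigma=0.5,
            signature_dirichlet_alpha=0.1,
            cna_genes_per_type=20,
            cna_log2_shift_mean=0.5,
            cna_log2_shift_sd=0.35,
            territory_mb=38.0,
            seed=29,
        )
    raise ValueError(f"unknown scale {scale!r}; expected 'tiny' or 'desk'")


def schema_for(config: SimulationConfig):
    """The feature schema over the generator's full gene universes."""
    from .features import build_schema

    return build_schema(
        [f"MG{i:05d}" for i in range(config.n_mut_genes)],
        [f"CG{i:05d}" for i in range(config.n_cnv_genes)],
        territory_mb=config.territory_mb,
    )


def _dominant_contexts(sig: np.ndarray, mass: float = 0.8) -> tuple[str, ...]:
    """Smallest set of contexts carrying at least ``mass`` of the signature."""
    order = np.argsort(-sig, kind="stable")
    cum = np.cumsum(sig[order])
    k = int(np.searchsorted(cum, mass) + 1)
    return tuple(SIGNATURE_NAMES[i] for i in sorted(order[:k]))


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[VariantTable, pd.DataFrame, LabelMap, SimulationTruth]:
    """Generate a labeled cohort: variants, gene-level log2 matrix, labels, truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    mut_genes = [f"MG{i:05d}" for i in range(config.n_mut_genes)]
    cnv_genes = [f"CG{i:05d}" for i in range(config.n_cnv_genes)]
    types = [f"CT{i + 1:02d}" for i in range(config.n_types)]
    sizes = config.per_type_sizes()

    # Disjoint driver / copy-shifted gene sets per type, via seeded shuffles.
    mut_perm = rng.permutation(config.n_mut_genes)
    cnv_perm = rng.permutation(config.n_cnv_genes)
    drivers: dict[str, tuple[str, ...]] = {}
    cna_sets: dict[str, tuple[str, ...]] = {}
    signatures: dict[str, np.ndarray] = {}
    sig_contexts: dict[str, tuple[str, ...]] = {}
    for ti, t in enumerate(types):
        d = mut_perm[ti * config.drivers_per_type : (ti + 1) * config.drivers_per_type]
        drivers[t] = tuple(sorted(mut_genes[i] for i in d))
        c = cnv_perm[ti * config.cna_genes_per_type : (ti + 1) * config.cna_genes_per_type]
        cna_sets[t] = tuple(sorted(cnv_genes[i] for i in c))
        sig = rng.dirichlet(np.full(96, config.signature_dirichlet_alpha))
        signatures[t] = sig
        sig_contexts[t] = _dominant_contexts(sig)

    variant_classes = np.array(["Missense_Mutation", "Nonsense_Mutation", "Splice_Site"])
    class_probs = np.array([0.8, 0.12, 0.08])

    records: list[VariantRecord] = []
    labels: dict[str, str] = {}
    sample_ids: list[str] = []
    for ti, t in enumerate(types):
        driver_idx = np.array([mut_genes.index(g) for g in drivers[t]])
        sig = signatures[t]
        for si in range(sizes[ti]):
            sample = f"{t}_S{si:04d}"
            sample_ids.append(sample)
            labels[sample] = t
            n_snv = int(
                round(
                    rng.lognormal(
                        np.log(config.background_mutation_rate), config.burden_lognormal_sigma
                    )
                )
            )
            n_snv = max(n_snv, 1)
            is_driver = rng.random(n_snv) < config.driver_mutation_prob
            gene_ids = np.where(
                is_driver,
                driver_idx[rng.integers(0, len(driver_idx), n_snv)],
                rng.integers(0, config.n_mut_genes, n_snv),
            )
            ctx_ids = rng.choice(96, size=n_snv, p=sig)
            classes = variant_classes[rng.choice(3, size=n_snv, p=class_probs)]
            positions = rng.integers(1_000_000, 50_000_000, n_snv)
            for gi, ci, vc, pos in zip(gene_ids, ctx_ids, classes, positions):
                name = SIGNATURE_NAMES[ci]  # e.g. "ACA.C>T"
                trinuc, spectrum = name.split(".")
                records.append(
                    VariantRecord(
                        sample_id=sample,
                        gene=mut_genes[gi],
                        chrom=f"chr{1 + gi % 22}",
                        pos=int(pos),
                        ref_allele=spectrum[0],
                        alt_allele=spectrum[2],
                        variant_type="SNP",
                        variant_class=str(vc),
                        context5=trinuc[0],
                        context3=trinuc[2],
                    )
                )
            # ~10% of the SNV count as protein-altering indels, contexts absent.
            n_indel = int(rng.binomial(n_snv, 0.1))
            ind_genes = rng.integers(0, config.n_mut_genes, n_indel)
            ind_is_ins = rng.random(n_indel) < 0.5
            ind_pos = rng.integers(1_000_000, 50_000_000, n_indel)
            for gi, ins, pos in zip(ind_genes, ind_is_ins, ind_pos):
                records.append(
                    VariantRecord(
                        sample_id=sample,
                        gene=mut_genes[gi],
                        chrom=f"chr{1 + gi % 22}",
                        pos=int(pos),
                        ref_allele="-" if ins else "A",
                        alt_allele="A" if ins else "-",
                        variant_type="INS" if ins else "DEL",
                        variant_class="Frame_Shift_Ins" if ins else "Frame_Shift_Del",
                    )
                )

    # Copy-number matrix: N(0, 0.1) noise plus per-type shifts on planted genes.
    n_samples = len(sample_ids)
    cnv = rng.normal(0.0, 0.1, size=(n_samples, config.n_cnv_genes))
    row = 0
    for ti, t in enumerate(types):
        cols = [cnv_genes.index(g) for g in cna_sets[t]]
        block = rng.normal(
            config.cna_log2_shift_mean, config.cna_log2_shift_sd, size=(sizes[ti], len(cols))
        )
        cnv[row : row + sizes[ti], np.array(cols)] += block
        row += sizes[ti]
    cnv_df = pd.DataFrame(cnv, index=sample_ids, columns=cnv_genes)

    truth = SimulationTruth(
        drivers=drivers,
        signatures=signatures,
        signature_contexts=sig_contexts,
        cna_genes=cna_sets,
    )
    return VariantTable(records=tuple(records)), cnv_df, LabelMap(mapping=labels), truth
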