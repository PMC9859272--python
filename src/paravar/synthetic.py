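"""Synthetic gene families with region-specific selection and variant tables.

Each gene gets a random reference open reading frame (uniform over the 61
sense codons) and a star-tree set of orthologs: every non-reference species
is mutated independently from the reference, at most one nucleotide change
per codon. Substitution probability and the nonsynonymous fraction (omega)
differ between a designated domain region and its flanks, so the realized
per-codon synonymous/nonsynonymous counts are exactly what the conservation
counter must recover -- the generator doubles as its oracle.

Variant tables emulate four database schemas (gnomAD-, ClinVar-, Geno2MP-
and COSMIC-like) with planted source memberships recorded in the truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._codons import SENSE_CODONS, neighbor_classes, translate_codon
from .conservation import MIN_PROTEIN_LENGTH, CodonAlignment
from .coords import DomainAnnotation
from .variants import SOURCES, VariantRecord, write_variants_tsv

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

SIGNIFICANCES = (
    "Pathogenic",
    "Likely pathogenic",
    "Uncertain significance",
    "Likely benign",
    "Benign",
)
TISSUES = ("large_intestine", "lung", "skin", "stomach", "breast", "thyroid")
HISTOLOGIES = ("adenocarcinoma", "squamous_cell_carcinoma", "carcinoma_NS")


@dataclass(frozen=True)
class FamilySimConfig:
    n_genes: int = 4
    species_per_gene: int = 30
    protein_length: int = 120
    domain_start: int = 31
    domain_end: int = 109  # 79-codon domain by default
    p_sub_domain: float = 0.1
    p_sub_flank: float = 0.3
    omega_domain: float = 0.1
    omega_flank: float = 0.7
    n_variants_per_source: dict[str, int] = field(
        default_factory=lambda: {s: 20 for s in SOURCES}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.protein_length < MIN_PROTEIN_LENGTH:
            raise ValueError(
                f"protein_length {self.protein_length} < {MIN_PROTEIN_LENGTH}: "
                "the 21-codon window is undefined"
            )
        if not 1 <= self.domain_start <= self.domain_end <= self.protein_length:
            raise ValueError("require 1 <= domain_start <= domain_end <= protein_length")
        for name in ("p_sub_domain", "p_sub_flank", "omega_domain", "omega_flank"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name}={val} outside [0, 1]")
        if self.n_genes < 1 or self.species_per_gene < 1:
            raise ValueError("need at least one gene and one species")
        unknown = set(self.n_variants_per_source) - set(SOURCES)
        if unknown:
            raise ValueError(f"unknown variant sources: {sorted(unknown)}")

    def gene_names(self) -> list[str]:
        return [f"GENE{i + 1}" for i in range(self.n_genes)]

    def region(self, codon_index: int) -> str:
        return (
            "domain"
            if self.domain_start <= codon_index <= self.domain_end
            else "flank"
        )

    def annotation(self, gene: str) -> DomainAnnotation:
        return DomainAnnotation(
            gene=gene,
            domain="core",
            start=self.domain_start,
            end=self.domain_end,
            protein_length=self.protein_length,
        )


@dataclass
class PlantedVariant:
    gene: str
    protein_pos: int
    ref_aa: str
    alt_aa: str
    sources: tuple[str, ...]
    attributes: dict = field(default_factory=dict)


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside the simulated family."""

    config: FamilySimConfig
    region: dict[str, list[str]] = field(default_factory=dict)  # gene -> per-codon label
    s_counts: dict[str, np.ndarray] = field(default_factory=dict)
    n_counts: dict[str, np.ndarray] = field(default_factory=dict)
    #: (gene, species, codon_index) attempts where no neighbor of the
    #: required class existed and the codon was left unchanged
    skipped: list[tuple[str, str, int]] = field(default_factory=list)
    variants: list[PlantedVariant] = field(default_factory=list)


def simulate_orthologs(
    config: FamilySimConfig,
) -> tuple[dict[str, CodonAlignment], SyntheticTruth]:
    """Simulate one codon alignment per gene plus exact substitution truth."""
    rng = np.random.default_rng(config.seed)
    truth = SyntheticTruth(config=config)
    alignments: dict[str, CodonAlignment] = {}
    for gene in config.gene_names():
        ref_codons = [
            SENSE_CODONS[i]
            for i in rng.integers(0, len(SENSE_CODONS), size=config.protein_length)
        ]
        sequences = {"human": "".join(ref_codons)}
        s_counts = np.zeros(config.protein_length, dtype=int)
        n_counts = np.zeros(config.protein_length, dtype=int)
        for k in range(config.species_per_gene - 1):
            species = f"species{k + 1}"
            codons = list(ref_codons)
            for idx in range(config.protein_length):
                region = config.region(idx + 1)
                p_sub = config.p_sub_domain if region == "domain" else config.p_sub_flank
                omega = config.omega_domain if region == "domain" else config.omega_flank
                if rng.random() >= p_sub:
                    continue
                syn, nonsyn = neighbor_classes(ref_codons[idx])
                pool = nonsyn if rng.random() < omega else syn
                if not pool:
                    truth.skipped.append((gene, species, idx + 1))
                    continue
                new = pool[rng.integers(0, len(pool))]
                codons[idx] = new
                if translate_codon(new) == translate_codon(ref_codons[idx]):
                    s_counts[idx] += 1
                else:
                    n_counts[idx] += 1
            sequences[species] = "".join(codons)
        alignments[gene] = CodonAlignment(
            gene=gene, reference_id="human", sequences=sequences
        )
        truth.region[gene] = [
            config.region(i + 1) for i in range(config.protein_length)
        ]
        truth.s_counts[gene] = s_counts
        truth.n_counts[gene] = n_counts
    return alignments, truth


def _membership(rng: np.random.Generator, quotas: dict[str, int]) -> list[tuple[str, ...]]:
    """Assign source memberships to a pool of sites meeting per-source quotas."""
    active = [s for s, n in quotas.items() if n > 0]
    remaining = dict(quotas)
    memberships: list[tuple[str, ...]] = []
    while any(remaining[s] > 0 for s in active):
        open_sources = [s for s in active if remaining[s] > 0]
        # each new site joins every still-open source independently
        chosen = [s for s in open_sources if rng.random() < 0.5]
        if not chosen:
            chosen = [open_sources[rng.integers(0, len(open_sources))]]
        for s in chosen:
            remaining[s] -= 1
        memberships.append(tuple(sorted(chosen)))
    return memberships


def simulate_variant_tables(
    config: FamilySimConfig,
    truth: SyntheticTruth,
    alignments: dict[str, CodonAlignment],
) -> dict[str, list[VariantRecord]]:
    """Plant variants at sampled residues and emit per-source record lists.

    Source memberships are drawn per site so that database overlaps occur;
    every planted row is recorded in ``truth.variants``.
    """
    rng = np.random.default_rng(config.seed + 1)
    quotas = {s: config.n_variants_per_source.get(s, 0) for s in SOURCES}
    capacity = config.n_genes * config.protein_length
    if sum(quotas.values()) > capacity:
        raise ValueError(
            f"requested {sum(quotas.values())} variant rows but the family has "
            f"only {capacity} residues; variants are planted at distinct sites"
        )
    tables: dict[str, list[VariantRecord]] = {s: [] for s in SOURCES}
    genes = config.gene_names()
    used_sites: set[tuple[str, int]] = set()
    for sources in _membership(rng, quotas):
        while True:
            gene = genes[rng.integers(0, len(genes))]
            pos = int(rng.integers(1, config.protein_length + 1))
            if (gene, pos) not in used_sites:
                used_sites.add((gene, pos))
                break
        ref_aa = translate_codon(alignments[gene].reference_codon(pos))
        alts = [a for a in AMINO_ACIDS if a != ref_aa]
        alt_aa = alts[rng.integers(0, len(alts))]
        attributes = {
            "allele_count": int(rng.geometric(0.1)),
            "cadd": round(float(rng.uniform(5.0, 40.0)), 1),
            "hpo_profile_count": int(rng.geometric(0.4)),
            "significance": SIGNIFICANCES[rng.integers(0, len(SIGNIFICANCES))],
            "tissue": TISSUES[rng.integers(0, len(TISSUES))],
            "histology": HISTOLOGIES[rng.integers(0, len(HISTOLOGIES))],
        }
        planted = PlantedVariant(
            gene=gene,
            protein_pos=pos,
            ref_aa=ref_aa,
            alt_aa=alt_aa,
            sources=sources,
            attributes=attributes,
        )
        truth.variants.append(planted)
        for rec in records_for_planted(planted):
            tables[rec.source].append(rec)
    return tables


def records_for_planted(planted: PlantedVariant) -> list[VariantRecord]:
    """Expand one planted variant into its per-source records."""
    base = dict(
        gene=planted.gene,
        protein_pos=planted.protein_pos,
        ref_aa=planted.ref_aa,
        alt_aa=planted.alt_aa,
    )
    attrs = planted.attributes
    out = []
    for source in planted.sources:
        if source == "gnomad":
            out.append(
                VariantRecord(source="gnomad", allele_count=attrs["allele_count"], **base)
            )
        elif source == "geno2mp":
            out.append(
                VariantRecord(
                    source="geno2mp",
                    cadd=attrs["cadd"],
                    hpo_profile_count=attrs["hpo_profile_count"],
                    **base,
                )
            )
        elif source in ("clinvar", "literature"):
            out.append(
                VariantRecord(source=source, significance=attrs["significance"], **base)
            )
        elif source == "cosmic":
            out.append(
                VariantRecord(
                    source="cosmic",
                    tissue=attrs["tissue"],
                    histology=attrs["histology"],
                    **base,
                )
            )
    return out


def write_fasta(alignment: CodonAlignment, path) -> None:
    with open(path, "w") as fh:
        ref = alignment.reference_id
        order = [ref] + sorted(k for k in alignment.sequences if k != ref)
        for seq_id in order:
            fh.write(f">{seq_id}\n{alignment.sequences[seq_id]}\n")


def write_config(config: FamilySimConfig, path) -> None:
    with open(path, "w") as fh:
        for f in dataclasses.fields(config):
            val = getattr(config, f.name)
            if isinstance(val, dict):
                val = ",".join(f"{k}:{v}" for k, v in sorted(val.items()))
            fh.write(f"{f.name}\t{val}\n")


def write_fixtures(config: FamilySimConfig, outdir) -> dict[str, Path]:
    """Emit a complete synthetic bundle plus the packaged reference tables.

    Writes per-gene aligned FASTA, the four variant TSVs, a domain
    annotation TSV, the generator config, and copies of the packaged
    table fixtures. Returns a name -> path manifest.
    """
    from .fixtures import FIXTURE_NAMES, fixture_path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Path] = {}

    alignments, truth = simulate_orthologs(config)
    tables = simulate_variant_tables(config, truth, alignments)

    for gene, aln in alignments.items():
        path = outdir / f"{gene}.fasta"
        write_fasta(aln, path)
        manifest[f"alignment:{gene}"] = path

    ann_path = outdir / "annotations.tsv"
    with open(ann_path, "w") as fh:
        fh.write("gene\tdomain\tstart\tend\tprotein_length\n")
        for gene in config.gene_names():
            fh.write(
                f"{gene}\tcore\t{config.domain_start}\t{config.domain_end}\t"
                f"{config.protein_length}\n"
            )
    manifest["annotations"] = ann_path

    for source, records in tables.items():
        path = outdir / f"variants_{source}.tsv"
        write_variants_tsv(records, path, source)
        manifest[f"variants:{source}"] = path

    cfg_path = outdir / "config.tsv"
    write_config(config, cfg_path)
    manifest["config"] = cfg_path

    for name in FIXTURE_NAMES:
        src = fixture_path(name)
        dst = outdir / src.name
        dst.write_text(src.read_text())
        manifest[f"fixture:{name}"] = dst
    return manifest
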