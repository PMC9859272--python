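"""End-to-end pipeline: filter -> conserve -> map -> integrate -> prioritize -> enrich."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import conservation, coords, prioritize, variants
from .conservation import ConservationProfile, build_profile, filter_sequences, read_codon_fasta
from .coords import DomainAnnotation, build_paralog_table, read_annotations_tsv
from .prioritize import (
    clinical_position_evidence,
    cosmic_highrisk_summary,
    cross_paralog_clinvar_positions,
    filter_geno2mp_hmg,
    prioritize_outside_domain,
)
from .variants import annotate_sites, hmg_enrichment, overlap_categories, read_variants_tsv

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    alignments_dir: str
    annotations: str
    variant_tables: dict[str, str]  # source -> TSV path
    outdir: str
    reference_id: str = "human"
    cadd_min: float = 20.0
    score_min: float = 1.0
    window_min: float = 10.0
    flank_up: int = 10
    flank_down: int = 25
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        unknown = set(self.variant_tables) - set(variants.SOURCES)
        if unknown:
            raise ValueError(f"unknown variant sources: {sorted(unknown)}")
        if not (self.cadd_min >= 0 and self.score_min >= 0 and self.window_min >= 0):
            raise ValueError("thresholds must be non-negative")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def validate_paths(self) -> None:
        missing = [
            p
            for p in [self.alignments_dir, self.annotations, *self.variant_tables.values()]
            if not Path(p).exists()
        ]
        if missing:
            raise FileNotFoundError(f"missing inputs: {missing}")


def load_alignments(
    alignments_dir, reference_id: str = "human"
) -> tuple[dict[str, conservation.CodonAlignment], dict[str, list[tuple[str, str]]]]:
    """Read every ``*.fasta`` in a directory (gene = file stem) and filter."""
    alignments: dict[str, conservation.CodonAlignment] = {}
    rejections: dict[str, list[tuple[str, str]]] = {}
    paths = sorted(Path(alignments_dir).glob("*.fasta"))
    if not paths:
        raise FileNotFoundError(f"no *.fasta files under {alignments_dir}")
    for path in paths:
        gene = path.stem
        aln = read_codon_fasta(path, gene=gene, reference_id=reference_id)
        kept, rejected = filter_sequences(aln.sequences, reference_id)
        rejections[gene] = rejected
        alignments[gene] = conservation.CodonAlignment(
            gene=gene, reference_id=reference_id, sequences=kept
        )
        log.info("%s: kept %d sequences, removed %d", gene, len(kept), len(rejected))
    return alignments, rejections


def build_profiles(
    alignments: dict[str, conservation.CodonAlignment]
) -> dict[str, ConservationProfile]:
    return {gene: build_profile(aln) for gene, aln in sorted(alignments.items())}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and write the report bundle; returns the summary dict."""
    config.validate_paths()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    alignments, rejections = load_alignments(config.alignments_dir, config.reference_id)
    profiles = build_profiles(alignments)
    annotations = read_annotations_tsv(config.annotations)

    for gene, profile in profiles.items():
        path = outdir / f"profile_{gene}.tsv"
        profile.write_tsv(path)
        manifest[f"profile:{gene}"] = path.name

    proteins = {g: aln.reference_protein() for g, aln in alignments.items()}
    table = build_paralog_table(
        proteins,
        profiles,
        annotations,
        flank_up=config.flank_up,
        flank_down=config.flank_down,
    )
    table.write_tsv(outdir / "paralog_table.tsv")
    manifest["paralog_table"] = "paralog_table.tsv"

    records: list[variants.VariantRecord] = []
    for source, path in sorted(config.variant_tables.items()):
        records.extend(read_variants_tsv(path, source))
    summaries = annotate_sites(records, annotations, profiles)
    variants.summaries_to_dataframe(summaries).to_csv(
        outdir / "site_summaries.tsv", sep="\t", index=False
    )
    manifest["site_summaries"] = "site_summaries.tsv"

    categories = overlap_categories(summaries)
    with open(outdir / "overlap_categories.tsv", "w") as fh:
        fh.write("sources\tn_sites\tn_in_domain\tratio\n")
        for key in sorted(categories):
            cat = categories[key]
            fh.write(
                f"{'+'.join(key)}\t{cat.n_sites}\t{cat.n_in_domain}\t{cat.ratio:.4f}\n"
            )
    manifest["overlap_categories"] = "overlap_categories.tsv"

    multi_paralog, multi_change = cross_paralog_clinvar_positions(summaries)
    clinical_positions = clinical_position_evidence(summaries)
    geno2mp_calls = filter_geno2mp_hmg(
        summaries,
        cadd_min=config.cadd_min,
        score_min=config.score_min,
        clinvar_by_position=clinical_positions,
    )
    outside_calls = prioritize_outside_domain(
        summaries, score_min=config.score_min, window_min=config.window_min
    )
    cosmic_groups = cosmic_highrisk_summary(summaries, set(clinical_positions))

    all_calls = geno2mp_calls + outside_calls
    prioritize.calls_to_dataframe(all_calls).to_csv(
        outdir / "priority_calls.tsv", sep="\t", index=False
    )
    manifest["priority_calls"] = "priority_calls.tsv"

    with open(outdir / "cosmic_highrisk.tsv", "w") as fh:
        fh.write("tissue\thistology\tcount\ttop_gene\ttop_gene_share\n")
        for grp in cosmic_groups:
            fh.write(
                f"{grp.tissue}\t{grp.histology}\t{grp.count}\t{grp.top_gene}\t"
                f"{grp.top_gene_share:.4f}\n"
            )
    manifest["cosmic_highrisk"] = "cosmic_highrisk.tsv"

    with open(outdir / "enrichment.tsv", "w") as fh:
        fh.write("gene\tsource\tenrichment\n")
        for gene in sorted(alignments):
            ann = annotations.get(gene)
            if ann is None:
                continue
            plen = ann.protein_length or len(proteins[gene])
            for source in sorted(config.variant_tables):
                val = hmg_enrichment(records, gene, source, ann, plen)
                if val is not None:
                    fh.write(f"{gene}\t{source}\t{val:.4f}\n")
    manifest["enrichment"] = "enrichment.tsv"

    summary = {
        "n_genes": len(alignments),
        "n_sequences_kept": {g: alignments[g].n_sequences for g in sorted(alignments)},
        "n_sequences_removed": {g: len(rejections[g]) for g in sorted(rejections)},
        "n_variant_records": len(records),
        "n_variant_sites": len(summaries),
        "multi_paralog_positions": len(multi_paralog),
        "multi_change_sites": len({pos for _, pos in multi_change}),
        "geno2mp_filtered": len(geno2mp_calls),
        "outside_domain_calls": len(outside_calls),
        "cosmic_highrisk_variants": sum(g.count for g in cosmic_groups),
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    manifest["summary"] = "summary.json"
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return summary


def config_to_yaml(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)
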