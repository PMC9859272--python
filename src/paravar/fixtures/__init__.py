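"""Packaged reference tables and loaders that lift them into typed objects.

Four reference tables are shipped as TSV:

* ``table1`` -- literature-curated clinical variants (gene, protein change,
  dual domain numbering, disease, source).
* ``table3`` -- clinical-database variants inside the shared domain, one row
  per gene-variant cell, with per-position amino-acid usage and conservation.
* ``table4`` -- phenotype-database (Geno2MP-style) in-domain candidate
  variants with CADD and conservation scores.
* ``table5`` -- outside-domain candidate variants with selection scores and
  21-codon window sums.

``table3_summaries`` / ``table4_summaries`` / ``table5_summaries`` convert
the rows into :class:`~paravar.variants.SiteSummary` objects so that the
prioritization rules can run on them directly.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from ..variants import SiteSummary

FIXTURE_NAMES = ("table1", "table3", "table4", "table5")

#: the tabulated domain spans positions 1..75 in its own numbering
DOMAIN_SPAN = (1, 75)


def fixture_path(name: str) -> Path:
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; known: {FIXTURE_NAMES}")
    return Path(str(resources.files(__package__) / f"{name}.tsv"))


def load_fixture(name: str) -> pd.DataFrame:
    """Load one packaged table as a DataFrame (empty cells become '')."""
    df = pd.read_csv(fixture_path(name), sep="\t", dtype=str, keep_default_na=False)
    if df.empty:
        raise ValueError(f"fixture {name!r} parsed empty")
    return df


def split_variant_cell(cell: str) -> tuple[str, int, list[str]]:
    """Parse 'M113V/I' into ('M', 113, ['V', 'I'])."""
    ref = cell[0]
    i = 1
    while i < len(cell) and cell[i].isdigit():
        i += 1
    pos = int(cell[1:i])
    alts = [a for a in cell[i:].split("/") if a]
    return ref, pos, alts


def table3_summaries() -> list[SiteSummary]:
    """Clinical in-domain variant sites keyed to the shared domain frame."""
    df = load_fixture("table3")
    out = []
    for row in df.itertuples(index=False):
        ref, pos, alts = split_variant_cell(row.variant)
        dpos = int(row.uniprot_pos)
        out.append(
            SiteSummary(
                gene=row.gene,
                protein_pos=pos,
                ref_aa=ref,
                sources={"clinvar"},
                in_domain=DOMAIN_SPAN[0] <= dpos <= DOMAIN_SPAN[1],
                domain_pos=dpos,
                score=float(row.conservation_score),
                alt_alleles={"clinvar": set(alts)},
            )
        )
    return out


def table4_summaries() -> list[SiteSummary]:
    """Phenotype-database in-domain candidate sites."""
    df = load_fixture("table4")
    out = []
    for row in df.itertuples(index=False):
        ref, pos, alts = split_variant_cell(row.variant)
        out.append(
            SiteSummary(
                gene=row.gene,
                protein_pos=pos,
                ref_aa=ref,
                sources={"geno2mp"},
                in_domain=True,
                domain_pos=int(row.hmg_pos),
                score=float(row.conservation_score),
                max_cadd=float(row.cadd),
                hpo_profiles=int(row.hpo_profiles),
                allele_count=int(row.gnomad_count),
                alt_alleles={"geno2mp": set(alts)},
            )
        )
    return out


def table5_summaries() -> list[SiteSummary]:
    """Outside-domain candidate sites with window context.

    Source membership is derived from the printed evidence columns: every
    row carries a clinical condition string (ClinVar), a gnomAD allele count
    when present, and a phenotype-database variant when present.
    """
    df = load_fixture("table5")
    out = []
    for row in df.itertuples(index=False):
        ref, pos, alts = split_variant_cell(row.variant)
        sources = {"clinvar"}
        alt_alleles = {"clinvar": set(alts)}
        allele_count = 0
        max_cadd = None
        hpo = 0
        if row.gnomad_count:
            sources.add("gnomad")
            allele_count = int(row.gnomad_count)
        if row.geno2mp_var:
            sources.add("geno2mp")
            g_ref, g_pos, g_alts = split_variant_cell(row.geno2mp_var)
            alt_alleles["geno2mp"] = set(g_alts)
            max_cadd = float(row.cadd) if row.cadd else None
            hpo = int(row.hpo_profiles) if row.hpo_profiles else 0
        out.append(
            SiteSummary(
                gene=row.gene,
                # codon index in the analysis frame, not the printed
                # alternate-isoform residue number
                protein_pos=int(row.codon),
                ref_aa=ref,
                sources=sources,
                in_domain=False,
                score=float(row.selection_score),
                window_sum=float(row.window_sum),
                max_cadd=max_cadd,
                hpo_profiles=hpo,
                allele_count=allele_count,
                alt_alleles=alt_alleles,
            )
        )
    return out
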