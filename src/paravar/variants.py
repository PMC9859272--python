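"""Readers for the four variant-table schemas and per-residue aggregation.

A variant "site" is a residue, i.e. a (gene, protein_pos) pair; distinct
alternate alleles at one residue belong to the same site but are retained as
attributes. Sites are annotated with domain membership, the shared domain
position and the gene's conservation score, then partitioned by the exact
combination of source databases in which they appear.
"""

from __future__ import annotations

import logging
import re
from collections import defaultdict
from dataclasses import dataclass, field

import pandas as pd

from .coords import DomainAnnotation, to_domain_position

log = logging.getLogger(__name__)

SOURCES = ("gnomad", "clinvar", "geno2mp", "cosmic", "literature")

#: mandatory columns beyond gene + variant identity, per source
SCHEMA_COLUMNS: dict[str, tuple[str, ...]] = {
    "gnomad": ("allele_count",),
    "clinvar": ("significance",),
    "geno2mp": ("cadd", "hpo_profile_count"),
    "cosmic": ("tissue", "histology"),
    "literature": ("significance",),
}

OPTIONAL_COLUMNS: dict[str, tuple[str, ...]] = {
    "gnomad": ("allele_frequency", "rsid"),
    "clinvar": ("condition", "rsid"),
    "geno2mp": ("rsid",),
    "cosmic": ("rsid",),
    "literature": ("condition", "reference"),
}

_PROTEIN_CHANGE = re.compile(r"^(?:p\.)?([A-Z\*])(\d+)([A-Z\*])$")


@dataclass(frozen=True)
class VariantRecord:
    """One missense variant from one source database."""

    gene: str
    protein_pos: int
    ref_aa: str
    alt_aa: str
    source: str
    allele_count: int | None = None
    allele_frequency: float | None = None
    significance: str | None = None
    condition: str | None = None
    cadd: float | None = None
    hpo_profile_count: int | None = None
    tissue: str | None = None
    histology: str | None = None
    rsid: str | None = None

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")
        if self.ref_aa == self.alt_aa:
            raise ValueError("ref_aa equals alt_aa")
        if self.protein_pos < 1:
            raise ValueError("protein_pos must be >= 1")


def parse_protein_change(text: str) -> tuple[str, int, str]:
    """Parse 'E137K' / 'p.E137K' into (ref_aa, protein_pos, alt_aa)."""
    m = _PROTEIN_CHANGE.match(text.strip())
    if not m:
        raise ValueError(f"cannot parse protein change {text!r}")
    return m.group(1), int(m.group(2)), m.group(3)


def read_variants_tsv(path, source: str) -> list[VariantRecord]:
    """Read one source's TSV; malformed rows are logged and skipped.

    Variant identity comes either from ref_aa/protein_pos/alt_aa columns or
    a single ``variant`` column in E137K notation.
    """
    if source not in SOURCES:
        raise ValueError(f"unknown source {source!r}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "gene" not in df.columns:
        raise ValueError(f"{path}: missing mandatory column 'gene'")
    has_triplet = {"protein_pos", "ref_aa", "alt_aa"} <= set(df.columns)
    if not has_triplet and "variant" not in df.columns:
        raise ValueError(f"{path}: need ref_aa/protein_pos/alt_aa or 'variant'")
    missing = [c for c in SCHEMA_COLUMNS[source] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing {source} columns {missing}")

    records: list[VariantRecord] = []
    for lineno, row in enumerate(df.to_dict("records"), start=2):
        try:
            if has_triplet and row.get("ref_aa"):
                ref, pos, alt = row["ref_aa"], int(row["protein_pos"]), row["alt_aa"]
            else:
                ref, pos, alt = parse_protein_change(row["variant"])
            extras = {}
            for col in SCHEMA_COLUMNS[source] + OPTIONAL_COLUMNS[source]:
                val = row.get(col, "")
                if val == "":
                    continue
                if col in ("allele_count", "hpo_profile_count"):
                    extras[col] = int(val)
                elif col in ("allele_frequency", "cadd"):
                    extras[col] = float(val)
                else:
                    extras[col] = val
            records.append(
                VariantRecord(
                    gene=row["gene"],
                    protein_pos=pos,
                    ref_aa=ref,
                    alt_aa=alt,
                    source=source,
                    **extras,
                )
            )
        except (ValueError, KeyError) as exc:
            log.warning("%s line %d rejected: %s", path, lineno, exc)
    return records


def write_variants_tsv(records: list[VariantRecord], path, source: str) -> None:
    """Write one source's records back to its TSV schema."""
    cols = ["gene", "protein_pos", "ref_aa", "alt_aa"]
    cols += list(SCHEMA_COLUMNS[source]) + list(OPTIONAL_COLUMNS[source])
    rows = []
    for rec in records:
        if rec.source != source:
            raise ValueError(f"record source {rec.source!r} != table {source!r}")
        rows.append({c: getattr(rec, c, None) for c in cols})
    df = pd.DataFrame(rows, columns=cols)
    df.to_csv(path, sep="\t", index=False)


@dataclass
class SiteSummary:
    """Per-residue aggregation of variant evidence across sources."""

    gene: str
    protein_pos: int
    ref_aa: str
    sources: set[str] = field(default_factory=set)
    in_domain: bool = False
    domain_pos: int | None = None
    score: float | None = None
    window_sum: float | None = None
    max_cadd: float | None = None
    allele_count: int = 0
    hpo_profiles: int = 0
    max_hpo_profiles: int = 0
    alt_alleles: dict[str, set[str]] = field(default_factory=dict)  # source -> alts
    significances: set[str] = field(default_factory=set)
    cosmic_entries: list[tuple[str, str]] = field(default_factory=list)

    @property
    def site(self) -> tuple[str, int]:
        return (self.gene, self.protein_pos)

    def n_alt(self, source: str) -> int:
        return len(self.alt_alleles.get(source, ()))

    def distinct_alts(self, sources) -> set[str]:
        out: set[str] = set()
        for src in sources:
            out |= self.alt_alleles.get(src, set())
        return out


def annotate_sites(
    records: list[VariantRecord],
    annotations: dict[str, DomainAnnotation] | None = None,
    profiles: dict[str, "object"] | None = None,
) -> list[SiteSummary]:
    """Group records by residue and join domain and conservation context."""
    annotations = annotations or {}
    profiles = profiles or {}
    by_site: dict[tuple[str, int], SiteSummary] = {}
    for rec in records:
        summ = by_site.get((rec.gene, rec.protein_pos))
        if summ is None:
            summ = SiteSummary(
                gene=rec.gene, protein_pos=rec.protein_pos, ref_aa=rec.ref_aa
            )
            by_site[(rec.gene, rec.protein_pos)] = summ
        elif summ.ref_aa != rec.ref_aa:
            log.warning(
                "%s %d: conflicting reference residues %s/%s",
                rec.gene,
                rec.protein_pos,
                summ.ref_aa,
                rec.ref_aa,
            )
        summ.sources.add(rec.source)
        summ.alt_alleles.setdefault(rec.source, set()).add(rec.alt_aa)
        if rec.allele_count is not None:
            summ.allele_count += rec.allele_count
        if rec.cadd is not None:
            summ.max_cadd = max(summ.max_cadd or 0.0, rec.cadd)
        if rec.hpo_profile_count is not None:
            summ.hpo_profiles += rec.hpo_profile_count
            summ.max_hpo_profiles = max(summ.max_hpo_profiles, rec.hpo_profile_count)
        if rec.significance:
            summ.significances.add(rec.significance)
        if rec.tissue or rec.histology:
            summ.cosmic_entries.append((rec.tissue or "", rec.histology or ""))

    for summ in by_site.values():
        ann = annotations.get(summ.gene)
        if ann is not None:
            summ.in_domain = ann.contains(summ.protein_pos)
            summ.domain_pos = to_domain_position(summ.protein_pos, ann)
        profile = profiles.get(summ.gene)
        if profile is not None:
            summ.score = profile.score_at(summ.protein_pos)
            summ.window_sum = profile.window_at(summ.protein_pos)
        elif profiles:
            log.warning("%s: no conservation profile; score left null", summ.gene)
    return sorted(by_site.values(), key=lambda s: s.site)


@dataclass(frozen=True)
class CategoryCount:
    sources: tuple[str, ...]
    n_sites: int
    n_in_domain: int

    @property
    def ratio(self) -> float:
        return self.n_in_domain / self.n_sites


def overlap_categories(summaries: list[SiteSummary]) -> dict[tuple[str, ...], CategoryCount]:
    """Partition sites by their exact source combination."""
    sites: dict[tuple[str, ...], list[SiteSummary]] = defaultdict(list)
    for summ in summaries:
        sites[tuple(sorted(summ.sources))].append(summ)
    return {
        key: CategoryCount(
            sources=key,
            n_sites=len(group),
            n_in_domain=sum(1 for s in group if s.in_domain),
        )
        for key, group in sites.items()
    }


def hmg_enrichment(
    records: list[VariantRecord],
    gene: str,
    source: str,
    annotation: DomainAnnotation,
    protein_length: int,
) -> float | None:
    """Domain enrichment: in-domain variant fraction over domain length fraction.

    Returns None (not 0) when the gene/source combination has no variants.
    """
    hits = [r for r in records if r.gene == gene and r.source == source]
    if not hits:
        return None
    n_in = sum(1 for r in hits if annotation.contains(r.protein_pos))
    baseline = annotation.length / protein_length
    return (n_in / len(hits)) / baseline


def summaries_to_dataframe(summaries: list[SiteSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        rows.append(
            {
                "gene": s.gene,
                "protein_pos": s.protein_pos,
                "ref_aa": s.ref_aa,
                "sources": ",".join(sorted(s.sources)),
                "in_domain": s.in_domain,
                "domain_pos": s.domain_pos,
                "score": s.score,
                "window_sum": s.window_sum,
                "max_cadd": s.max_cadd,
                "allele_count": s.allele_count,
                "hpo_profiles": s.hpo_profiles,
                **{f"n_alt_{src}": s.n_alt(src) for src in SOURCES},
            }
        )
    return pd.DataFrame(rows)
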