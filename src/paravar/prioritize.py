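"""Variant-prioritization rules built on cross-paralog clinical evidence.

Clinical evidence means ClinVar plus literature-curated variants; the two
are merged into one channel for cross-paralog position counting. Rules:

* ``cross_paralog_clinvar``: a domain position at which two or more paralogs
  carry clinical variants.
* ``multi_change_single_gene``: a (gene, domain position) with two or more
  distinct alternate alleles in the clinical channel.
* ``geno2mp_hmg_filter``: in-domain Geno2MP sites with CADD strictly above
  the threshold and conservation score at or above the threshold.
* ``outside_domain_conserved``: sites outside the domain at a conserved
  residue within a conserved 21-codon context, seen in ClinVar, Geno2MP or
  gnomAD.
* ``cosmic_at_clinical_site``: COSMIC variants at domain positions that
  carry clinical evidence in any paralog.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import pandas as pd

from .variants import SiteSummary

CLINICAL_SOURCES = frozenset({"clinvar", "literature"})
PRIORITY_SOURCES = frozenset({"clinvar", "geno2mp", "gnomad"})

RULES = (
    "cross_paralog_clinvar",
    "multi_change_single_gene",
    "geno2mp_hmg_filter",
    "outside_domain_conserved",
    "cosmic_at_clinical_site",
)

DEFAULT_CADD_MIN = 20.0
DEFAULT_SCORE_MIN = 1.0
DEFAULT_WINDOW_MIN = 10.0


@dataclass(frozen=True)
class PriorityCall:
    gene: str
    protein_pos: int
    rule: str
    evidence: dict = field(compare=False)

    def __post_init__(self) -> None:
        if self.rule not in RULES:
            raise ValueError(f"unknown rule {self.rule!r}")
        if not self.evidence:
            raise ValueError("evidence must be non-empty")


def _clinical_summaries(summaries: list[SiteSummary]) -> list[SiteSummary]:
    return [
        s
        for s in summaries
        if s.sources & CLINICAL_SOURCES and s.in_domain and s.domain_pos is not None
    ]


def cross_paralog_clinvar_positions(
    summaries: list[SiteSummary],
) -> tuple[dict[int, set[str]], list[tuple[str, int]]]:
    """Cross-paralog clinical positions and multi-change single-gene sites.

    Returns (positions with >= 2 distinct paralogs carrying clinical
    variants, mapped to those paralogs; (gene, domain position) pairs where
    a single gene has >= 2 distinct alternate alleles at the site).
    """
    by_pos: dict[int, set[str]] = defaultdict(set)
    multi_change: list[tuple[str, int]] = []
    for summ in _clinical_summaries(summaries):
        by_pos[summ.domain_pos].add(summ.gene)
        if len(summ.distinct_alts(CLINICAL_SOURCES)) >= 2:
            multi_change.append((summ.gene, summ.domain_pos))
    multi_paralog = {pos: genes for pos, genes in by_pos.items() if len(genes) >= 2}
    return multi_paralog, sorted(multi_change, key=lambda t: (t[1], t[0]))


def clinical_position_evidence(summaries: list[SiteSummary]) -> dict[int, set[str]]:
    """All domain positions with clinical evidence (any number of paralogs)."""
    by_pos: dict[int, set[str]] = defaultdict(set)
    for summ in _clinical_summaries(summaries):
        by_pos[summ.domain_pos].add(summ.gene)
    return dict(by_pos)


def filter_geno2mp_hmg(
    summaries: list[SiteSummary],
    cadd_min: float = DEFAULT_CADD_MIN,
    score_min: float = DEFAULT_SCORE_MIN,
    clinvar_by_position: dict[int, set[str]] | None = None,
) -> list[PriorityCall]:
    """In-domain Geno2MP sites with CADD > cadd_min and score >= score_min.

    The CADD cut is strict and the score cut inclusive. Each call records the
    paralogs with clinical evidence at its domain position (possibly none).
    """
    if clinvar_by_position is None:
        clinvar_by_position = clinical_position_evidence(summaries)
    calls = []
    for summ in summaries:
        if "geno2mp" not in summ.sources or not summ.in_domain:
            continue
        if summ.max_cadd is None or summ.score is None:
            continue
        if summ.max_cadd > cadd_min and summ.score >= score_min:
            calls.append(
                PriorityCall(
                    gene=summ.gene,
                    protein_pos=summ.protein_pos,
                    rule="geno2mp_hmg_filter",
                    evidence={
                        "domain_pos": summ.domain_pos,
                        "cadd": summ.max_cadd,
                        "score": summ.score,
                        "clinvar_paralogs": sorted(
                            clinvar_by_position.get(summ.domain_pos, set()) - {summ.gene}
                        ),
                    },
                )
            )
    return calls


def prioritize_outside_domain(
    summaries: list[SiteSummary],
    score_min: float = DEFAULT_SCORE_MIN,
    window_min: float = DEFAULT_WINDOW_MIN,
) -> list[PriorityCall]:
    """Conserved sites in conserved context outside the domain.

    Keeps sites with in_domain False, conservation score >= score_min,
    21-codon window sum >= window_min, present in ClinVar, Geno2MP or gnomAD.
    """
    calls = []
    for summ in summaries:
        if summ.in_domain or not (summ.sources & PRIORITY_SOURCES):
            continue
        if summ.score is None or summ.window_sum is None:
            continue
        if summ.score >= score_min and summ.window_sum >= window_min:
            calls.append(
                PriorityCall(
                    gene=summ.gene,
                    protein_pos=summ.protein_pos,
                    rule="outside_domain_conserved",
                    evidence={
                        "score": summ.score,
                        "window_sum": summ.window_sum,
                        "sources": sorted(summ.sources & PRIORITY_SOURCES),
                    },
                )
            )
    return calls


@dataclass(frozen=True)
class TumorGroup:
    tissue: str
    histology: str
    count: int
    top_gene: str
    top_gene_share: float


def cosmic_highrisk_summary(
    summaries: list[SiteSummary],
    clinical_positions: set[int] | None = None,
) -> list[TumorGroup]:
    """COSMIC variants at clinically evidenced domain positions by tumor type.

    Restricts in-domain COSMIC entries to domain positions carrying clinical
    evidence in any paralog, groups them by (tissue, histology) and reports
    counts with the gene holding the largest share of each group, ranked by
    count (descending).
    """
    if clinical_positions is None:
        clinical_positions = set(clinical_position_evidence(summaries))
    by_group: dict[tuple[str, str], Counter] = defaultdict(Counter)
    for summ in summaries:
        if "cosmic" not in summ.sources or not summ.in_domain:
            continue
        if summ.domain_pos not in clinical_positions:
            continue
        for tissue, histology in summ.cosmic_entries:
            by_group[(tissue, histology)][summ.gene] += 1
    groups = []
    for (tissue, histology), gene_counts in by_group.items():
        total = sum(gene_counts.values())
        top_gene, top_n = gene_counts.most_common(1)[0]
        groups.append(
            TumorGroup(
                tissue=tissue,
                histology=histology,
                count=total,
                top_gene=top_gene,
                top_gene_share=top_n / total,
            )
        )
    return sorted(groups, key=lambda g: (-g.count, g.tissue, g.histology))


def calls_to_dataframe(calls: list[PriorityCall]) -> pd.DataFrame:
    rows = []
    for call in calls:
        row = {"gene": call.gene, "protein_pos": call.protein_pos, "rule": call.rule}
        for key, val in call.evidence.items():
            row[key] = ",".join(map(str, val)) if isinstance(val, (list, set)) else val
        rows.append(row)
    return pd.DataFrame(rows)
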