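"""Shared domain coordinate system and cross-paralog position statistics.

Positions inside the domain run 1..L (L = end - start + 1); there is no
position zero. The residue immediately upstream of the domain start is -1,
and positions continue past L downstream. An alternate numbering convention
offset by a fixed amount (+2 by default) is supported for tables that quote
both systems.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

DEFAULT_FLANK_UP = 10
DEFAULT_FLANK_DOWN = 25
ALT_OFFSET = 2


@dataclass(frozen=True)
class DomainAnnotation:
    """1-based inclusive protein coordinates of one gene's domain."""

    gene: str
    domain: str
    start: int
    end: int
    protein_length: int | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"{self.gene}: invalid domain bounds {self.start}..{self.end}")
        if self.protein_length is not None and self.end > self.protein_length:
            raise ValueError(f"{self.gene}: domain end beyond protein length")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, protein_pos: int) -> bool:
        return self.start <= protein_pos <= self.end


def to_domain_position(protein_pos: int, annotation: DomainAnnotation) -> int:
    """Map a protein position onto the no-zero domain coordinate."""
    if protein_pos < 1:
        raise ValueError("protein positions are 1-based")
    if protein_pos >= annotation.start:
        return protein_pos - annotation.start + 1
    return protein_pos - annotation.start  # already negative, zero skipped


def from_domain_position(domain_pos: int, annotation: DomainAnnotation) -> int:
    """Exact inverse of :func:`to_domain_position`."""
    if domain_pos == 0:
        raise ValueError("domain position 0 does not exist")
    if domain_pos > 0:
        return annotation.start + domain_pos - 1
    return annotation.start + domain_pos


def to_alternate_numbering(domain_pos: int, offset: int = ALT_OFFSET) -> int:
    """Shift a domain position by ``offset``, skipping the nonexistent zero."""
    if domain_pos == 0:
        raise ValueError("domain position 0 does not exist")
    if offset < 0:
        raise ValueError("only non-negative offsets are supported")
    out = domain_pos + offset
    if domain_pos < 0 <= out:
        out += 1  # crossing zero from below
        log.debug("alternate numbering crossed zero: %d -> %d", domain_pos, out)
    return out


def read_annotations_tsv(path) -> dict[str, DomainAnnotation]:
    """Read a gene/domain/start/end[/protein_length] TSV keyed by gene."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "domain", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation TSV missing columns: {sorted(missing)}")
    out: dict[str, DomainAnnotation] = {}
    for row in df.itertuples(index=False):
        length = int(row.protein_length) if "protein_length" in df.columns else None
        out[row.gene] = DomainAnnotation(
            gene=row.gene,
            domain=row.domain,
            start=int(row.start),
            end=int(row.end),
            protein_length=length,
        )
    return out


@dataclass
class PositionRow:
    """Cross-paralog statistics at one domain position."""

    domain_pos: int
    alt_pos: int
    residues: dict[str, str]  # gene -> residue
    scores: dict[str, float]  # gene -> conservation score at its own residue

    @property
    def aa_set(self) -> set[str]:
        return set(self.residues.values())

    @property
    def usage_count(self) -> int:
        return len(self.aa_set)

    @property
    def score_mean(self) -> float:
        vals = [v for v in self.scores.values() if not np.isnan(v)]
        return float(np.mean(vals)) if vals else float("nan")

    @property
    def score_sd(self) -> float:
        vals = [v for v in self.scores.values() if not np.isnan(v)]
        return float(np.std(vals)) if vals else float("nan")


@dataclass
class ParalogPositionTable:
    """Per-domain-position amino-acid usage and conservation across paralogs."""

    rows: dict[int, PositionRow]
    domain_length: int

    def positions(self) -> list[int]:
        return sorted(self.rows, key=lambda p: (p > 0, p) if p < 0 else (True, p))

    def to_dataframe(self) -> pd.DataFrame:
        recs = []
        for pos in sorted(self.rows, key=_position_sort_key):
            row = self.rows[pos]
            recs.append(
                {
                    "domain_pos": row.domain_pos,
                    "alt_pos": row.alt_pos,
                    "aa_set": "".join(sorted(row.aa_set)),
                    "aa_used": row.usage_count,
                    "cons_mean": row.score_mean,
                    "cons_sd": row.score_sd,
                }
            )
        return pd.DataFrame(recs)

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.4f")


def _position_sort_key(pos: int) -> int:
    # collapse the missing zero so -1 sorts just before 1
    return pos if pos > 0 else pos + 1


def build_paralog_table(
    proteins: dict[str, str],
    profiles: dict[str, "object"],
    annotations: dict[str, DomainAnnotation],
    *,
    flank_up: int = DEFAULT_FLANK_UP,
    flank_down: int = DEFAULT_FLANK_DOWN,
    alt_offset: int = ALT_OFFSET,
) -> ParalogPositionTable:
    """Align paralogs on the shared domain frame, gap-free inside the domain.

    ``proteins`` maps gene -> full protein sequence; ``profiles`` maps gene ->
    ConservationProfile (anything with ``score_at``). All annotated domains
    must have equal length. Positions covered run -flank_up .. L + flank_down
    (zero skipped); a gene contributes at a position only where its protein
    actually has a residue.
    """
    genes = sorted(set(proteins) & set(annotations))
    if not genes:
        raise ValueError("no gene has both a protein sequence and an annotation")
    lengths = {annotations[g].length for g in genes}
    if len(lengths) != 1:
        raise ValueError(f"domain lengths differ across paralogs: {sorted(lengths)}")
    (domain_len,) = lengths

    positions = [p for p in range(-flank_up, domain_len + flank_down + 1) if p != 0]
    rows: dict[int, PositionRow] = {}
    for pos in positions:
        residues: dict[str, str] = {}
        scores: dict[str, float] = {}
        for gene in genes:
            ann = annotations[gene]
            ppos = from_domain_position(pos, ann)
            seq = proteins[gene]
            if not 1 <= ppos <= len(seq):
                continue
            residues[gene] = seq[ppos - 1]
            profile = profiles.get(gene)
            sc = profile.score_at(ppos) if profile is not None else None
            scores[gene] = float("nan") if sc is None else sc
        if residues:
            rows[pos] = PositionRow(
                domain_pos=pos,
                alt_pos=to_alternate_numbering(pos, alt_offset),
                residues=residues,
                scores=scores,
            )
    return ParalogPositionTable(rows=rows, domain_length=domain_len)


@dataclass
class SegregationProfile:
    """Signed, conservation-weighted comparison of a focal paralog to siblings.

    At each frame position the sibling value is +score when the sibling
    residue equals the focal residue and -score when it differs; ``additive``
    sums the sibling values.
    """

    positions: list[int]
    per_sibling: dict[str, np.ndarray]
    additive: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        data = {"position": self.positions}
        data.update({g: v for g, v in self.per_sibling.items()})
        data["additive"] = self.additive
        return pd.DataFrame(data)


def segregation_profile(
    focal_residues: str,
    focal_scores,
    sibling_residues: dict[str, str],
    positions: list[int] | None = None,
) -> SegregationProfile:
    """Compare a focal sequence against siblings in a shared alignment frame.

    All residue strings must have equal length; ``focal_scores`` gives the
    focal gene's conservation score at each frame position.
    """
    n = len(focal_residues)
    scores = np.asarray(focal_scores, dtype=float)
    if len(scores) != n:
        raise ValueError("focal scores and residues differ in length")
    for name, seq in sibling_residues.items():
        if len(seq) != n:
            raise ValueError(f"sibling {name!r} not in the focal frame")
    if positions is None:
        positions = list(range(1, n + 1))
    per_sibling: dict[str, np.ndarray] = {}
    for name, seq in sibling_residues.items():
        sign = np.array(
            [1.0 if seq[i] == focal_residues[i] else -1.0 for i in range(n)]
        )
        per_sibling[name] = sign * scores
    additive = (
        np.sum(list(per_sibling.values()), axis=0)
        if per_sibling
        else np.zeros(n)
    )
    return SegregationProfile(
        positions=list(positions), per_sibling=per_sibling, additive=additive
    )
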