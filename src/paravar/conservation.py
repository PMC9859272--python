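"""Per-codon evolutionary statistics and the combined conservation score.

The unit of analysis is a reference-anchored codon alignment of one gene's
orthologs. For every reference codon we count synonymous (s) and
nonsynonymous (n) differences of each ortholog codon relative to the human
reference codon, derive a standardized selection signal (``dnds_z``), fold
both into a quantized 0-2 conservation score, and place the score on a
21-codon sliding window normalized per gene to a 0-1 profile.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

from ._codons import is_unambiguous, site_counts, translate_codon

log = logging.getLogger(__name__)

GAP = "-"
WINDOW_FLANK = 10  # codons on each side: 21-codon window
MIN_PROTEIN_LENGTH = 21

# conservation score rubric
AA_CONSERVED_MIN = 0.90
S_TIER_1 = 5
S_TIER_2 = 15
Z_TIER_1 = -1.0
Z_TIER_2 = -2.0
SCORE_STEP = 0.25
SCORE_MAX = 2.0


class ReferenceFilteredError(ValueError):
    """The designated reference sequence failed a sequence filter."""


@dataclass
class CodonAlignment:
    """Reference-anchored codon alignment of one gene's orthologs.

    ``sequences`` maps sequence id -> aligned nucleotide string (uppercase,
    gaps as '-'). All strings share one length divisible by 3; gaps occur in
    whole-codon triplets. Reference codon index k (1-based) is the k-th
    alignment triplet at which the reference is ungapped.
    """

    gene: str
    reference_id: str
    sequences: dict[str, str]
    _codon_columns: list[int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.reference_id not in self.sequences:
            raise ValueError(f"reference {self.reference_id!r} not in alignment")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise ValueError("aligned sequences differ in length")
        (length,) = lengths
        if length % 3 != 0:
            raise ValueError("alignment length not divisible by 3")
        self.sequences = {k: v.upper() for k, v in self.sequences.items()}
        ref = self.sequences[self.reference_id]
        self._codon_columns = [
            col for col in range(length // 3) if GAP not in ref[3 * col : 3 * col + 3]
        ]

    @property
    def n_codons(self) -> int:
        """Number of reference codons (gapped reference columns carry none)."""
        return len(self._codon_columns)

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    def codon(self, seq_id: str, codon_index: int) -> str:
        """Aligned codon of ``seq_id`` at reference codon ``codon_index`` (1-based)."""
        if not 1 <= codon_index <= self.n_codons:
            raise IndexError(f"codon_index {codon_index} out of range 1..{self.n_codons}")
        col = self._codon_columns[codon_index - 1]
        return self.sequences[seq_id][3 * col : 3 * col + 3]

    def reference_codon(self, codon_index: int) -> str:
        return self.codon(self.reference_id, codon_index)

    def reference_protein(self) -> str:
        return "".join(
            translate_codon(self.reference_codon(i)) for i in range(1, self.n_codons + 1)
        )


@dataclass(frozen=True)
class CodonColumnStats:
    """Substitution counts at one reference codon."""

    codon_index: int
    s: int
    n: int
    aa_match_fraction: float
    n_compared: int


@dataclass
class ConservationProfile:
    """Per-reference-codon conservation metrics for one gene."""

    gene: str
    ref_aa: str  # reference protein, one letter per codon index
    s: np.ndarray
    n: np.ndarray
    aa_match_fraction: np.ndarray
    dnds_z: np.ndarray  # NaN where undefined (n_compared < 3)
    n_compared: np.ndarray
    score: np.ndarray
    window_sum: np.ndarray
    normalized_window: np.ndarray

    @property
    def n_codons(self) -> int:
        return len(self.ref_aa)

    def score_at(self, protein_pos: int) -> float | None:
        if 1 <= protein_pos <= self.n_codons:
            return float(self.score[protein_pos - 1])
        return None

    def window_at(self, protein_pos: int) -> float | None:
        if 1 <= protein_pos <= self.n_codons:
            return float(self.window_sum[protein_pos - 1])
        return None

    def to_dataframe(self) -> pd.DataFrame:
        idx = np.arange(1, self.n_codons + 1)
        return pd.DataFrame(
            {
                "gene": self.gene,
                "codon_index": idx,
                "ref_aa": list(self.ref_aa),
                "s": self.s,
                "n": self.n,
                "aa_match_fraction": self.aa_match_fraction,
                "dnds_z": self.dnds_z,
                "score": self.score,
                "window_sum": self.window_sum,
                "normalized_window": self.normalized_window,
            }
        )

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def read_codon_fasta(path, gene: str, reference_id: str) -> CodonAlignment:
    """Read an aligned codon FASTA into a :class:`CodonAlignment`."""
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        raise ValueError(f"no sequences in {path}")
    return CodonAlignment(gene=gene, reference_id=reference_id, sequences=seqs)


def filter_sequences(
    sequences: dict[str, str],
    reference_id: str,
    *,
    occupancy_min: float = 0.90,
    max_missing: int = 9,
) -> tuple[dict[str, str], list[tuple[str, str]]]:
    """Apply the two sequence-quality rules, never dropping the reference.

    Rule 1: drop any sequence containing an ambiguity code (any character
    other than A/C/G/T or the gap symbol).
    Rule 2: drop any sequence missing more than ``max_missing`` nucleotides
    at alignment columns occupied (non-gap) by more than ``occupancy_min``
    of the input sequences.

    Returns (kept sequences, rejection log of (seq_id, reason)).
    """
    if reference_id not in sequences:
        raise ValueError(f"reference {reference_id!r} missing from input")
    sequences = {k: v.upper() for k, v in sequences.items()}
    n_seq = len(sequences)
    length = len(next(iter(sequences.values())))
    if any(len(s) != length for s in sequences.values()):
        raise ValueError("sequences differ in aligned length")

    arr = np.array([list(s) for s in sequences.values()])
    occupied = (arr != GAP).sum(axis=0) / n_seq
    dense_cols = occupied > occupancy_min

    kept: dict[str, str] = {}
    rejected: list[tuple[str, str]] = []
    for seq_id, seq in sequences.items():
        reason = None
        if any(c not in "ACGT-" for c in seq):
            reason = "ambiguity code present"
        else:
            missing = sum(
                1 for col in np.flatnonzero(dense_cols) if seq[col] == GAP
            )
            if missing > max_missing:
                reason = (
                    f"missing {missing} nt at columns occupied by "
                    f">{occupancy_min:.0%} of sequences"
                )
        if reason is None:
            kept[seq_id] = seq
        elif seq_id == reference_id:
            raise ReferenceFilteredError(
                f"reference {reference_id!r} fails filter: {reason}"
            )
        else:
            rejected.append((seq_id, reason))
            log.info("filtered %s: %s", seq_id, reason)
    if not kept:
        raise ValueError("no sequences left after filtering")
    return kept, rejected


def column_substitution_counts(
    alignment: CodonAlignment, codon_index: int
) -> CodonColumnStats:
    """Count synonymous/nonsynonymous differences to the reference codon.

    Only non-reference sequences with an ungapped, unambiguous codon at the
    column contribute; each contributes to s if its codon differs but
    encodes the reference amino acid, to n if it encodes another amino acid.
    """
    ref_codon = alignment.reference_codon(codon_index)
    if not is_unambiguous(ref_codon):
        raise ValueError(
            f"reference codon at index {codon_index} is gapped or ambiguous"
        )
    ref_aa = translate_codon(ref_codon)
    s = n = matches = n_compared = 0
    for seq_id in alignment.sequences:
        if seq_id == alignment.reference_id:
            continue
        codon = alignment.codon(seq_id, codon_index)
        if not is_unambiguous(codon):
            continue
        n_compared += 1
        aa = translate_codon(codon)
        if aa == ref_aa:
            matches += 1
            if codon != ref_codon:
                s += 1
        else:
            n += 1
    frac = matches / n_compared if n_compared else 0.0
    return CodonColumnStats(codon_index, s, n, frac, n_compared)


def gene_dnds_profile(
    alignment: CodonAlignment, stats: list[CodonColumnStats] | None = None
) -> np.ndarray:
    """Standardized per-codon dN-dS signal (z-scored within the gene).

    raw(i) = n/Nsites - s/Ssites with site counts from single-nucleotide
    neighbor enumeration of the reference codon (a term with zero sites
    contributes zero). Codons with fewer than 3 comparable sequences are
    returned as NaN and excluded from the standardization.
    """
    if stats is None:
        stats = [
            column_substitution_counts(alignment, i)
            for i in range(1, alignment.n_codons + 1)
        ]
    raw = np.full(len(stats), np.nan)
    for k, st in enumerate(stats):
        if st.n_compared < 3:
            log.warning(
                "%s codon %d: only %d comparable sequences; dnds_z undefined",
                alignment.gene,
                st.codon_index,
                st.n_compared,
            )
            continue
        ref_codon = alignment.reference_codon(st.codon_index)
        s_sites, n_sites = site_counts(ref_codon)
        val = 0.0
        if n_sites > 0:
            val += st.n / n_sites
        if s_sites > 0:
            val -= st.s / s_sites
        raw[k] = val
    defined = ~np.isnan(raw)
    if not defined.any():
        return raw
    mu = raw[defined].mean()
    sd = raw[defined].std()
    z = np.full_like(raw, np.nan)
    if sd == 0:
        log.warning("%s: zero variance in raw dN-dS; dnds_z set to 0", alignment.gene)
        z[defined] = 0.0
    else:
        z[defined] = (raw[defined] - mu) / sd
    return z


def conservation_score(stats: CodonColumnStats, dnds_z: float) -> float:
    """Quantized 0-2 score combining amino-acid conservation and selection.

    Base 1.0 when the amino acid matches the reference in >= 90% of compared
    sequences, plus 0.25 for each of: s >= 5, s >= 15, dnds_z <= -1,
    dnds_z <= -2; capped at 2.0. An undefined dnds_z (NaN) adds nothing.
    """
    score = 1.0 if stats.aa_match_fraction >= AA_CONSERVED_MIN else 0.0
    if stats.s >= S_TIER_1:
        score += SCORE_STEP
    if stats.s >= S_TIER_2:
        score += SCORE_STEP
    if not math.isnan(dnds_z):
        if dnds_z <= Z_TIER_1:
            score += SCORE_STEP
        if dnds_z <= Z_TIER_2:
            score += SCORE_STEP
    return min(score, SCORE_MAX)


def sliding_window(scores: np.ndarray, flank: int = WINDOW_FLANK) -> np.ndarray:
    """Sum of scores over codons [i-flank, i+flank], truncated at the termini."""
    scores = np.asarray(scores, dtype=float)
    out = np.empty_like(scores)
    n = len(scores)
    for i in range(n):
        out[i] = scores[max(0, i - flank) : min(n, i + flank + 1)].sum()
    return out


def normalize_profile(window_sums: np.ndarray) -> np.ndarray:
    """Divide by the gene maximum; an all-zero profile stays all-zero."""
    window_sums = np.asarray(window_sums, dtype=float)
    peak = window_sums.max(initial=0.0)
    if peak <= 0:
        log.warning("all-zero window profile; normalization skipped")
        return np.zeros_like(window_sums)
    return window_sums / peak


def build_profile(alignment: CodonAlignment) -> ConservationProfile:
    """Compute the full conservation profile for one gene."""
    if alignment.n_codons < MIN_PROTEIN_LENGTH:
        raise ValueError(
            f"{alignment.gene}: {alignment.n_codons} codons; the 21-codon "
            "window requires at least 21"
        )
    stats = [
        column_substitution_counts(alignment, i)
        for i in range(1, alignment.n_codons + 1)
    ]
    dnds_z = gene_dnds_profile(alignment, stats)
    scores = np.array(
        [conservation_score(st, float(z)) for st, z in zip(stats, dnds_z)]
    )
    window = sliding_window(scores)
    return ConservationProfile(
        gene=alignment.gene,
        ref_aa=alignment.reference_protein(),
        s=np.array([st.s for st in stats]),
        n=np.array([st.n for st in stats]),
        aa_match_fraction=np.array([st.aa_match_fraction for st in stats]),
        dnds_z=dnds_z,
        n_compared=np.array([st.n_compared for st in stats]),
        score=scores,
        window_sum=window,
        normalized_window=normalize_profile(window),
    )
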