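"""Codon-level helpers shared by the simulator and the conservation scorer."""

from __future__ import annotations

from functools import lru_cache

from Bio.Data.CodonTable import standard_dna_table

NUCLEOTIDES = "ACGT"

#: codon -> single-letter amino acid; stop codons map to "*"
CODON_TO_AA: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    CODON_TO_AA[_stop] = "*"

SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c, aa in CODON_TO_AA.items() if aa != "*")
)


def translate_codon(codon: str) -> str:
    """Translate one uppercase DNA codon; returns '*' for stops.

    Raises KeyError for codons containing gaps or ambiguity codes.
    """
    return CODON_TO_AA[codon]


def is_unambiguous(codon: str) -> bool:
    return len(codon) == 3 and all(b in NUCLEOTIDES for b in codon)


@lru_cache(maxsize=None)
def single_nt_neighbors(codon: str) -> tuple[str, ...]:
    """All 9 codons one nucleotide change away from `codon`."""
    out = []
    for i, ref_base in enumerate(codon):
        for b in NUCLEOTIDES:
            if b != ref_base:
                out.append(codon[:i] + b + codon[i + 1 :])
    return tuple(out)


@lru_cache(maxsize=None)
def neighbor_classes(codon: str) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Partition single-nucleotide neighbors into (synonymous, nonsynonymous).

    Stop-producing neighbors belong to neither class.
    """
    aa = translate_codon(codon)
    syn, nonsyn = [], []
    for nb in single_nt_neighbors(codon):
        nb_aa = translate_codon(nb)
        if nb_aa == "*":
            continue
        (syn if nb_aa == aa else nonsyn).append(nb)
    return tuple(syn), tuple(nonsyn)


@lru_cache(maxsize=None)
def site_counts(codon: str) -> tuple[float, float]:
    """(Ssites, Nsites) for a reference codon from neighbor enumeration.

    Each of the 9 single-nucleotide neighbors is classified; stop-producing
    neighbors are excluded from both classes. Ssites is the synonymous
    fraction in per-position units (synonymous neighbors / 3); Nsites is the
    remaining non-stop mutational opportunity (non-stop neighbors - Ssites).
    E.g. GCT (Ala, 4-fold third position): Ssites = 1, Nsites = 8.
    """
    syn, nonsyn = neighbor_classes(codon)
    s_sites = len(syn) / 3.0
    n_sites = (len(syn) + len(nonsyn)) - s_sites
    return s_sites, n_sites
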