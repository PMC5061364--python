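"""Codon-level utilities for protein-coding mtDNA.

Everything here works on the invertebrate mitochondrial genetic code
(NCBI translation table 5) by default, the code under which copepod mtCOI
is translated.  The codon table itself comes from Biopython; what this
module adds is the bookkeeping needed for the Nei–Gojobori (1986) method:
counting synonymous/nonsynonymous *sites* per codon and
synonymous/nonsynonymous *differences* per codon pair by averaging over
all mutational pathways.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import permutations

from Bio.Data import CodonTable

BASES = "ACGT"
INVERTEBRATE_MITO_ID = 5

_TABLES: dict[int, CodonTable.CodonTable] = {}


def get_code(code_id: int = INVERTEBRATE_MITO_ID) -> CodonTable.CodonTable:
    """Return the unambiguous-DNA codon table for an NCBI table id."""
    if code_id not in _TABLES:
        try:
            _TABLES[code_id] = CodonTable.unambiguous_dna_by_id[code_id]
        except KeyError as exc:
            raise ValueError(f"unknown genetic code id: {code_id}") from exc
    return _TABLES[code_id]


@lru_cache(maxsize=None)
def _amino(codon: str, code_id: int) -> str:
    """One-letter amino acid, with '*' for stop codons."""
    table = get_code(code_id)
    if codon in table.stop_codons:
        return "*"
    return table.forward_table[codon]


def translate(seq: str, code_id: int = INVERTEBRATE_MITO_ID) -> str:
    """Translate an in-frame ACGT string; stops appear as '*'."""
    if len(seq) % 3:
        raise ValueError("sequence length is not a multiple of 3")
    return "".join(_amino(seq[i : i + 3], code_id) for i in range(0, len(seq), 3))


def is_stop(codon: str, code_id: int = INVERTEBRATE_MITO_ID) -> bool:
    return codon in get_code(code_id).stop_codons


def sense_codons(code_id: int = INVERTEBRATE_MITO_ID) -> list[str]:
    """All codons that encode an amino acid (no stops), sorted."""
    return sorted(get_code(code_id).forward_table)


def is_synonymous(codon: str, pos: int, new_base: str,
                  code_id: int = INVERTEBRATE_MITO_ID) -> bool:
    """Does substituting ``new_base`` at codon position ``pos`` keep the amino acid?

    A change into or out of a stop codon counts as nonsynonymous.
    """
    mutant = codon[:pos] + new_base + codon[pos + 1 :]
    return _amino(codon, code_id) == _amino(mutant, code_id)


@lru_cache(maxsize=None)
def syn_sites(codon: str, code_id: int = INVERTEBRATE_MITO_ID) -> float:
    """Number of synonymous sites in a codon (Nei–Gojobori counting).

    Each of the three positions contributes the fraction of its three
    possible point changes that are synonymous; changes creating a stop
    codon count as nonsynonymous.  The nonsynonymous site count is
    ``3 - syn_sites(codon)``.
    """
    s = 0.0
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            if is_synonymous(codon, pos, b, code_id):
                s += 1.0 / 3.0
    return s


@lru_cache(maxsize=None)
def pathway_differences(c1: str, c2: str,
                        code_id: int = INVERTEBRATE_MITO_ID) -> tuple[float, float]:
    """Synonymous and nonsynonymous difference counts between two codons.

    Averages over all orderings of the differing positions (the Nei–Gojobori
    pathway method).  Pathways passing through a stop codon are excluded;
    if every pathway hits a stop, all pathways are used as a fallback so the
    counts stay defined.
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths: list[tuple[float, float]] = []
    fallback: list[tuple[float, float]] = []
    for order in permutations(diff_pos):
        cur = c1
        sd = nd = 0.0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if is_synonymous(cur, pos, c2[pos], code_id):
                sd += 1.0
            else:
                nd += 1.0
            if is_stop(nxt, code_id):
                through_stop = True
            cur = nxt
        fallback.append((sd, nd))
        if not through_stop:
            paths.append((sd, nd))
    use = paths if paths else fallback
    sd = sum(p[0] for p in use) / len(use)
    nd = sum(p[1] for p in use) / len(use)
    return sd, nd
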