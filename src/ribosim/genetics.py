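"""Genetic-code helpers: codon normalization, stop/sense sets, codon-anticodon pairing.

Codons are handled internally as DNA 3-mers (U normalized to T) read 5'->3'.
Anticodons are RNA 3-mers read 5'->3'; codon position ``i`` (1-based, 5'->3')
pairs with anticodon position ``4 - i``.
"""

from __future__ import annotations

import itertools

from Bio.Data.CodonTable import unambiguous_dna_by_id

from .errors import InvalidCodonError

_STANDARD_TABLE = unambiguous_dna_by_id[1]

STOP_CODONS: frozenset[str] = frozenset(_STANDARD_TABLE.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(
    c for c in ("".join(p) for p in itertools.product("TCAG", repeat=3))
    if c not in STOP_CODONS
)
assert len(SENSE_CODONS) == 61

# Watson-Crick partners on the anticodon (RNA) side for each codon (DNA) letter.
_WC_PARTNER = {"A": "U", "T": "A", "G": "C", "C": "G"}

_RNA_LETTERS = frozenset("ACGU")


def normalize_codon(codon: str) -> str:
    """Return ``codon`` upper-cased with U->T; raise on anything else.

    Accepts DNA or RNA alphabets. Stop codons pass through; callers that
    need a sense codon use :func:`require_sense_codon`.
    """
    c = codon.upper().replace("U", "T")
    if len(c) != 3 or any(b not in "ACGT" for b in c):
        raise InvalidCodonError(f"not a codon over ACGT/U: {codon!r}")
    return c


def require_sense_codon(codon: str) -> str:
    c = normalize_codon(codon)
    if c in STOP_CODONS:
        raise InvalidCodonError(f"stop codon where a sense codon is required: {codon!r}")
    return c


def translate_codon(codon: str) -> str:
    """One-letter amino acid for a sense codon ('*' never returned)."""
    return _STANDARD_TABLE.forward_table[require_sense_codon(codon)]


def validate_anticodon(anticodon: str) -> str:
    a = anticodon.upper().replace("T", "U")
    if len(a) != 3 or any(b not in _RNA_LETTERS for b in a):
        raise InvalidCodonError(f"not an RNA anticodon: {anticodon!r}")
    return a


def wc_anticodon(codon: str) -> str:
    """The perfectly Watson-Crick complementary anticodon (RNA, 5'->3')."""
    c = normalize_codon(codon)
    return "".join(_WC_PARTNER[b] for b in reversed(c))


def mismatch_positions(codon: str, anticodon: str) -> tuple[int, ...]:
    """Codon positions (1-3, 5'->3') that do not form a strict WC pair.

    Strict Watson-Crick only (A-U, G-C); wobble pairs count as mismatches
    here, since decoding legitimacy is carried by specificity tables, not
    inferred from the anticodon.
    """
    c = normalize_codon(codon)
    a = validate_anticodon(anticodon)
    return tuple(i for i in range(1, 4) if a[3 - i] != _WC_PARTNER[c[i - 1]])


def codons_of(seq: str) -> list[str]:
    """Split a nucleotide string into codons (length must be divisible by 3)."""
    s = seq.upper().replace("U", "T")
    if len(s) % 3:
        raise InvalidCodonError(f"sequence length {len(s)} not divisible by 3")
    return [s[i : i + 3] for i in range(0, len(s), 3)]
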