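"""Canonical lox-site sequences and small sequence helpers.

All sequences are written on the analysis (top) strand. A lox site is
left RBE (13 bp) + asymmetric spacer (8 bp) + right RBE (13 bp); the two
RBEs are an inverted repeat, so the wild-type right RBE is the reverse
complement of the left RBE. Table-style listings elsewhere often print
the loxP spacer as its bottom-strand reading GCATACAT.
"""

from __future__ import annotations

DNA_ALPHABET = "ACGT"

#: Left recombinase-binding element, shared by loxP and lox2272.
LEFT_RBE = "ATAACTTCGTATA"

#: Wild-type right RBE on the top strand (reverse complement of LEFT_RBE).
WT_RBE = "TATACGAAGTTAT"

#: 8-bp spacers on the top strand. loxP and lox2272 spacers are
#: incompatible, which makes excision between the two pairs mutually
#: exclusive on one molecule.
LOXP_SPACER = "ATGTATGC"
LOX2272_SPACER = "AAGTATCC"

#: 21-bp anchors (left RBE + spacer) used for exact-match variant
#: extraction: the 13 bases following a loxP anchor are the variant RBE.
LOXP_ANCHOR = LEFT_RBE + LOXP_SPACER
LOX2272_ANCHOR = LEFT_RBE + LOX2272_SPACER

RBE_LENGTH = 13
LOX_SITE_LENGTH = 34

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (ACGT, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def lox_site(right_rbe: str, spacer: str = LOXP_SPACER) -> str:
    """Assemble a 34-bp lox site from a right RBE and a spacer."""
    if len(right_rbe) != RBE_LENGTH:
        raise ValueError(f"right RBE must be {RBE_LENGTH} bp, got {len(right_rbe)}")
    return LEFT_RBE + spacer + right_rbe


#: The canonical 34-bp sites.
LOXP_SITE = lox_site(WT_RBE, LOXP_SPACER)
LOX2272_SITE = lox_site(WT_RBE, LOX2272_SPACER)
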