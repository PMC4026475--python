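"""Published R2 size-class structures for *Rhinolophus sinicus*.

The run-length structures of every observed R2 size class (one row per
clone size class, grouped by taxon and individual), together with the
published array length and full-unit count N.  These rows serve as
reference inputs for the repeat decomposer: reconstructing a row's
sequence from its structure string and decomposing it must round-trip to
the printed structure, length and N.

Three rows (LLJ028 S1/S2 and ASY20 S1) are reproduced verbatim although
their printed run counts do not sum to their own N column (whose product
with the 11-bp period does match the printed length); the structure
strings of those rows evidently contain typesetting errors.  They are
flagged via :attr:`SizeClassRow.arithmetic_consistent` so that
length/N summaries can restrict themselves to self-consistent rows.
"""

from __future__ import annotations

from dataclasses import dataclass

from .motifs import parse_structure

__all__ = ["SizeClassRow", "KNOWN_ROWS", "rows_for"]


@dataclass(frozen=True)
class SizeClassRow:
    taxon: str
    individual: str
    size_class: str
    length: int
    n_units: int
    structure: str

    @property
    def arithmetic_consistent(self) -> bool:
        """True when the printed runs sum to N and 11*N + literals = length."""
        runs = parse_structure(self.structure)
        full = sum(c for lab, c in runs if len(lab) == 1)
        lit = sum(len(lab) * c for lab, c in runs if len(lab) > 1)
        return full == self.n_units and 11 * full + lit == self.length


_E = "East sinicus"
_H = "Hainan sinicus"
_C = "Central sinicus"
_S = "septentrionalis"

KNOWN_ROWS: tuple[SizeClassRow, ...] = (
    SizeClassRow(_E, "FGB008", "S1", 220, 20, "(A)4(B)1(A)5(B)2(A)6(B)2"),
    SizeClassRow(_E, "FGB008", "S2", 220, 20, "(A)4(B)1(A)5(B)2(A)7(B)1"),
    SizeClassRow(_E, "ZY03", "S1", 209, 19, "(A)1(B)1(A)5(B)2(A)3(B)1(A)3(B)3"),
    SizeClassRow(_E, "ZY03", "S2", 198, 18, "(A)1(B)1(A)5(B)2(A)2(B)1(A)3(B)3"),
    SizeClassRow(_E, "ZY03", "S3", 187, 17, "(A)1(B)1(A)4(B)2(A)2(B)1(A)3(B)3"),
    SizeClassRow(_E, "ZY03", "S4", 187, 17, "(A)1(B)1(A)5(B)1(A)2(B)1(A)3(B)3"),
    SizeClassRow(_E, "YH05", "S1", 187, 17, "(A)10(B)7"),
    SizeClassRow(_E, "HS04", "S1", 176, 16, "(A)2(B)7(A)3(B)4"),
    SizeClassRow(_E, "HS04", "S2", 154, 14, "(A)2(B)2(A)2(B)2(A)1(B)5"),
    SizeClassRow(_E, "HS04", "S3", 143, 13, "(A)2(B)4(A)3(B)4"),
    SizeClassRow(_E, "LLJ028", "S1", 209, 19, "(C)1(D)6(C)1(D)4(C)5(D)1(C)1(D)1(C)1"),
    SizeClassRow(_E, "LLJ028", "S2", 198, 18, "(C)2(D)4(C)1(D)4(C)5(D)1(C)1(D)1(C)1"),
    SizeClassRow(_E, "WLB007", "S1", 209, 19, "(D)1(C)1(D)1(C)1(D)4(C)2(D)1(C)3(D)3(C)2"),
    SizeClassRow(_E, "WLB007", "S2", 209, 19, "(D)1(C)1(D)1(C)1(D)3(C)3(D)1(C)3(D)3(C)2"),
    SizeClassRow(_E, "ASY20", "S1", 209, 19,
                 "(E)2(D)1(E)3(D)1(E)3(D)1(E)1(D)1(E)1(C)1(D)1(C)4(D)1(C)2"),
    SizeClassRow(_E, "ASY20", "S2", 198, 18, "(E)1(D)1(E)1(D)5(E)1(C)1(D)1(C)4(D)1(C)2"),
    SizeClassRow(_E, "ASY20", "S3", 176, 16, "(E)1(D)5(E)1(C)1(D)1(C)4(D)1(C)2"),
    SizeClassRow(_E, "ASY20", "S4", 165, 15, "(E)1(D)1(E)1(D)4(E)1(C)1(D)1(C)2(D)1(C)2"),
    SizeClassRow(_H, "YGL418", "S1", 214, 19, "(C)1AACGC(D)6(C)1(D)1(C)3(D)2(C)1(D)1(C)3"),
    SizeClassRow(_H, "YGL418", "S2", 203, 18, "(C)1AACGC(D)5(C)1(D)1(C)3(D)2(C)1(D)1(C)3"),
    SizeClassRow(_H, "YGL418", "S3", 181, 16, "(C)1AACGC(D)4(C)1(D)1(C)3(D)1(C)1(D)1(C)3"),
    SizeClassRow(_H, "YG24", "S1", 209, 19,
                 "(C)3(D)3(C)1(D)1(C)1(D)1(C)1(D)3(C)1(D)1(C)1(D)1(C)1"),
    SizeClassRow(_H, "YG11", "S1", 176, 16, "(C)5(D)1(C)4(D)1(C)1(D)1(C)1(D)1(C)1"),
    SizeClassRow(_H, "YG11", "S2", 154, 14, "(C)3(D)1(C)4(D)1(C)1(D)1(C)1(D)1(C)1"),
    SizeClassRow(_H, "CX03", "S1", 198, 18, "(C)7(D)3(C)4(D)1(C)3"),
    SizeClassRow(_H, "CX03", "S2", 187, 17, "(C)6(D)3(C)4(D)1(C)3"),
    SizeClassRow(_C, "TL07", "S1", 209, 19, "(C)19"),
    SizeClassRow(_C, "TL07", "S2", 176, 16, "(C)16"),
    SizeClassRow(_C, "JJ09", "S1", 198, 18, "(C)18"),
    SizeClassRow(_C, "JJ08", "S1", 77, 7, "(C)7"),
    SizeClassRow(_S, "SHC009", "S1", 209, 19, "(C)10(D)1(C)8"),
    SizeClassRow(_S, "SHC009", "S2", 187, 17, "(C)17"),
    SizeClassRow(_S, "WM32", "S1", 209, 19, "(C)19"),
    SizeClassRow(_S, "WM32", "S2", 198, 18, "(C)18"),
    SizeClassRow(_S, "YBG15", "S1", 165, 15, "(C)15"),
    SizeClassRow(_S, "YBG15", "S2", 33, 3, "(C)3"),
)


def rows_for(taxon: str | None = None, individual: str | None = None) -> list[SizeClassRow]:
    """Filter the published rows by taxon and/or individual."""
    rows = list(KNOWN_ROWS)
    if taxon is not None:
        rows = [r for r in rows if r.taxon == taxon]
    if individual is not None:
        rows = [r for r in rows if r.individual == individual]
    return rows
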