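"""Junction-read chemistry constants shared by the simulator and the trimmer.

A splinkerette junction read is laid out as::

    [transposon IRDR end] [genomic flank starting at the TA junction] [linker]

The transposon integrates at a TA dinucleotide, so the genomic flank always
begins with ``TA`` regardless of which strand the read comes from (TA is its
own reverse complement). Reads may come off either transposon end (the left or
right inverted repeat/direct repeat, IRDR-L / IRDR-R) and map to either
genomic strand.

Orientation convention
----------------------
``transposon_orient`` is the genomic strand on which the transposon's internal
(CAG) promoter points in its transcriptional direction. The pairing of IRDR
end and mapped strand determines it via the fixed table ``ORIENTATION``:

    (IRDR end, mapped strand) -> transposon_orient
    (R, +) -> +        (L, -) -> +
    (R, -) -> -        (L, +) -> -

Only the pairing is load-bearing: the simulator emits reads using the inverse
of this table and the locator applies it forward, so a consistent relabelling
of the two ends would leave every downstream statistic unchanged.
"""

from __future__ import annotations

# Synthetic stand-ins for the transposon terminal repeats and the splinkerette
# linker. Lengths (30/30/24 nt) are typical of the real chemistry; the actual
# base content only needs to be unambiguous against random genomic sequence.
IRDR_L = "TTACAGTTGAAGTCGGAAGTTTACATACAC"
IRDR_R = "GGATTAAATGTCAGGAATTGTGAAAAAGTG"
LINKER = "CGAATCGTAACCGTTCGTACGAGA"

#: (irdr_end, mapped_strand) -> transposon orientation on the genome.
ORIENTATION: dict[tuple[str, str], str] = {
    ("R", "+"): "+",
    ("L", "-"): "+",
    ("R", "-"): "-",
    ("L", "+"): "-",
}

#: transposon orientation -> list of (irdr_end, strand) pairs producing it.
ORIENTATION_INVERSE: dict[str, list[tuple[str, str]]] = {
    "+": [("R", "+"), ("L", "-")],
    "-": [("R", "-"), ("L", "+")],
}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]
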