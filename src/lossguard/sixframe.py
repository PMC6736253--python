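"""Six-frame conceptual translation and frame/genome coordinate mapping.

A genome is translated in all three offsets on both strands (frames
+1, +2, +3, -1, -2, -3, transeq-style: the offset applies to the 5' end
of the respective strand).  Stop codons are rendered ``*`` and codons
containing ``N`` as ``X``; trailing nucleotides that do not fill a codon
are dropped.  NCBI translation tables are supported through Biopython —
notably table 6 (ciliate nuclear), where TAA/TAG encode glutamine.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Data import CodonTable
from Bio.Seq import Seq

__all__ = [
    "FrameTranslation",
    "FRAMES",
    "translate_six_frames",
    "frame_to_genome",
    "genome_to_frame",
    "reverse_complement",
]

FRAMES = (1, 2, 3, -1, -2, -3)

_VALID = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(dna: str) -> str:
    return dna.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class FrameTranslation:
    """Translation of one contig in one reading frame."""

    contig_id: str
    frame: int  # +1..+3 forward, -1..-3 on the reverse complement
    peptide: str
    source_length: int  # contig length in nt

    @property
    def strand(self) -> str:
        return "+" if self.frame > 0 else "-"


def _check_table(table_id: int) -> None:
    try:
        CodonTable.unambiguous_dna_by_id[table_id]
    except KeyError:
        raise ValueError(f"unsupported NCBI translation table: {table_id}") from None


def _translate_frame(strand_seq: str, offset: int, table_id: int) -> str:
    sub = strand_seq[offset:]
    sub = sub[: len(sub) - len(sub) % 3]
    if not sub:
        return ""
    return str(Seq(sub).translate(table=table_id))


def translate_six_frames(dna: str, table_id: int = 1, contig_id: str = "") -> list[FrameTranslation]:
    """Translate ``dna`` in all six reading frames.

    Parameters
    ----------
    dna:
        Nucleotide sequence over the alphabet ``{A, C, G, T, N}``
        (case-insensitive).
    table_id:
        NCBI translation table; 1 (standard) and 6 (ciliate) are the
        tables used in practice, any Biopython-known table is accepted.

    Returns
    -------
    list of six :class:`FrameTranslation`, in frame order
    +1, +2, +3, -1, -2, -3.
    """
    if not dna:
        raise ValueError("empty sequence")
    dna = dna.upper()
    if not set(dna) <= _VALID:
        bad = sorted(set(dna) - _VALID)
        raise ValueError(f"sequence contains unsupported characters: {bad}")
    _check_table(table_id)
    rc = reverse_complement(dna)
    out = []
    for frame in FRAMES:
        strand_seq = dna if frame > 0 else rc
        offset = abs(frame) - 1
        out.append(
            FrameTranslation(
                contig_id=contig_id,
                frame=frame,
                peptide=_translate_frame(strand_seq, offset, table_id),
                source_length=len(dna),
            )
        )
    return out


def frame_to_genome(contig_length: int, frame: int, aa_start: int, aa_end: int) -> tuple[int, int, str]:
    """Map a peptide interval in one reading frame to forward-strand
    genomic coordinates.

    Both the input peptide interval and the returned nucleotide interval
    are 0-based half-open.  For reverse frames the interval is computed
    on the reverse complement and then reflected onto the forward strand.

    Returns ``(nt_start, nt_end, strand)`` with strand ``'+'`` or ``'-'``.
    """
    if frame not in FRAMES:
        raise ValueError(f"invalid frame: {frame}")
    offset = abs(frame) - 1
    n_codons = (contig_length - offset) // 3
    if not (0 <= aa_start <= aa_end <= max(n_codons, 0)):
        raise ValueError(
            f"aa interval [{aa_start}, {aa_end}) out of range for frame {frame} of a {contig_length} nt contig"
        )
    lo = offset + 3 * aa_start
    hi = offset + 3 * aa_end
    if frame > 0:
        return lo, hi, "+"
    return contig_length - hi, contig_length - lo, "-"


def genome_to_frame(contig_length: int, frame: int, nt_start: int, nt_end: int) -> tuple[int, int]:
    """Inverse of :func:`frame_to_genome` for codon-aligned intervals."""
    if frame not in FRAMES:
        raise ValueError(f"invalid frame: {frame}")
    offset = abs(frame) - 1
    if frame > 0:
        lo, hi = nt_start, nt_end
    else:
        lo, hi = contig_length - nt_end, contig_length - nt_start
    if (lo - offset) % 3 or (hi - offset) % 3:
        raise ValueError(f"interval [{nt_start}, {nt_end}) is not codon-aligned in frame {frame}")
    aa_start, aa_end = (lo - offset) // 3, (hi - offset) // 3
    if aa_start < 0 or aa_end < aa_start:
        raise ValueError(f"interval [{nt_start}, {nt_end}) out of range for frame {frame}")
    return aa_start, aa_end
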