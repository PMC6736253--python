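"""Validation and post-processing of domain hits.

This module turns raw homology hits — from HMMER's domtblout or from the
built-in motif detector — into presence/absence calls: per-family bitscore
cutoffs (gathering-cutoff semantics, inclusive ``>=``), removal of
stop-codon-containing hits in translated DNA (operational pseudogene
definition), and greedy selection of best-scoring non-overlapping hits
per domain family.

Overlap is judged in forward-strand genomic coordinates across frames and
strands: two reading frames over the same locus are one biological signal
and must not be counted twice.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import DomainModel
from .sixframe import FrameTranslation, frame_to_genome

__all__ = [
    "Hit",
    "apply_score_cutoffs",
    "flag_pseudogene",
    "select_best_nonoverlapping",
    "toy_detect_sixframe",
    "toy_detect_proteome",
    "hits_to_matrix",
]

PROTEOME = "proteome"
SIXFRAME = "sixframe"


@dataclass(frozen=True)
class Hit:
    """One validated or candidate domain hit.

    ``interval`` is 0-based half-open: forward-strand genomic nucleotides
    for six-frame hits, target amino-acid positions for proteome hits.
    """

    domain_id: str
    species_id: str
    target_id: str
    target_kind: str  # PROTEOME | SIXFRAME
    bitscore: float
    interval: tuple[int, int]
    frame: int | None = None  # six-frame hits only
    aligned_subseq: str = ""  # aa, may contain '*'

    def __post_init__(self):
        if self.target_kind not in (PROTEOME, SIXFRAME):
            raise ValueError(f"invalid target_kind: {self.target_kind}")
        if self.target_kind == SIXFRAME and self.interval[1] <= self.interval[0]:
            raise ValueError("six-frame hit must have a nonempty genomic interval")


def apply_score_cutoffs(hits: Sequence[Hit], cutoffs: Mapping[str, float]) -> list[Hit]:
    """Keep hits whose bitscore meets the per-domain cutoff (inclusive).

    Every hit's domain must have a cutoff entry; a missing entry is an
    error rather than a silent keep.
    """
    missing = {h.domain_id for h in hits} - set(cutoffs)
    if missing:
        raise KeyError(f"no score cutoff for domains: {sorted(missing)}")
    return [h for h in hits if h.bitscore >= cutoffs[h.domain_id]]


def flag_pseudogene(hit: Hit) -> bool:
    """True iff the aligned translated sequence contains a stop symbol.

    Only six-frame hits can be pseudogenes; proteome hits are never
    flagged (predicted proteins do not contain in-frame stops).
    """
    if hit.target_kind != SIXFRAME:
        return False
    return "*" in hit.aligned_subseq


def select_best_nonoverlapping(hits: Iterable[Hit]) -> list[Hit]:
    """Greedy best-scoring non-overlapping hit selection.

    Hits are taken in order of descending bitscore (ties: smaller
    interval start, then lexicographic target id); a candidate is
    discarded if its interval shares at least one position with an
    already-kept hit of the same domain on the same target/contig,
    regardless of frame or strand.
    """
    ordered = sorted(hits, key=lambda h: (-h.bitscore, h.interval[0], h.target_id))
    kept: list[Hit] = []
    occupied: dict[tuple[str, str, str], list[tuple[int, int]]] = {}
    for hit in ordered:
        key = (hit.domain_id, hit.species_id, hit.target_id)
        intervals = occupied.setdefault(key, [])
        lo, hi = hit.interval
        if any(lo < b and a < hi for a, b in intervals):
            continue
        intervals.append((lo, hi))
        kept.append(hit)
    return kept


# ---------------------------------------------------------------------------
# Toy motif detector
#
# A deliberately simple profile-search stand-in: each domain family is
# represented by a consensus peptide, and a hit is a window of the target
# matching it with at most `max_mismatches` substitutions.  Stop ('*') and
# unknown ('X') characters in the target are tolerated (not counted as
# mismatches): a homology search aligns through in-frame stops, which is
# precisely what makes pseudogenes detectable — and flaggable — in
# translated DNA.  Score = match_length - 2 * mismatches.
# ---------------------------------------------------------------------------

_TOLERATED = frozenset("*X")


def _scan(target: str, peptide: str, max_mismatches: int) -> list[tuple[int, int]]:
    """Find approximate occurrences of ``peptide`` in ``target``.

    Returns ``(offset, n_mismatches)`` pairs.  Uses a pigeonhole anchor
    strategy: the peptide is split into ``max_mismatches + 2`` chunks, so
    any window with <= max_mismatches substitutions plus at most one
    tolerated stop/unknown has one chunk matching exactly; candidates are
    located with C-speed ``str.find`` and verified per-position.
    """
    m = len(peptide)
    if m == 0 or len(target) < m:
        return []
    n_chunks = max_mismatches + 2
    chunk_len = m // n_chunks
    results: dict[int, int] = {}

    def verify(offset: int) -> None:
        if offset in results or offset < 0 or offset + m > len(target):
            return
        mm = 0
        window = target[offset : offset + m]
        for a, b in zip(window, peptide):
            if a != b and a not in _TOLERATED:
                mm += 1
                if mm > max_mismatches:
                    return
        results[offset] = mm

    if chunk_len < 4:
        # peptide too short for anchoring: brute-force scan
        for offset in range(len(target) - m + 1):
            verify(offset)
    else:
        for c in range(n_chunks):
            lo = c * chunk_len
            hi = m if c == n_chunks - 1 else lo + chunk_len
            chunk = peptide[lo:hi]
            start = target.find(chunk)
            while start != -1:
                verify(start - lo)
                start = target.find(chunk, start + 1)
    return sorted(results.items())


def toy_detect_sixframe(
    translations: Mapping[str, Sequence[FrameTranslation]],
    models: Mapping[str, DomainModel],
    max_mismatches: int = 0,
) -> list[Hit]:
    """Scan six-frame translations for consensus-peptide matches.

    Parameters
    ----------
    translations:
        species_id -> the six :class:`FrameTranslation` objects of each
        of its contigs (concatenated into one sequence per frame entry).
    models:
        domain_id -> :class:`DomainModel` with a consensus peptide.
    """
    hits: list[Hit] = []
    for species_id, frames in translations.items():
        for ft in frames:
            for model in models.values():
                pep = model.consensus_peptide
                if not pep:
                    continue
                for offset, mm in _scan(ft.peptide, pep, max_mismatches):
                    nt_lo, nt_hi, _strand = frame_to_genome(
                        ft.source_length, ft.frame, offset, offset + len(pep)
                    )
                    hits.append(
                        Hit(
                            domain_id=model.domain_id,
                            species_id=species_id,
                            target_id=ft.contig_id,
                            target_kind=SIXFRAME,
                            bitscore=float(len(pep) - 2 * mm),
                            interval=(nt_lo, nt_hi),
                            frame=ft.frame,
                            aligned_subseq=ft.peptide[offset : offset + len(pep)],
                        )
                    )
    return hits


def toy_detect_proteome(
    proteomes: Mapping[str, Mapping[str, str]],
    models: Mapping[str, DomainModel],
    max_mismatches: int = 0,
) -> list[Hit]:
    """Scan predicted proteomes (species_id -> {protein_id: aa seq}).

    Proteins of one species are scanned as a single separator-joined
    string so each consensus needs one pass per species; matches spanning
    the separator are impossible (the separator character never matches).
    """
    hits: list[Hit] = []
    sep = "#"
    for species_id, proteins in proteomes.items():
        ids = list(proteins)
        seqs = [proteins[i] for i in ids]
        joined = sep.join(seqs)
        # protein start offsets in the joined string
        starts: list[int] = []
        pos = 0
        for s in seqs:
            starts.append(pos)
            pos += len(s) + 1
        for model in models.values():
            pep = model.consensus_peptide
            if not pep:
                continue
            for offset, mm in _scan(joined, pep, max_mismatches):
                window = joined[offset : offset + len(pep)]
                if sep in window:
                    continue
                # locate containing protein by binary search on starts
                idx = bisect.bisect_right(starts, offset) - 1
                local = offset - starts[idx]
                hits.append(
                    Hit(
                        domain_id=model.domain_id,
                        species_id=species_id,
                        target_id=ids[idx],
                        target_kind=PROTEOME,
                        bitscore=float(len(pep) - 2 * mm),
                        interval=(local, local + len(pep)),
                        frame=None,
                        aligned_subseq=window,
                    )
                )
    return hits


def hits_to_matrix(
    hits: Sequence[Hit],
    domain_ids: Sequence[str],
    species_ids: Sequence[str],
) -> pd.DataFrame:
    """Collapse validated hits into a binary presence/absence matrix.

    A cell is 1 iff the species has at least one surviving
    non-pseudogene hit for the domain.  Hits referencing unknown domains
    or species are an error.
    """
    matrix = pd.DataFrame(0, index=pd.Index(domain_ids, name="domain_id"), columns=list(species_ids), dtype="int8")
    domain_set, species_set = set(domain_ids), set(species_ids)
    for hit in hits:
        if hit.domain_id not in domain_set:
            raise KeyError(f"hit references unknown domain: {hit.domain_id}")
        if hit.species_id not in species_set:
            raise KeyError(f"hit references unknown species: {hit.species_id}")
        if not flag_pseudogene(hit):
            matrix.at[hit.domain_id, hit.species_id] = 1
    return matrix
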