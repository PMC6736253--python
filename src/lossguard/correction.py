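"""Verification of inferred absences in translated genomes and loss recount.

This is the headline computation: absences inferred from predicted
proteomes are re-examined against six-frame translated genomes.  An
absence with a surviving non-pseudogene hit is a *found* (falsely
inferred) absence; an absence whose only hits carry in-frame stops is a
pseudogene and stays absent.  Found absences are flipped to present and
the single-gain reconstruction is re-run per domain — with the ancestral
domain set frozen from the uncorrected analysis — to quantify how much
the loss estimate shrinks.

Correcting a species-specific absence removes exactly one terminal-branch
loss; correcting a clade-specific absence can leave the domain's loss
count unchanged or even raise it (the ancestral loss splits into several
shallower ones), which is why species-specific false absences dominate
the loss-estimate inflation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import dollo
from .dollo import AbsenceRecord, LossSummary
from .hitproc import Hit, flag_pseudogene
from .tree import SpeciesTree

logger = logging.getLogger(__name__)

__all__ = [
    "CorrectionResult",
    "find_absence_hits",
    "correct_and_recount",
    "summarize_found",
]


@dataclass
class CorrectionResult:
    """Corrected matrix and loss recount after absence verification."""

    corrected_matrix: pd.DataFrame
    uncorrected: LossSummary
    corrected: LossSummary
    reduction_percent: float  # 100 * (uncorrected - corrected) / uncorrected


def find_absence_hits(
    absences: Sequence[AbsenceRecord],
    sixframe_hits: Sequence[Hit],
    presence_matrix: pd.DataFrame | None = None,
) -> list[AbsenceRecord]:
    """Match processed six-frame hits against inferred absences.

    ``sixframe_hits`` must already have gone through the same validation
    chain as proteome hits (score cutoffs, overlap resolution) with
    pseudogene-flagged hits retained: an absence is *found* iff it has at
    least one non-pseudogene hit, and *pseudogene-only* iff it has hits
    but all of them carry stops.

    Hits for cells that are not absences are ignored with a warning when
    a presence matrix is supplied (presence is already established).
    """
    absent_keys = {(a.domain_id, a.species_id) for a in absences}
    clean: dict[tuple[str, str], int] = {}
    stopped: dict[tuple[str, str], int] = {}
    n_ignored = 0
    for hit in sixframe_hits:
        key = (hit.domain_id, hit.species_id)
        if key not in absent_keys:
            if (
                presence_matrix is not None
                and hit.domain_id in presence_matrix.index
                and hit.species_id in presence_matrix.columns
            ):
                n_ignored += 1
                logger.debug(
                    "six-frame hit for non-absent cell (%s, %s) ignored", hit.domain_id, hit.species_id
                )
            continue
        if flag_pseudogene(hit):
            stopped[key] = stopped.get(key, 0) + 1
        else:
            clean[key] = clean.get(key, 0) + 1
    if n_ignored:
        logger.warning("%d six-frame hits for non-absent cells ignored (presence already established)", n_ignored)
    out = []
    for rec in absences:
        key = (rec.domain_id, rec.species_id)
        found = clean.get(key, 0) > 0
        pseudo_only = not found and stopped.get(key, 0) > 0
        out.append(replace(rec, found_in_genome=found, pseudogene_only=pseudo_only))
    return out


def correct_and_recount(
    tree: SpeciesTree,
    observed_matrix: pd.DataFrame,
    absences: Sequence[AbsenceRecord],
    leca_domains: Iterable[str],
) -> CorrectionResult:
    """Flip found absences to present and re-run the reconstruction.

    The ancestral domain set is frozen from the uncorrected analysis
    (``leca_domains``); found absences outside it are not corrected.
    Pseudogene-only absences never change the matrix.
    """
    leca = [d for d in observed_matrix.index if d in set(leca_domains)]
    corrected = observed_matrix.copy()
    for rec in absences:
        if not rec.found_in_genome:
            continue
        if observed_matrix.at[rec.domain_id, rec.species_id] != 0:
            raise ValueError(
                f"found flag for non-absent cell ({rec.domain_id}, {rec.species_id})"
            )
        if rec.domain_id in set(leca):
            corrected.at[rec.domain_id, rec.species_id] = 1

    def recount(matrix: pd.DataFrame) -> LossSummary:
        recs = [
            dollo.reconstruct(tree, matrix.loc[d].to_dict(), d)
            for d in leca
            if matrix.loc[d].sum() > 0
        ]
        return dollo.count_losses(recs)

    uncorr = recount(observed_matrix)
    corr = recount(corrected)
    reduction = (
        100.0 * (uncorr.total - corr.total) / uncorr.total if uncorr.total else 0.0
    )
    return CorrectionResult(
        corrected_matrix=corrected,
        uncorrected=uncorr,
        corrected=corr,
        reduction_percent=reduction,
    )


def summarize_found(
    absences: Sequence[AbsenceRecord],
    min_absences_per_genome: int | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-genome found-absence percentages and dataset medians.

    For every genome (species) the percentage of found absences is
    computed among all absences and within the clade-/species-specific
    categories; a genome contributes to a category's median only if it
    has at least one absence in that category.  With
    ``min_absences_per_genome`` set (BUSCO-style universal sets), only
    genomes with *more* than that many absences are included at all.

    Returns the per-genome table and a summary dict with found counts,
    overall percentages and medians.
    """
    frame = pd.DataFrame(
        [
            {
                "species_id": a.species_id,
                "category": a.category,
                "found": bool(a.found_in_genome),
                "pseudogene_only": bool(a.pseudogene_only),
            }
            for a in absences
        ]
    )
    if frame.empty:
        return pd.DataFrame(), {"n_absences": 0}
    rows = []
    for species_id, grp in frame.groupby("species_id"):
        if min_absences_per_genome is not None and len(grp) <= min_absences_per_genome:
            continue
        row = {"species_id": species_id, "n_absences": len(grp), "n_found": int(grp["found"].sum())}
        row["pct_found_total"] = 100.0 * row["n_found"] / row["n_absences"]
        for cat in (dollo.CLADE_SPECIFIC, dollo.SPECIES_SPECIFIC):
            sub = grp[grp["category"] == cat]
            row[f"n_{cat}"] = len(sub)
            row[f"n_found_{cat}"] = int(sub["found"].sum())
            row[f"pct_found_{cat}"] = (
                100.0 * sub["found"].sum() / len(sub) if len(sub) else float("nan")
            )
        rows.append(row)
    per_genome = pd.DataFrame(rows).set_index("species_id") if rows else pd.DataFrame()
    summary: dict[str, float] = {
        "n_absences": int(len(frame)),
        "n_found": int(frame["found"].sum()),
        "n_genomes": int(len(per_genome)),
    }
    if len(frame):
        summary["pct_found_total"] = 100.0 * frame["found"].sum() / len(frame)
    for cat in (dollo.CLADE_SPECIFIC, dollo.SPECIES_SPECIFIC):
        sub = frame[frame["category"] == cat]
        summary[f"n_{cat}"] = int(len(sub))
        summary[f"n_found_{cat}"] = int(sub["found"].sum())
        if len(sub):
            summary[f"pct_found_{cat}"] = 100.0 * sub["found"].sum() / len(sub)
    if not per_genome.empty:
        summary["median_pct_found_total"] = float(per_genome["pct_found_total"].median())
        for cat in (dollo.CLADE_SPECIFIC, dollo.SPECIES_SPECIFIC):
            vals = per_genome[f"pct_found_{cat}"].dropna()
            if len(vals):
                summary[f"median_pct_found_{cat}"] = float(vals.median())
    return per_genome, summary
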