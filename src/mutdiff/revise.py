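"""Difficulty-weighted revised counts, threshold calibration, and
functional classification of coding mutations.

The revised count of an event is the sum over cancer types of the per-type
sample count weighted by that type's relative difficulty for the event's
context class:

    R = Σ_t O_t × D_{c,t}

A revised count below the wild-type bound predicts retained function; above
the loss-of-function bound predicts loss of function; the band between is
indeterminate. Events whose protein change was also produced by a
multi-nucleotide substitution are left unscored unless the SNV-derived
revised count already exceeds the LOF bound (difficulties are never assigned
to double substitutions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .catalog_io import CodingGenome, MutationEvent
from .context import extract_context
from .difficulty import DifficultyTable
from .errors import DataError

WT_MAX_DEFAULT = 700.0
LOF_MIN_DEFAULT = 900.0

WT_LIKE = "wt_like"
INDETERMINATE = "indeterminate"
LOF = "lof"
UNSCORED = "unscored"


@dataclass
class RevisedAssessment:
    """Revised count and functional call for one mutation event."""

    event: MutationEvent
    pentamer: str
    contributions: dict[str, tuple[int, float, float]]  # type -> (O_t, D_t, O_t*D_t)
    revised_count: float
    label: str
    wt_max: float
    lof_min: float

    @property
    def original_count(self) -> int:
        return self.event.original_count


def classify(
    assessment_or_count,
    wt_max: float = WT_MAX_DEFAULT,
    lof_min: float = LOF_MIN_DEFAULT,
    mnv_support: bool = False,
) -> str:
    """Functional label from a revised count.

    Strict inequalities on both sides: R < wt_max → wt_like, R > lof_min →
    lof, anything in [wt_max, lof_min] → indeterminate. MNV-supported events
    are unscored unless R already exceeds the LOF bound.
    """
    if wt_max > lof_min:
        raise DataError(f"wt_max ({wt_max}) must not exceed lof_min ({lof_min})")
    if isinstance(assessment_or_count, RevisedAssessment):
        r = assessment_or_count.revised_count
        mnv_support = mnv_support or assessment_or_count.event.mnv_support
    else:
        r = float(assessment_or_count)
    if r > lof_min:
        return LOF
    if mnv_support:
        return UNSCORED
    if r < wt_max:
        return WT_LIKE
    return INDETERMINATE


def revised_count(
    event: MutationEvent,
    genome: CodingGenome,
    per_type_tables: Mapping[str, DifficultyTable] | None = None,
    fallback_table: DifficultyTable | None = None,
    wt_max: float = WT_MAX_DEFAULT,
    lof_min: float = LOF_MIN_DEFAULT,
) -> RevisedAssessment:
    """Compute R = Σ_t O_t × D_t for one event and label it.

    Cancer types without a dedicated table use the fallback (pan-cancer)
    table. Raises if the event's context is unavailable or its class is
    undefined under the table's zero policy.
    """
    per_type_tables = per_type_tables or {}
    pent = extract_context(genome, event.gene_id, event.cds_position)
    if pent is None:
        raise DataError(
            f"context unavailable for {event.gene_id}:c.{event.cds_position}"
            f"{event.ref}>{event.alt}; cannot compute a revised count"
        )
    contributions: dict[str, tuple[int, float, float]] = {}
    total = 0.0
    for ctype, o_t in sorted(event.per_type_counts.items()):
        table = per_type_tables.get(ctype, fallback_table)
        if table is None:
            raise DataError(
                f"no difficulty table for cancer type {ctype!r} and no fallback given"
            )
        d_t = table.difficulty(pent, event.alt)
        contributions[ctype] = (o_t, d_t, o_t * d_t)
        total += o_t * d_t
    label = classify(total, wt_max, lof_min, mnv_support=event.mnv_support)
    return RevisedAssessment(
        event=event,
        pentamer=pent,
        contributions=contributions,
        revised_count=total,
        label=label,
        wt_max=wt_max,
        lof_min=lof_min,
    )


@dataclass
class CalibrationResult:
    """Wild-type threshold derived from the synonymous revised-count
    distribution, with outliers (possible splice-disrupting synonymous
    changes) listed."""

    revised_counts: list[float]
    percentile: float
    wt_max: float
    outliers: list[tuple[str, float]]  # (description, R) for R > wt_max


def calibrate_thresholds(
    synonymous_assessments: Sequence,
    percentile: float = 95.0,
    min_events: int = 20,
) -> CalibrationResult:
    """Derive wt_max as a percentile of synonymous revised counts.

    Synonymous changes should be functionally silent, so their revised-count
    distribution bounds what neutral drift produces; events above the chosen
    percentile are reported as outliers (they may disrupt splicing rather
    than protein sequence).
    """
    values: list[float] = []
    names: list[str] = []
    for a in synonymous_assessments:
        if isinstance(a, RevisedAssessment):
            values.append(a.revised_count)
            ev = a.event
            names.append(f"{ev.gene_id}:c.{ev.cds_position}{ev.ref}>{ev.alt}")
        else:
            values.append(float(a))
            names.append("")
    if len(values) < min_events:
        raise DataError(
            f"only {len(values)} synonymous events (need >= {min_events}); "
            f"fall back to the default thresholds wt_max={WT_MAX_DEFAULT}, "
            f"lof_min={LOF_MIN_DEFAULT}"
        )
    wt_max = float(np.percentile(values, percentile))
    outliers = [(n, v) for n, v in zip(names, values) if v > wt_max]
    return CalibrationResult(
        revised_counts=values,
        percentile=percentile,
        wt_max=wt_max,
        outliers=sorted(outliers, key=lambda t: -t[1]),
    )


def _protein_change(cds: str, pos: int, ref: str, alt: str) -> tuple[str, int, str, str]:
    """(notation, residue index, ref_aa, alt_aa) for an SNV on a CDS."""
    i = pos - 1
    codon_idx = i // 3
    codon = cds[3 * codon_idx: 3 * codon_idx + 3]
    if len(codon) < 3:
        return (f"c.{pos}{ref}>{alt}", codon_idx + 1, "?", "?")
    offset = i - 3 * codon_idx
    new_codon = codon[:offset] + alt + codon[offset + 1:]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(new_codon).translate())
    return (f"{aa_ref}{codon_idx + 1}{aa_alt}", codon_idx + 1, aa_ref, aa_alt)


def annotate_gene(
    gene_events: Iterable[MutationEvent],
    genome: CodingGenome,
    per_type_tables: Mapping[str, DifficultyTable] | None = None,
    fallback_table: DifficultyTable | None = None,
    wt_max: float = WT_MAX_DEFAULT,
    lof_min: float = LOF_MIN_DEFAULT,
    per_residue: bool = False,
) -> pd.DataFrame:
    """Assessment table for a gene's events.

    One row per event with protein change, original count, revised count and
    label; ``per_residue=True`` instead aggregates events sharing an
    amino-acid position (summing original and revised counts), mirroring
    residue-level mutation histograms.
    """
    rows = []
    for ev in gene_events:
        cds = genome.cds(ev.gene_id)
        assessment = revised_count(ev, genome, per_type_tables, fallback_table, wt_max, lof_min)
        notation, residue, aa_ref, aa_alt = _protein_change(cds, ev.cds_position, ev.ref, ev.alt)
        rows.append(
            {
                "gene": ev.gene_id,
                "protein_change": notation,
                "cds_change": f"c.{ev.cds_position}{ev.ref}>{ev.alt}",
                "residue": residue,
                "synonymous": aa_ref == aa_alt,
                "pentamer": assessment.pentamer,
                "original_count": ev.original_count,
                "revised_count": assessment.revised_count,
                "label": assessment.label,
                "flags": "mnv_support" if ev.mnv_support else "",
            }
        )
    columns = [
        "gene", "protein_change", "cds_change", "residue", "synonymous",
        "pentamer", "original_count", "revised_count", "label", "flags",
    ]
    df = pd.DataFrame(rows, columns=columns)
    if not per_residue or df.empty:
        return df
    agg = (
        df.groupby(["gene", "residue"], as_index=False)
        .agg(
            original_count=("original_count", "sum"),
            revised_count=("revised_count", "sum"),
            n_events=("protein_change", "size"),
            protein_changes=("protein_change", lambda s: ";".join(s)),
        )
        .sort_values(["gene", "residue"], ignore_index=True)
    )
    return agg


def resistance_index(g1: float, g2: float) -> float:
    """Relative resistance index RI = (G2 − G1·G2) / (G1 − G1·G2).

    G1 and G2 are the marker-positive fractions before and after drug
    selection. RI > 1 means the construct enriched under treatment
    (dominant-negative readout); RI < 1 means sensitization.
    """
    if not 0 < g1 < 1:
        raise DataError(f"G1 must lie strictly between 0 and 1, got {g1}")
    if not 0 <= g2 <= 1:
        raise DataError(f"G2 must lie in [0, 1], got {g2}")
    denominator = g1 - g1 * g2
    if denominator == 0:
        raise DataError("resistance index undefined: G2 = 1 makes the denominator zero")
    return (g2 - g1 * g2) / denominator
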