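"""Synonymous codon recoding ("shielding") of mutation hotspot sites.

A hotspot codon can often be recoded synonymously so that the
single-nucleotide changes producing deleterious amino-acid substitutions
fall into harder-to-generate context classes. The quantity compared is the
summed mutational *tendency* (rate, not difficulty) of the SNVs in the codon
whose translated change belongs to a user-supplied loss-of-function target
set; recoding the codon changes both which SNVs produce those amino acids
and the pentanucleotide contexts of every position within two nucleotides.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio.Data import CodonTable
from Bio.Seq import Seq

from .catalog_io import CodingGenome
from .context import BASES, ContextClass, FLANK, PENTAMER_LEN
from .difficulty import TendencyEstimate
from .errors import DataError

_STANDARD = CodonTable.unambiguous_dna_by_id[1]


def _translate(codon: str) -> str:
    return str(Seq(codon).translate())


def synonymous_codons(codon: str) -> set[str]:
    """All sense codons encoding the same amino acid, excluding the input.

    Standard genetic code; stop codons are rejected.
    """
    codon = codon.upper()
    if len(codon) != 3 or set(codon) - set(BASES):
        raise DataError(f"invalid codon {codon!r}")
    if codon in _STANDARD.stop_codons:
        raise DataError(f"stop codon {codon!r} has no synonymous sense codons")
    aa = _translate(codon)
    return {
        c for c in _STANDARD.forward_table
        if _STANDARD.forward_table[c] == aa and c != codon
    }


def _rates(tendencies) -> Mapping[ContextClass, float]:
    if isinstance(tendencies, TendencyEstimate):
        return tendencies.rates
    return tendencies


def _context_from_seq(genome: CodingGenome, gene: str, seq: str, pos0: int) -> str | None:
    """Pentamer around 0-based position pos0 of a (possibly recoded) CDS,
    padded with the gene's genomic flanks at the edges."""
    L = len(seq)
    left_need = max(0, FLANK - pos0)
    right_need = max(0, pos0 + FLANK - (L - 1))
    left = right = ""
    if left_need or right_need:
        fl = genome.flanks(gene)
        if fl is None:
            return None
        up, down = fl
        if left_need:
            if len(up) < left_need:
                return None
            left = up[-left_need:]
        if right_need:
            if len(down) < right_need:
                return None
            right = down[:right_need]
    pent = left + seq[max(0, pos0 - FLANK): min(L, pos0 + FLANK + 1)] + right
    return pent if len(pent) == PENTAMER_LEN else None


def lof_tendency_sum(
    genome: CodingGenome,
    gene: str,
    codon_index: int,
    lof_changes: Iterable[str],
    tendencies,
    codon_override: str | None = None,
    expect_aa: str | None = None,
) -> float:
    """Summed tendency of the codon's SNVs whose amino-acid change is in the
    LOF target set.

    Parameters
    ----------
    codon_index
        1-based residue index (protein notation, e.g. 273 for R273).
    lof_changes
        Alternate amino acids (one-letter, '*' for nonsense) treated as
        deleterious at this residue.
    tendencies
        A TendencyEstimate or a ContextClass → rate mapping; classes absent
        from the mapping (or NaN) contribute zero.
    codon_override
        A synonymous replacement codon substituted into the sequence before
        context extraction, so all three positions (and neighbors within
        2 nt) see the recoded contexts.
    """
    cds = genome.cds(gene)
    start = 3 * (codon_index - 1)
    if start + 3 > len(cds):
        raise DataError(f"codon {codon_index} outside CDS of {gene!r}")
    codon = cds[start: start + 3]
    aa = _translate(codon)
    if expect_aa is not None and aa != expect_aa:
        raise DataError(
            f"residue {codon_index} of {gene!r} is {aa}, expected {expect_aa}"
        )
    seq = cds
    if codon_override is not None:
        codon_override = codon_override.upper()
        if _translate(codon_override) != aa:
            raise DataError(
                f"override {codon_override!r} is not synonymous with {codon!r} ({aa})"
            )
        seq = cds[:start] + codon_override + cds[start + 3:]

    rates = _rates(tendencies)
    lof = set(lof_changes)
    total = 0.0
    current = seq[start: start + 3]
    for offset in range(3):
        pos0 = start + offset
        ref = seq[pos0]
        for alt in BASES:
            if alt == ref:
                continue
            new_codon = current[:offset] + alt + current[offset + 1:]
            alt_aa = _translate(new_codon)
            if alt_aa == aa or alt_aa not in lof:
                continue
            pent = _context_from_seq(genome, gene, seq, pos0)
            if pent is None:
                continue  # context-unavailable SNV contributes nothing
            r = rates.get(ContextClass(pent, alt), 0.0)
            if not math.isnan(r):
                total += r
    return total


def _all_changes(genome: CodingGenome, gene: str, codon_index: int) -> set[str]:
    """Every amino acid other than the residue's own (incl. stop): the
    default deleterious target set for neighbor-impact accounting."""
    cds = genome.cds(gene)
    start = 3 * (codon_index - 1)
    aa = _translate(cds[start: start + 3])
    return (set("ACDEFGHIKLMNPQRSTVWY*") - {aa})


@dataclass
class ShieldReport:
    """Effect of one synonymous candidate codon at a hotspot residue."""

    gene: str
    codon_index: int
    original_codon: str
    candidate_codon: str
    lof_changes: frozenset[str]
    baseline_sum: float  # T0
    candidate_sum: float  # T1
    fold_reduction: float  # T0/T1; inf when T1 == 0 (complete shielding)
    complete_shielding: bool
    neighbor_deltas: dict[int, float] = field(default_factory=dict)


def shield_report(
    genome: CodingGenome,
    gene: str,
    codon_index: int,
    lof_changes: Iterable[str],
    tendencies,
    neighbor_window: int = 2,
    include_self: bool = False,
    neighbor_lof_changes: Mapping[int, Iterable[str]] | None = None,
) -> list[ShieldReport]:
    """Rank synonymous recodings of a hotspot codon by LOF-rate reduction.

    For each candidate codon the LOF tendency sum is recomputed under the
    recoded sequence (T1) and compared with the original (T0); candidates
    are ranked by fold reduction F = T0/T1 descending, complete shielding
    (T1 = 0) first. Neighbor deltas report, for each residue within
    ``neighbor_window`` codons, the change in its own deleterious tendency
    sum caused by the recoding (the recoded codon only perturbs contexts
    within 2 nt, so residues two or more codons away are untouched).
    """
    cds = genome.cds(gene)
    start = 3 * (codon_index - 1)
    if start + 3 > len(cds):
        raise DataError(f"codon {codon_index} outside CDS of {gene!r}")
    original = cds[start: start + 3]
    lof = frozenset(lof_changes)
    n_codons = len(cds) // 3

    neighbors = [
        j for j in range(codon_index - neighbor_window, codon_index + neighbor_window + 1)
        if j != codon_index and 1 <= j <= n_codons
    ]

    def neighbor_set(j: int) -> set[str]:
        if neighbor_lof_changes and j in neighbor_lof_changes:
            return set(neighbor_lof_changes[j])
        return _all_changes(genome, gene, j)

    t0 = lof_tendency_sum(genome, gene, codon_index, lof, tendencies)
    baseline_neighbor = {
        j: lof_tendency_sum(genome, gene, j, neighbor_set(j), tendencies)
        for j in neighbors
    }

    candidates = sorted(synonymous_codons(original))
    if include_self:
        candidates = [original] + candidates

    reports = []
    for cand in candidates:
        t1 = lof_tendency_sum(genome, gene, codon_index, lof, tendencies, codon_override=cand)
        complete = t1 == 0.0 and t0 > 0.0
        fold = math.inf if complete else (t0 / t1 if t1 > 0 else math.nan)
        recoded_genome = CodingGenome(
            {**genome.cds_by_gene, gene: cds[:start] + cand + cds[start + 3:]},
            genome.flanks_by_gene,
        )
        deltas = {
            j: lof_tendency_sum(recoded_genome, gene, j, neighbor_set(j), tendencies)
            - baseline_neighbor[j]
            for j in neighbors
        }
        reports.append(
            ShieldReport(
                gene=gene,
                codon_index=codon_index,
                original_codon=original,
                candidate_codon=cand,
                lof_changes=lof,
                baseline_sum=t0,
                candidate_sum=t1,
                fold_reduction=fold,
                complete_shielding=complete,
                neighbor_deltas=deltas,
            )
        )
    reports.sort(
        key=lambda r: (-r.fold_reduction if not math.isnan(r.fold_reduction) else math.inf)
    )
    return reports


def write_shield_reports(reports: Sequence[ShieldReport], path: str | Path) -> None:
    """Tab-separated report: candidate, T0, T1, fold reduction, then one
    delta column per neighboring residue."""
    neighbor_cols: list[int] = sorted({j for r in reports for j in r.neighbor_deltas})
    with open(path, "w") as fh:
        header = ["gene", "codon_index", "original_codon", "candidate", "T0", "T1",
                  "fold_reduction", "complete_shielding"]
        header += [f"delta_residue_{j}" for j in neighbor_cols]
        fh.write("\t".join(header) + "\n")
        for r in reports:
            fold = "inf" if math.isinf(r.fold_reduction) else (
                "nan" if math.isnan(r.fold_reduction) else f"{r.fold_reduction:.6g}"
            )
            row = [r.gene, str(r.codon_index), r.original_codon, r.candidate_codon,
                   f"{r.baseline_sum:.6g}", f"{r.candidate_sum:.6g}", fold,
                   str(int(r.complete_shielding))]
            row += [f"{r.neighbor_deltas.get(j, 0.0):.6g}" for j in neighbor_cols]
            fh.write("\t".join(row) + "\n")
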