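"""Pentanucleotide context extraction and genome-wide context-site counting.

Every SNV is assigned to one of 12 × 4⁴ = 3072 context classes: the
substitution route at the center plus the two flanking bases on each side,
read from the coding strand. Reverse-complement collapsing is intentionally
not performed. Context-site denominators count only 5-mer windows that lie
fully inside a CDS; numerator contexts at CDS edges may additionally draw on
genomic flank sequence when available.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Iterable, Iterator, Mapping, NamedTuple

from .catalog_io import CodingGenome, MutationRecord
from .errors import DataError

BASES = "ACGT"
FLANK = 2  # bases on each side of the mutated position
PENTAMER_LEN = 2 * FLANK + 1
N_CLASSES = 12 * 4 ** (2 * FLANK)  # 3072

_VALID = frozenset(BASES)


class ContextClass(NamedTuple):
    """One of the 3072 (pentamer, alternate base) mutation classes."""

    pentamer: str
    alt: str

    @property
    def ref(self) -> str:
        return self.pentamer[FLANK]


def all_context_classes() -> Iterator[ContextClass]:
    """Iterate the full class space in lexicographic order (3072 classes)."""
    for flanks5 in product(BASES, repeat=2 * FLANK + 1):
        pent = "".join(flanks5)
        for alt in BASES:
            if alt != pent[FLANK]:
                yield ContextClass(pent, alt)


def extract_context(genome: CodingGenome, gene_id: str, cds_position: int) -> str | None:
    """Pentanucleotide context centered on a CDS site, or None when
    unavailable.

    Windows overrunning a CDS end are padded from the gene's genomic flanks
    when present; otherwise — and whenever the window contains a non-ACGT
    base — the site is context-unavailable.
    """
    cds = genome.cds(gene_id)
    L = len(cds)
    if not 1 <= cds_position <= L:
        raise DataError(
            f"cds_position {cds_position} outside CDS of {gene_id!r} (length {L})"
        )
    c = cds_position - 1
    left_need = max(0, FLANK - c)
    right_need = max(0, c + FLANK - (L - 1))
    left = right = ""
    if left_need or right_need:
        fl = genome.flanks(gene_id)
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
    pent = left + cds[max(0, c - FLANK): min(L, c + FLANK + 1)] + right
    if len(pent) != PENTAMER_LEN or set(pent) - _VALID:
        return None
    return pent


@dataclass
class ContextSiteTable:
    """Pentamer → number of sites per coding genome (the tendency
    denominator); windows containing non-ACGT bases are skipped and
    counted."""

    counts: dict[str, int]
    n_skipped: int = 0

    def __getitem__(self, pentamer: str) -> int:
        return self.counts.get(pentamer, 0)

    def total_windows(self) -> int:
        return sum(self.counts.values())

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("pentamer\tsites\n")
            for pent in sorted(self.counts):
                fh.write(f"{pent}\t{self.counts[pent]}\n")

    @classmethod
    def read(cls, path: str | Path) -> "ContextSiteTable":
        counts = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                counts[row["pentamer"]] = int(row["sites"])
        return cls(counts)


def count_context_sites(genome: CodingGenome) -> ContextSiteTable:
    """Count every overlapping 5-mer window fully inside each CDS."""
    counter: Counter[str] = Counter()
    skipped = 0
    for gene in genome.genes:
        seq = genome.cds(gene)
        for i in range(len(seq) - PENTAMER_LEN + 1):
            window = seq[i: i + PENTAMER_LEN]
            if set(window) - _VALID:
                skipped += 1
            else:
                counter[window] += 1
    return ContextSiteTable(dict(counter), n_skipped=skipped)


def classify_mutation(record: MutationRecord, genome: CodingGenome) -> ContextClass | None:
    """Assign an SNV record to its context class; None when the context is
    unavailable (window off-genome or containing ambiguous bases) or the
    record is an MNV."""
    if record.is_mnv:
        return None
    pent = extract_context(genome, record.gene_id, record.cds_position)
    if pent is None:
        return None
    ref = genome.cds(record.gene_id)[record.cds_position - 1]
    if ref != record.ref:
        raise DataError(
            f"reference mismatch at {record.gene_id}:{record.cds_position}: "
            f"catalog says {record.ref}, CDS has {ref}"
        )
    return ContextClass(pent, record.alt)


def collapse_to_trinucleotide(counts: Mapping, keyfunc=None) -> dict:
    """Aggregate pentamer-keyed counts down to the central trinucleotide.

    Works on pentamer→count mappings and on ContextClass→count mappings
    (yielding (trimer, alt) keys).
    """
    out: dict = {}
    for key, value in counts.items():
        if isinstance(key, ContextClass):
            new_key = (key.pentamer[FLANK - 1: FLANK + 2], key.alt)
        else:
            new_key = key[FLANK - 1: FLANK + 2]
        out[new_key] = out.get(new_key, 0) + value
    return out
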