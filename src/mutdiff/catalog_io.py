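"""Readers, writers, aggregation and recurrence filtering for coding-space
somatic mutation catalogs.

Coordinates throughout are 1-based positions on the coding strand of a CDS.
No strand collapsing is performed anywhere: C→T and G→A are distinct
substitution routes. Two catalog dialects are supported:

``generic``
    tab-separated columns ``gene, sample, cancer_type, cds_pos, ref, alt``;
    a multi-base ref/alt pair of equal length denotes a multi-nucleotide
    substitution (MNV).
``cosmic``
    tab-separated columns ``gene, sample, primary_site, hgvs_c`` where the
    last holds an HGVS-style CDS change such as ``c.215C>G`` or
    ``c.375_376CC>TT``. Insertions, deletions and duplications are skipped
    (their count is logged); unparseable strings are skipped and counted.
"""

from __future__ import annotations

import csv
import logging
import re
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

from .errors import DataError

log = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGT")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CodingGenome:
    """Per-gene coding sequences with optional genomic flanks.

    Parameters
    ----------
    cds_by_gene
        Mapping of gene id to its CDS nucleotide string (uppercase).
    flanks_by_gene
        Optional mapping of gene id to ``(upstream, downstream)`` genomic
        flank strings used for context extraction at CDS-edge sites.
    """

    cds_by_gene: Mapping[str, str]
    flanks_by_gene: Mapping[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, seq in self.cds_by_gene.items():
            if len(seq) < 1:
                raise DataError(f"empty CDS for gene {gene!r}")
        for gene, (up, down) in self.flanks_by_gene.items():
            if len(up) < 2 or len(down) < 2:
                raise DataError(f"flanks for gene {gene!r} must be >= 2 nt")

    @property
    def n_genes(self) -> int:
        return len(self.cds_by_gene)

    @property
    def genes(self) -> list[str]:
        return sorted(self.cds_by_gene)

    def cds(self, gene_id: str) -> str:
        try:
            return self.cds_by_gene[gene_id]
        except KeyError:
            raise DataError(f"unknown gene {gene_id!r}") from None

    def flanks(self, gene_id: str) -> tuple[str, str] | None:
        return self.flanks_by_gene.get(gene_id)


@dataclass(frozen=True)
class MutationRecord:
    """A single observed substitution call in one cancer sample.

    For SNVs ``ref``/``alt`` are single bases. For multi-nucleotide
    substitutions (``is_mnv=True``) they hold the full changed run and
    ``cds_position`` is the 1-based start of the run.
    """

    gene_id: str
    sample_id: str
    cancer_type: str
    cds_position: int
    ref: str
    alt: str
    is_mnv: bool = False

    def __post_init__(self) -> None:
        if self.cds_position < 1:
            raise DataError(f"cds_position must be >= 1, got {self.cds_position}")
        if not self.is_mnv:
            if len(self.ref) != 1 or len(self.alt) != 1:
                raise DataError("SNV record must carry single-base ref/alt")
            if self.ref == self.alt:
                raise DataError(f"ref == alt ({self.ref}) at {self.gene_id}:{self.cds_position}")
        else:
            if len(self.ref) != len(self.alt) or len(self.ref) < 2:
                raise DataError("MNV record must carry an equal-length run of >= 2 nt")


@dataclass
class MutationEvent:
    """A unique coding change with per-cancer-type distinct-sample counts.

    ``original_count`` is the number of distinct cancer samples carrying the
    change (samples are deduplicated before counting). ``mnv_support`` marks
    events whose protein change was also produced by at least one
    multi-nucleotide substitution in an additional sample.
    """

    gene_id: str
    cds_position: int
    ref: str
    alt: str
    per_type_counts: dict[str, int]
    mnv_support: bool = False

    @property
    def original_count(self) -> int:
        return sum(self.per_type_counts.values())

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.gene_id, self.cds_position, self.ref, self.alt)


# ---------------------------------------------------------------------------
# FASTA input
# ---------------------------------------------------------------------------


def read_cds_fasta(
    path: str | Path,
    canonical_list: Mapping[str, str] | None = None,
) -> CodingGenome:
    """Read one CDS per gene from a FASTA file.

    Record ids are either ``gene`` or ``gene|transcript``. When several
    records share a gene, the canonical list (gene → transcript id) decides
    which is kept; without one the longest CDS wins, ties broken by the
    lexicographically smallest record id.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise DataError(f"no FASTA records in {path}")
    seen_ids: set[str] = set()
    by_gene: dict[str, list[tuple[str, str, str]]] = defaultdict(list)
    for rec in records:
        if rec.id in seen_ids:
            raise DataError(f"duplicate FASTA record id {rec.id!r}")
        seen_ids.add(rec.id)
        gene, _, transcript = rec.id.partition("|")
        by_gene[gene].append((rec.id, transcript, str(rec.seq).upper()))

    cds: dict[str, str] = {}
    for gene, entries in by_gene.items():
        if canonical_list and gene in canonical_list:
            wanted = canonical_list[gene]
            matches = [e for e in entries if e[1] == wanted or e[0] == wanted]
            if not matches:
                raise DataError(
                    f"canonical transcript {wanted!r} for gene {gene!r} not in FASTA"
                )
            cds[gene] = matches[0][2]
        else:
            # longest CDS; tie -> smallest record id
            best = min(entries, key=lambda e: (-len(e[2]), e[0]))
            cds[gene] = best[2]
    return CodingGenome(cds)


def read_flanks_fasta(path: str | Path) -> dict[str, tuple[str, str]]:
    """Read genomic flank sequences from a FASTA with ids
    ``gene|upstream`` and ``gene|downstream``."""
    ups: dict[str, str] = {}
    downs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        gene, _, which = rec.id.partition("|")
        if which == "upstream":
            ups[gene] = str(rec.seq).upper()
        elif which == "downstream":
            downs[gene] = str(rec.seq).upper()
        else:
            raise DataError(f"flank record id {rec.id!r} must end in |upstream or |downstream")
    flanks = {}
    for gene in set(ups) | set(downs):
        flanks[gene] = (ups.get(gene, ""), downs.get(gene, ""))
    return flanks


def write_cds_fasta(genome: CodingGenome, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene in genome.genes:
            fh.write(f">{gene}\n{genome.cds(gene)}\n")


# ---------------------------------------------------------------------------
# Mutation table input
# ---------------------------------------------------------------------------

_HGVS_SNV = re.compile(r"^c\.(\d+)([ACGT])>([ACGT])$")
_HGVS_MNV = re.compile(r"^c\.(\d+)_(\d+)([ACGT]{2,})>([ACGT]{2,})$")
_HGVS_INDEL = re.compile(r"del|ins|dup")

_GENERIC_COLS = ("gene", "sample", "cancer_type", "cds_pos", "ref", "alt")
_COSMIC_COLS = ("gene", "sample", "primary_site", "hgvs_c")


def parse_hgvs_cds(hgvs: str) -> tuple[int, str, str, bool] | None:
    """Parse an HGVS-style CDS substitution string.

    Returns ``(position, ref, alt, is_mnv)`` for substitutions, ``None`` for
    anything else (indels, duplications, unparseable strings).
    """
    hgvs = hgvs.strip()
    m = _HGVS_SNV.match(hgvs)
    if m:
        return int(m.group(1)), m.group(2), m.group(3), False
    m = _HGVS_MNV.match(hgvs)
    if m:
        start, end = int(m.group(1)), int(m.group(2))
        ref, alt = m.group(3), m.group(4)
        if end - start + 1 != len(ref) or len(ref) != len(alt):
            return None
        return start, ref, alt, True
    return None


def read_mutation_table(path: str | Path, dialect: str = "generic") -> list[MutationRecord]:
    """Read a delimited somatic mutation catalog into records.

    SNVs become plain records, equal-length multi-base substitutions become
    ``is_mnv`` records; insertions/deletions and unparseable rows are skipped
    with logged counts.
    """
    if dialect not in ("generic", "cosmic"):
        raise DataError(f"unknown dialect {dialect!r}")
    required = _GENERIC_COLS if dialect == "generic" else _COSMIC_COLS

    records: list[MutationRecord] = []
    n_indel = n_bad = 0
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise DataError(f"empty mutation table {path}")
        missing = [c for c in required if c not in reader.fieldnames]
        if missing:
            raise DataError(f"mutation table missing mandatory column(s): {missing}")
        for row in reader:
            if dialect == "generic":
                ref, alt = row["ref"].upper(), row["alt"].upper()
                if not ref or not alt or set(ref + alt) - _VALID_BASES:
                    n_bad += 1
                    continue
                if len(ref) != len(alt):
                    n_indel += 1
                    continue
                records.append(
                    MutationRecord(
                        gene_id=row["gene"],
                        sample_id=row["sample"],
                        cancer_type=row["cancer_type"],
                        cds_position=int(row["cds_pos"]),
                        ref=ref,
                        alt=alt,
                        is_mnv=len(ref) > 1,
                    )
                )
            else:
                hgvs = row["hgvs_c"]
                parsed = parse_hgvs_cds(hgvs)
                if parsed is None:
                    if _HGVS_INDEL.search(hgvs):
                        n_indel += 1
                    else:
                        n_bad += 1
                    continue
                pos, ref, alt, is_mnv = parsed
                records.append(
                    MutationRecord(
                        gene_id=row["gene"],
                        sample_id=row["sample"],
                        cancer_type=row["primary_site"],
                        cds_position=pos,
                        ref=ref,
                        alt=alt,
                        is_mnv=is_mnv,
                    )
                )
    log.info(
        "read %d substitution records from %s (%d indel rows skipped, %d unparseable rows skipped)",
        len(records), path, n_indel, n_bad,
    )
    return records


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------


def _aa_changes(cds: str, pos: int, ref: str, alt: str) -> set[tuple[int, str, str]]:
    """Amino-acid changes (1-based residue, ref_aa, alt_aa) caused by a
    substitution run starting at 1-based CDS position `pos`."""
    i = pos - 1
    if i + len(ref) > len(cds) or cds[i : i + len(ref)] != ref:
        return set()
    mutated = cds[:i] + alt + cds[i + len(ref):]
    first_codon = i // 3
    last_codon = (i + len(ref) - 1) // 3
    changes = set()
    for c in range(first_codon, last_codon + 1):
        codon = cds[3 * c : 3 * c + 3]
        new = mutated[3 * c : 3 * c + 3]
        if len(codon) < 3:
            continue
        aa_ref = str(Seq(codon).translate())
        aa_alt = str(Seq(new).translate())
        if aa_ref != aa_alt:
            changes.add((c + 1, aa_ref, aa_alt))
    return changes


def aggregate_events(
    records: Iterable[MutationRecord],
    genome: CodingGenome | None = None,
) -> list[MutationEvent]:
    """Collapse records into unique events with distinct-sample counts.

    A sample contributes at most one count to an event regardless of how many
    times the identical call appears. When a genome is supplied, MNV records
    are translated and any SNV event producing the same amino-acid change in
    the same gene gets ``mnv_support`` set.
    """
    per_event_samples: dict[tuple, dict[str, set[str]]] = defaultdict(lambda: defaultdict(set))
    mnv_records: list[MutationRecord] = []
    for rec in records:
        if rec.is_mnv:
            mnv_records.append(rec)
            continue
        key = (rec.gene_id, rec.cds_position, rec.ref, rec.alt)
        per_event_samples[key][rec.cancer_type].add(rec.sample_id)

    events = []
    for key in sorted(per_event_samples):
        gene, pos, ref, alt = key
        counts = {t: len(s) for t, s in sorted(per_event_samples[key].items())}
        events.append(MutationEvent(gene, pos, ref, alt, counts))

    if genome is not None and mnv_records:
        mnv_changes: dict[str, set[tuple[int, str, str]]] = defaultdict(set)
        for rec in mnv_records:
            try:
                cds = genome.cds(rec.gene_id)
            except DataError:
                continue
            mnv_changes[rec.gene_id] |= _aa_changes(cds, rec.cds_position, rec.ref, rec.alt)
        for ev in events:
            if ev.gene_id not in mnv_changes:
                continue
            try:
                cds = genome.cds(ev.gene_id)
            except DataError:
                continue
            own = _aa_changes(cds, ev.cds_position, ev.ref, ev.alt)
            if own and own <= mnv_changes[ev.gene_id]:
                ev.mnv_support = True
    return events


def filter_recurrent(
    records: Sequence[MutationRecord],
    events: Iterable[MutationEvent],
    max_samples: int = 5,
) -> tuple[list[MutationRecord], float]:
    """Drop SNV records whose event recurs in more than ``max_samples``
    distinct samples.

    Returns the retained records together with the excluded fraction (over
    SNV records). Used only upstream of tendency estimation — assessment
    always sees the full catalog. MNV records pass through untouched (they
    never enter tendency estimation).
    """
    if max_samples < 1:
        raise DataError(f"max_samples must be >= 1, got {max_samples}")
    recurrent = {ev.key for ev in events if ev.original_count > max_samples}
    kept: list[MutationRecord] = []
    n_snv = n_dropped = 0
    for rec in records:
        if rec.is_mnv:
            kept.append(rec)
            continue
        n_snv += 1
        if (rec.gene_id, rec.cds_position, rec.ref, rec.alt) in recurrent:
            n_dropped += 1
        else:
            kept.append(rec)
    fraction = n_dropped / n_snv if n_snv else 0.0
    log.info(
        "recurrence filter (O > %d): excluded %d/%d SNV records (%.2f%%)",
        max_samples, n_dropped, n_snv, 100 * fraction,
    )
    return kept, fraction


# ---------------------------------------------------------------------------
# Event table round trip
# ---------------------------------------------------------------------------

_EVENT_COLS = ("gene_id", "cds_position", "ref", "alt", "original_count", "mnv_support", "per_type_counts")


def write_events(events: Iterable[MutationEvent], path: str | Path) -> None:
    """Write events as tab-separated text; per-type counts serialized as
    ``type:count`` pairs joined by ';'."""
    with open(path, "w") as fh:
        fh.write("\t".join(_EVENT_COLS) + "\n")
        for ev in events:
            per_type = ";".join(f"{t}:{c}" for t, c in sorted(ev.per_type_counts.items()))
            fh.write(
                f"{ev.gene_id}\t{ev.cds_position}\t{ev.ref}\t{ev.alt}\t"
                f"{ev.original_count}\t{int(ev.mnv_support)}\t{per_type}\n"
            )


def read_events(path: str | Path) -> list[MutationEvent]:
    events = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            per_type = {}
            if row["per_type_counts"]:
                for part in row["per_type_counts"].split(";"):
                    t, _, c = part.rpartition(":")
                    per_type[t] = int(c)
            ev = MutationEvent(
                gene_id=row["gene_id"],
                cds_position=int(row["cds_position"]),
                ref=row["ref"],
                alt=row["alt"],
                per_type_counts=per_type,
                mnv_support=bool(int(row["mnv_support"])),
            )
            if ev.original_count != int(row["original_count"]):
                raise DataError(f"inconsistent counts for event {ev.key}")
            events.append(ev)
    return events
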