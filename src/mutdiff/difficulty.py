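"""Per-class mutational tendency and relative difficulty estimation.

The mutational tendency of a class is its mutation count divided by the
number of available context sites per coding genome times the number of
genomes surveyed:

    r_c = n_c / (s_p × N)

The easiest pan-cancer class (maximum tendency) defines the reference rate
r₀ and difficulty 1; every class's relative difficulty is D_c = r₀ / r_c.
Cancer-type-specific tables reuse the *pan-cancer* reference rate, so a
per-type difficulty below 1 means the change is easier to generate in that
cancer type than the pan-cancer reference — difficulties are directly
comparable across types.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .catalog_io import CodingGenome, MutationRecord
from .context import ContextClass, ContextSiteTable, all_context_classes, classify_mutation, count_context_sites
from .errors import DataError

log = logging.getLogger(__name__)

PAN_CANCER = "pan-cancer"


def mutation_rate(n_mutations: int, sites_per_genome: int, n_genomes: int) -> float:
    """Class tendency r = n / (s × N); the core rate quotient."""
    if n_genomes <= 0:
        raise DataError(f"number of genomes must be positive, got {n_genomes}")
    if sites_per_genome <= 0:
        raise DataError(f"sites_per_genome must be positive, got {sites_per_genome}")
    return n_mutations / (sites_per_genome * n_genomes)


@dataclass
class TendencyEstimate:
    """Estimated per-class rates for one scope (pan-cancer or one type).

    ``rates`` covers all 3072 classes; classes whose pentamer never occurs in
    the coding genome (s_p = 0) are listed in ``undefined`` and carry NaN.
    """

    scope: str
    n_genomes: int
    counts: dict[ContextClass, int]
    sites: ContextSiteTable
    rates: dict[ContextClass, float]
    undefined: set[ContextClass] = field(default_factory=set)
    n_unclassified: int = 0


def estimate_tendencies(
    filtered_records: Iterable[MutationRecord],
    genome: CodingGenome,
    n_genomes: int,
    site_table: ContextSiteTable | None = None,
    scope: str = PAN_CANCER,
) -> TendencyEstimate:
    """Estimate r_c = n_c / (s_p × N) for every context class.

    Records should already have passed the recurrence filter when the goal is
    a background (selection-free) tendency. MNV and context-unavailable
    records are excluded and counted.
    """
    if n_genomes <= 0:
        raise DataError(f"n_genomes must be positive, got {n_genomes}")
    if site_table is None:
        site_table = count_context_sites(genome)

    counts: dict[ContextClass, int] = {}
    n_unclassified = 0
    for rec in filtered_records:
        cls = classify_mutation(rec, genome)
        if cls is None:
            n_unclassified += 1
            continue
        counts[cls] = counts.get(cls, 0) + 1

    rates: dict[ContextClass, float] = {}
    undefined: set[ContextClass] = set()
    for cls in all_context_classes():
        s_p = site_table[cls.pentamer]
        if s_p == 0:
            rates[cls] = math.nan
            undefined.add(cls)
        else:
            rates[cls] = counts.get(cls, 0) / (s_p * n_genomes)
    if undefined:
        log.info("%s: %d classes undefined (pentamer absent from coding genome)",
                 scope, len(undefined))
    return TendencyEstimate(
        scope=scope,
        n_genomes=n_genomes,
        counts=counts,
        sites=site_table,
        rates=rates,
        undefined=undefined,
        n_unclassified=n_unclassified,
    )


@dataclass(frozen=True)
class ClassDifficulty:
    count: int
    sites_per_genome: int
    tendency: float
    difficulty: float  # NaN when undefined
    undefined: bool = False


@dataclass
class DifficultyTable:
    """Relative difficulty D_c = r₀ / r_c for every class, for one scope."""

    scope: str
    n_genomes: int
    reference_rate: float
    classes: dict[ContextClass, ClassDifficulty]

    def difficulty(self, pentamer: str, alt: str) -> float:
        """Look up D for a class; raises on undefined classes with a hint to
        re-run under the pseudocount policy."""
        cls = ContextClass(pentamer, alt)
        try:
            entry = self.classes[cls]
        except KeyError:
            raise DataError(f"unknown context class {cls}") from None
        if entry.undefined:
            raise DataError(
                f"difficulty undefined for class {cls} in scope {self.scope!r} "
                "(zero observations or zero sites); rebuild the table with "
                "zero_policy='pseudocount' to score it"
            )
        return entry.difficulty

    def tendency(self, pentamer: str, alt: str) -> float:
        return self.classes[ContextClass(pentamer, alt)].tendency

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cls in sorted(self.classes):
            e = self.classes[cls]
            rows.append(
                {
                    "scope": self.scope,
                    "pentamer": cls.pentamer,
                    "alt": cls.alt,
                    "count": e.count,
                    "sites_per_genome": e.sites_per_genome,
                    "tendency": e.tendency,
                    "difficulty": e.difficulty,
                    "flags": "undefined" if e.undefined else "",
                }
            )
        return pd.DataFrame(rows)

    def write(self, path: str | Path) -> None:
        df = self.to_frame()
        with open(path, "w") as fh:
            fh.write(f"# n_genomes={self.n_genomes}\treference_rate={self.reference_rate!r}\n")
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "DifficultyTable":
        with open(path) as fh:
            header = fh.readline().strip().lstrip("# ")
            meta = dict(item.split("=", 1) for item in header.split("\t"))
            df = pd.read_csv(fh, sep="\t", keep_default_na=False,
                             dtype={"flags": str})
        classes = {}
        scope = PAN_CANCER
        for row in df.itertuples(index=False):
            scope = row.scope
            classes[ContextClass(row.pentamer, row.alt)] = ClassDifficulty(
                count=int(row.count),
                sites_per_genome=int(row.sites_per_genome),
                tendency=float(row.tendency) if row.tendency != "" else math.nan,
                difficulty=float(row.difficulty) if row.difficulty != "" else math.nan,
                undefined=row.flags == "undefined",
            )
        return cls(
            scope=scope,
            n_genomes=int(meta["n_genomes"]),
            reference_rate=float(meta["reference_rate"]),
            classes=classes,
        )


def build_difficulty(
    tendencies: TendencyEstimate,
    reference_rate: float | None = None,
    zero_policy: str = "undefined",
    pseudocount: float = 0.5,
) -> DifficultyTable:
    """Convert tendencies into relative difficulties D_c = r₀ / r_c.

    Parameters
    ----------
    reference_rate
        r₀; defaults to the maximum tendency in this estimate (the easiest
        class, which then has difficulty exactly 1).
    zero_policy
        "undefined" flags zero-count classes (lookups raise); "pseudocount"
        recomputes their rate with n_c + pseudocount so every class with
        sites gets a finite difficulty.
    """
    if zero_policy not in ("undefined", "pseudocount"):
        raise DataError(f"unknown zero_policy {zero_policy!r}")
    finite = [r for r in tendencies.rates.values() if not math.isnan(r)]
    if reference_rate is None:
        reference_rate = max(finite, default=0.0)
    if reference_rate <= 0:
        raise DataError(f"reference_rate must be positive, got {reference_rate}")

    classes: dict[ContextClass, ClassDifficulty] = {}
    for cls, rate in tendencies.rates.items():
        s_p = tendencies.sites[cls.pentamer]
        n_c = tendencies.counts.get(cls, 0)
        if math.isnan(rate):  # no sites in the coding genome
            classes[cls] = ClassDifficulty(n_c, s_p, math.nan, math.nan, undefined=True)
        elif n_c == 0:
            if zero_policy == "pseudocount":
                r = (n_c + pseudocount) / (s_p * tendencies.n_genomes)
                classes[cls] = ClassDifficulty(n_c, s_p, r, reference_rate / r)
            else:
                classes[cls] = ClassDifficulty(n_c, s_p, 0.0, math.nan, undefined=True)
        else:
            classes[cls] = ClassDifficulty(n_c, s_p, rate, reference_rate / rate)
    return DifficultyTable(
        scope=tendencies.scope,
        n_genomes=tendencies.n_genomes,
        reference_rate=reference_rate,
        classes=classes,
    )


def cancer_type_difficulty(
    records_by_type: Mapping[str, Sequence[MutationRecord]],
    genome: CodingGenome,
    samples_per_type: Mapping[str, int],
    pan_reference_rate: float,
    min_samples: int = 100,
    pan_table: DifficultyTable | None = None,
    site_table: ContextSiteTable | None = None,
    zero_policy: str = "undefined",
    pseudocount: float = 0.5,
) -> dict[str, DifficultyTable]:
    """Per-cancer-type difficulty tables sharing the pan-cancer reference.

    Each type's tendencies use that type's genome count N_t; difficulty is
    pan_reference_rate / r_{c,t}, so values below 1 mean easier than the
    pan-cancer reference. Types with fewer than ``min_samples`` samples fall
    back to the supplied pan-cancer table (logged).
    """
    if site_table is None:
        site_table = count_context_sites(genome)
    tables: dict[str, DifficultyTable] = {}
    for ctype, records in records_by_type.items():
        if ctype not in samples_per_type:
            raise DataError(f"unknown cancer type label {ctype!r} (no sample count)")
        n_t = samples_per_type[ctype]
        if n_t < min_samples:
            if pan_table is None:
                raise DataError(
                    f"cancer type {ctype!r} has {n_t} samples (< {min_samples}) "
                    "and no pan-cancer table was supplied for fallback"
                )
            log.info("cancer type %s: %d samples < %d, falling back to pan-cancer table",
                     ctype, n_t, min_samples)
            tables[ctype] = pan_table
            continue
        est = estimate_tendencies(records, genome, n_t, site_table=site_table, scope=ctype)
        tables[ctype] = build_difficulty(
            est,
            reference_rate=pan_reference_rate,
            zero_policy=zero_policy,
            pseudocount=pseudocount,
        )
    return tables
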