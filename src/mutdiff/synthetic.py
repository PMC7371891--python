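"""Synthetic coding genomes and multi-cancer-type mutation catalogs with
known class-specific rates.

The generator emulates the statistical structure the estimation pipeline
assumes: every classifiable site mutates independently per sample with a
probability set by its context class and the sample's cancer-type burden
multiplier, and named driver events are additionally spiked in with a
per-sample enrichment probability (so the recurrence filter has something
real to remove). Defaults describe a desk-scale study: a 30-kb coding
genome (10 genes × 3 kb), two cancer types of 100 samples each with burden
multipliers 1 and 3, a baseline class rate of 2 × 10⁻⁴ per site per sample,
and a 10× multiplier for C→T classes (the transition that dominates real
catalogs via CpG deamination).

Randomness is split into independent streams (genome, catalog, MNV
injection) via ``numpy.random.SeedSequence.spawn``, so the genome is
reproducible independently of the catalog drawn on top of it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .catalog_io import CodingGenome, MutationRecord
from .context import BASES, ContextClass, extract_context
from .errors import DataError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CancerTypeSpec:
    n_samples: int
    burden: float = 1.0  # multiplies every class rate for this type


@dataclass(frozen=True)
class DriverSpec:
    """A selectively enriched event: present in each sample of every cancer
    type independently with probability ``enrichment``."""

    gene: str
    cds_position: int
    alt: str
    enrichment: float


def default_class_rate(pentamer: str, alt: str,
                       base_rate: float = 2e-4,
                       hot_multiplier: float = 10.0) -> float:
    """Two-tier rate rule: C→T classes run ``hot_multiplier`` times hotter
    than everything else."""
    ref = pentamer[2]
    return base_rate * (hot_multiplier if (ref, alt) == ("C", "T") else 1.0)


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic dataset (fixed by ``seed``)."""

    n_genes: int = 10
    gene_lengths: Sequence[int] | int = 3000  # nt, each a multiple of 3
    gc_content: float = 0.41
    base_rate: float = 2e-4
    hot_multiplier: float = 10.0
    class_rates: Mapping[ContextClass, float] | None = None  # overrides the rule
    cancer_types: Mapping[str, CancerTypeSpec] = field(
        default_factory=lambda: {
            "carcinoma_a": CancerTypeSpec(n_samples=100, burden=1.0),
            "carcinoma_b": CancerTypeSpec(n_samples=100, burden=3.0),
        }
    )
    drivers: Sequence[DriverSpec] = ()
    seed: int = 0

    def rate(self, pentamer: str, alt: str) -> float:
        """True per-site per-sample rate for a class (before burden)."""
        if self.class_rates is not None:
            return self.class_rates.get(ContextClass(pentamer, alt), 0.0)
        return default_class_rate(pentamer, alt, self.base_rate, self.hot_multiplier)

    def lengths(self) -> list[int]:
        if isinstance(self.gene_lengths, int):
            ls = [self.gene_lengths] * self.n_genes
        else:
            ls = list(self.gene_lengths)
            if len(ls) != self.n_genes:
                raise DataError("gene_lengths must match n_genes")
        for L in ls:
            if L < 3 or L % 3:
                raise DataError(f"gene length {L} is not a positive multiple of 3")
        return ls

    def _streams(self) -> list[np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(3)
        return [np.random.default_rng(c) for c in children]


def make_genome(spec: SyntheticSpec) -> CodingGenome:
    """Draw a coding genome: i.i.d. bases at the requested GC content,
    gene lengths multiples of 3, no ambiguous bases. Fully reproducible
    from the spec's seed."""
    if spec.n_genes < 1:
        raise DataError("need at least one gene")
    if not 0.0 <= spec.gc_content <= 1.0:
        raise DataError(f"gc_content must be in [0, 1], got {spec.gc_content}")
    rng = spec._streams()[0]
    p_at = (1.0 - spec.gc_content) / 2.0
    p_gc = spec.gc_content / 2.0
    probs = [p_at, p_gc, p_gc, p_at]  # A C G T
    cds = {}
    for i, L in enumerate(spec.lengths()):
        seq = rng.choice(list(BASES), size=L, p=probs)
        cds[f"gene{i + 1:03d}"] = "".join(seq)
    return CodingGenome(cds)


def simulate_catalog(spec: SyntheticSpec, genome: CodingGenome) -> list[MutationRecord]:
    """Draw a mutation catalog over a genome generated from the same spec.

    Per-site Bernoulli model: for each sample, each classifiable site
    mutates to alternate base a with probability rate(class) × burden,
    independently across sites and samples (at most one call per
    site/alt/sample). Driver events are layered on with their own
    per-sample enrichment probability. Expected count of class c is
    ≈ r_c × s_p × Σ_t N_t × m_t.
    """
    rng = spec._streams()[1]

    # enumerate classifiable sites once: (gene, pos, ref, alt, base probability)
    sites: list[tuple[str, int, str, str, float]] = []
    for gene in genome.genes:
        seq = genome.cds(gene)
        for pos in range(1, len(seq) + 1):
            pent = extract_context(genome, gene, pos)
            if pent is None:
                continue
            ref = seq[pos - 1]
            for alt in BASES:
                if alt == ref:
                    continue
                r = spec.rate(pent, alt)
                if r > 0:
                    sites.append((gene, pos, ref, alt, r))

    records: list[MutationRecord] = []
    seen: set[tuple[str, str, int, str]] = set()  # (sample, gene, pos, alt)

    base_p = np.array([s[4] for s in sites])
    for ctype in sorted(spec.cancer_types):
        cts = spec.cancer_types[ctype]
        p = base_p * cts.burden
        if np.any(p > 1.0):
            raise DataError(
                f"cancer type {ctype!r}: burden {cts.burden} pushes a class "
                "probability above 1"
            )
        hits = rng.binomial(cts.n_samples, p)
        for idx in np.nonzero(hits)[0]:
            gene, pos, ref, alt, _ = sites[idx]
            chosen = rng.choice(cts.n_samples, size=hits[idx], replace=False)
            for s in chosen:
                sample = f"{ctype}_s{s + 1:04d}"
                key = (sample, gene, pos, alt)
                if key in seen:
                    continue
                seen.add(key)
                records.append(MutationRecord(gene, sample, ctype, pos, ref, alt))

        for drv in spec.drivers:
            if not 0.0 <= drv.enrichment <= 1.0:
                raise DataError(f"driver enrichment must be a probability: {drv}")
            ref = genome.cds(drv.gene)[drv.cds_position - 1]
            if ref == drv.alt:
                raise DataError(f"driver alt equals reference base: {drv}")
            carriers = np.nonzero(rng.random(cts.n_samples) < drv.enrichment)[0]
            for s in carriers:
                sample = f"{ctype}_s{s + 1:04d}"
                key = (sample, drv.gene, drv.cds_position, drv.alt)
                if key in seen:
                    continue
                seen.add(key)
                records.append(
                    MutationRecord(drv.gene, sample, ctype, drv.cds_position, ref, drv.alt)
                )
    records.sort(key=lambda r: (r.gene_id, r.cds_position, r.alt, r.cancer_type, r.sample_id))
    log.info("simulated %d SNV records over %d classifiable site/alt pairs",
             len(records), len(sites))
    return records


def inject_mnv(
    records: list[MutationRecord],
    genome: CodingGenome,
    gene: str,
    cds_position: int,
    ref_run: str,
    alt_run: str,
    cancer_type: str,
    sample_id: str = "mnv_sample_0001",
) -> list[MutationRecord]:
    """Append a single fixed multi-nucleotide substitution record (for
    exercising the unscored `*` rule downstream)."""
    cds = genome.cds(gene)
    if cds[cds_position - 1: cds_position - 1 + len(ref_run)] != ref_run:
        raise DataError("MNV ref run does not match the genome")
    return records + [
        MutationRecord(gene, sample_id, cancer_type, cds_position, ref_run, alt_run, is_mnv=True)
    ]


def write_catalog(records: Sequence[MutationRecord], path) -> None:
    """Write records in the generic tab-separated dialect read by
    catalog_io.read_mutation_table."""
    with open(path, "w") as fh:
        fh.write("gene\tsample\tcancer_type\tcds_pos\tref\talt\n")
        for r in records:
            fh.write(f"{r.gene_id}\t{r.sample_id}\t{r.cancer_type}\t{r.cds_position}\t{r.ref}\t{r.alt}\n")


def samples_per_type(spec: SyntheticSpec) -> dict[str, int]:
    return {t: c.n_samples for t, c in spec.cancer_types.items()}
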