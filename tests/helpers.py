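"""Shared construction helpers for the test suite."""

import math

from mutdiff import CodingGenome, build_difficulty, count_context_sites
from mutdiff.context import all_context_classes
from mutdiff.difficulty import TendencyEstimate


def make_estimate(counts, sites, n_genomes=1, scope="pan-cancer"):
    """Assemble a TendencyEstimate directly from per-class counts and
    per-pentamer site numbers (hand-computed quotient oracle)."""
    site_table = count_context_sites(CodingGenome({"g": "AAAAA"}))  # placeholder
    site_table.counts = dict(sites)
    rates = {}
    undefined = set()
    for cls in all_context_classes():
        s = sites.get(cls.pentamer, 0)
        if s == 0:
            rates[cls] = math.nan
            undefined.add(cls)
        else:
            rates[cls] = counts.get(cls, 0) / (s * n_genomes)
    return TendencyEstimate(
        scope=scope,
        n_genomes=n_genomes,
        counts=dict(counts),
        sites=site_table,
        rates=rates,
        undefined=undefined,
    )


def uniform_table(genome, difficulty_value=1.0):
    """Difficulty table where every class present in the genome has the
    same difficulty."""
    sites = count_context_sites(genome)
    counts = {
        cls: sites[cls.pentamer]
        for cls in all_context_classes()
        if sites[cls.pentamer] > 0
    }
    est = make_estimate(counts, dict(sites.counts))
    # every defined class has rate 1; scale the reference to set D uniformly
    return build_difficulty(est, reference_rate=float(difficulty_value))
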