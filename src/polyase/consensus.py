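"""Per-position consensus calling for a parental strain.

Mirrors the conservative VarScan-style ``mpileup2cns`` thresholds used to
genotype the parental RNA-seq samples: a site needs 15x overall coverage to
be considered at all, reads need base quality >= 25 to count, and a variant
is only believed when it is supported by >= 20% of the qualifying reads, by
at least 5 reads, at Fisher's-exact p < 0.01, and by both strands. Calls are
emitted as IUPAC ambiguity codes ('N' when a site cannot be trusted).
"""

from __future__ import annotations

import dataclasses
from functools import lru_cache
from typing import Dict, Iterable, Iterator, Mapping

from scipy import stats

from .formats import PileupColumn

__all__ = [
    "Thresholds",
    "BaseCounts",
    "ConsensusCall",
    "IUPAC_CODES",
    "IUPAC_EXPAND",
    "LOW_COVERAGE",
    "STRAND_FAIL",
    "INSIGNIFICANT",
    "tally_bases",
    "variant_significance",
    "strand_check",
    "call_consensus",
    "call_column",
    "call_pileup",
]

LOW_COVERAGE = "LOW_COVERAGE"
STRAND_FAIL = "STRAND_FAIL"
INSIGNIFICANT = "INSIGNIFICANT"

_NUCS = "ACGT"

# Unambiguous-base sets -> IUPAC code, and the reverse expansion.
IUPAC_CODES: Dict[frozenset, str] = {
    frozenset(s): code
    for code, s in {
        "A": "A", "C": "C", "G": "G", "T": "T",
        "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
        "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
    }.items()
}
IUPAC_EXPAND: Dict[str, frozenset] = {code: s for s, code in IUPAC_CODES.items()}


@dataclasses.dataclass
class Thresholds:
    """Consensus-calling thresholds (VarScan-style defaults).

    ``>=`` comparisons are inclusive for coverage, frequency and read
    support; the p-value cut is strict (< 0.01). ``hom_frequency`` is the
    variant frequency at and above which a variant site is called
    homozygous for the variant base rather than heterozygous.
    """

    min_coverage: int = 15
    min_base_quality: int = 25
    min_var_frequency: float = 0.20
    min_var_reads: int = 5
    max_p: float = 0.01
    hom_frequency: float = 0.75
    strand_min_fraction: float = 0.10


DEFAULT_THRESHOLDS = Thresholds()


@dataclasses.dataclass
class BaseCounts:
    """Quality-filtered per-base, per-strand tallies at one position.

    ``total_depth`` is the full pileup depth, including observations that
    were dropped for low base quality or were ``*`` placeholders, so
    ``total_depth >= sum(plus.values()) + sum(minus.values())``.
    """

    plus: Dict[str, int]
    minus: Dict[str, int]
    mean_quality: Dict[str, float]
    total_depth: int

    def count(self, base: str) -> int:
        return self.plus.get(base, 0) + self.minus.get(base, 0)

    @property
    def qualified_depth(self) -> int:
        return sum(self.plus.values()) + sum(self.minus.values())


def tally_bases(column: PileupColumn, min_base_quality: int = 25) -> BaseCounts:
    """Tally A/C/G/T observations at or above ``min_base_quality``.

    Low-quality observations and ``*``/'N' placeholders stay in
    ``total_depth`` but are excluded from the per-base counts.
    """
    bases, quals = column.bases, column.quals
    total = len(bases)
    if total == 0:
        zero = {b: 0 for b in _NUCS}
        return BaseCounts(dict(zero), dict(zero), {b: 0.0 for b in _NUCS}, 0)
    cutoff = chr(min_base_quality + 33)
    qmin, qmax = min(quals), max(quals)
    if qmin >= cutoff and qmin == qmax:
        # Uniform passing quality: count at C speed.
        q = ord(qmin) - 33
        plus = {b: bases.count(b) for b in _NUCS}
        minus = {b: bases.count(b.lower()) for b in _NUCS}
        mean_q = {b: (float(q) if plus[b] + minus[b] else 0.0) for b in _NUCS}
        return BaseCounts(plus, minus, mean_q, total)
    plus = {b: 0 for b in _NUCS}
    minus = {b: 0 for b in _NUCS}
    qsum = {b: 0 for b in _NUCS}
    for b, qc in zip(bases, quals):
        q = ord(qc) - 33
        if q < min_base_quality:
            continue
        upper = b.upper()
        if upper not in plus:  # '*' or 'N'
            continue
        if b.isupper():
            plus[upper] += 1
        else:
            minus[upper] += 1
        qsum[upper] += q
    mean_q = {
        b: (qsum[b] / (plus[b] + minus[b]) if plus[b] + minus[b] else 0.0)
        for b in _NUCS
    }
    return BaseCounts(plus, minus, mean_q, total)


@lru_cache(maxsize=65536)
def variant_significance(ref_reads: int, var_reads: int) -> float:
    """One-sided Fisher's exact p-value for the variant call.

    The observed (ref, var) split is compared against the all-reference
    expectation with the same read total, i.e. the 2x2 table
    ``[[ref, var], [ref + var, 0]]``; smaller p means stronger variant
    evidence. Returns 1.0 when there is no variant evidence at all.
    """
    if ref_reads < 0 or var_reads < 0:
        raise ValueError("read counts must be non-negative")
    if var_reads == 0:
        return 1.0
    table = [[ref_reads, var_reads], [ref_reads + var_reads, 0]]
    return float(stats.fisher_exact(table, alternative="less").pvalue)


def strand_check(var_plus: int, var_minus: int, min_fraction: float = 0.10) -> bool:
    """Both-strand support filter for variant reads.

    Passes iff each strand carries at least one variant read and the
    minority strand carries at least ``min_fraction`` (inclusive) of them.
    Guards against strand-biased artifacts such as PCR over-amplification.
    """
    if var_plus < 0 or var_minus < 0:
        raise ValueError("strand counts must be non-negative")
    total = var_plus + var_minus
    if total == 0 or var_plus == 0 or var_minus == 0:
        return False
    return min(var_plus, var_minus) / total >= min_fraction


@dataclasses.dataclass
class ConsensusCall:
    """The consensus genotype at one position of one strain."""

    iupac: str
    variant_frequency: float
    p_value: float
    depth: int
    flags: frozenset = frozenset()


def call_consensus(
    counts: BaseCounts,
    ref_base: str,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> ConsensusCall:
    """Apply the six threshold rules to base tallies at one position.

    Decision order: insufficient coverage -> 'N'/LOW_COVERAGE; the single
    most frequent non-reference base (ties broken alphabetically) is the
    only variant candidate; a candidate reaching the frequency and
    min-read gates but failing significance or the strand filter taints
    the site ('N' with INSIGNIFICANT / STRAND_FAIL); a candidate passing
    everything is called homozygous (frequency >= ``hom_frequency``) or as
    the heterozygous IUPAC code of {reference, variant}; anything else is
    homozygous reference.
    """
    t = thresholds
    ref = ref_base.upper()
    if ref not in _NUCS:
        raise ValueError(f"unknown reference base {ref_base!r}")
    depth = counts.total_depth
    if depth < t.min_coverage or counts.qualified_depth == 0:
        return ConsensusCall("N", 0.0, 1.0, depth, frozenset({LOW_COVERAGE}))

    candidate = min(
        (b for b in _NUCS if b != ref),
        key=lambda b: (-counts.count(b), b),
    )
    var_n = counts.count(candidate)
    freq = var_n / counts.qualified_depth
    if var_n >= t.min_var_reads and freq >= t.min_var_frequency:
        p = variant_significance(counts.count(ref), var_n)
        if not p < t.max_p:
            return ConsensusCall("N", freq, p, depth, frozenset({INSIGNIFICANT}))
        if not strand_check(
            counts.plus[candidate], counts.minus[candidate], t.strand_min_fraction
        ):
            return ConsensusCall("N", freq, p, depth, frozenset({STRAND_FAIL}))
        if freq >= t.hom_frequency:
            return ConsensusCall(candidate, freq, p, depth, frozenset())
        return ConsensusCall(IUPAC_CODES[frozenset({ref, candidate})], freq, p, depth, frozenset())
    return ConsensusCall(ref, freq, 1.0, depth, frozenset())


def call_column(
    column: PileupColumn, thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> ConsensusCall:
    """Tally and call one parsed pileup column."""
    counts = tally_bases(column, thresholds.min_base_quality)
    return call_consensus(counts, column.ref_base, thresholds)


def call_pileup(
    columns: Iterable[PileupColumn], thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> Iterator[tuple[PileupColumn, ConsensusCall]]:
    """Stream (column, call) pairs over a whole pileup."""
    for column in columns:
        yield column, call_consensus(
            tally_bases(column, thresholds.min_base_quality),
            column.ref_base,
            thresholds,
        )
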