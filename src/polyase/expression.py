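"""Transcript expression and allele-specific expression (ASE) values.

Whole-transcript expression is the geometric mean of per-position coverage
depth over the covered positions (depth >= 1), a measure that is largely
insensitive to transcript length and to local coverage spikes. Samples are
made comparable with DESeq-style median-of-ratios size factors computed on
those geometric means. At each dSNP the fraction of covering reads that
carry the discriminating base, multiplied by the transcript's (normalized)
geometric-mean depth, gives a fractional expression value; averaging the
strictly positive fractional values over a strain's dSNPs in a transcript
yields that allele's ASE value.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dsnp import Dsnp

__all__ = [
    "CoverageTrack",
    "DsnpObservation",
    "AseRecord",
    "geometric_mean_depth",
    "size_factors",
    "fractional_expression",
    "ase_values",
    "compare_expression_measures",
]


@dataclasses.dataclass
class CoverageTrack:
    """Per-position coverage depth of one transcript in one sample."""

    transcript_id: str
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth)
        if (self.depth < 0).any():
            raise ValueError("coverage depths must be non-negative")

    @property
    def covered_length(self) -> int:
        return int((self.depth >= 1).sum())


def geometric_mean_depth(track: "CoverageTrack | Sequence[int]") -> float:
    """Geometric mean of depth over covered positions, in log space.

    Positions with zero depth are excluded; a transcript with no covered
    position has expression 0.
    """
    depth = track.depth if isinstance(track, CoverageTrack) else np.asarray(track)
    covered = depth[depth >= 1].astype(float)
    if covered.size == 0:
        return 0.0
    return float(np.exp(np.log(covered).mean()))


def size_factors(g_matrix: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors from a transcripts x samples matrix.

    Each transcript's representative expression is the geometric mean of
    its values across samples; a sample's factor is the median over
    transcripts of (value / representative). Transcripts with a zero in any
    sample are excluded from the factor computation (their log is
    undefined), exactly as DESeq excludes zero-count genes.
    """
    if g_matrix.shape[1] < 1:
        raise ValueError("size factors need at least one sample")
    positive = g_matrix[(g_matrix > 0).all(axis=1)]
    if positive.empty:
        raise ValueError(
            "size factors undefined: no transcript has positive expression in every sample"
        )
    log_g = np.log(positive.astype(float))
    log_ratios = log_g.sub(log_g.mean(axis=1), axis=0)
    return np.exp(log_ratios.median(axis=0))


@dataclasses.dataclass
class DsnpObservation:
    """Read support at one dSNP position in one (triploid) sample.

    ``n`` is the number of reads covering the position, ``n_s`` the number
    carrying the discriminating base. Reads carrying any other base stay in
    the denominator only, so sequencing errors dilute rather than credit
    the allele.
    """

    dsnp: Dsnp
    n: int
    n_s: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_s <= self.n:
            raise ValueError(f"need 0 <= n_s <= n, got n_s={self.n_s}, n={self.n}")


def fractional_expression(g: float, obs: "DsnpObservation | tuple") -> float:
    """Allele expression at one dSNP: G * n_s / n (0 when uncovered)."""
    if g < 0:
        raise ValueError("expression must be non-negative")
    n, n_s = (obs.n, obs.n_s) if isinstance(obs, DsnpObservation) else obs
    if n == 0:
        return 0.0
    return g * n_s / n


@dataclasses.dataclass
class AseRecord:
    """Per-strain ASE values for one transcript; whole-gene = their sum."""

    transcript_id: str
    values: Dict[str, float]

    @property
    def whole_gene_expression(self) -> float:
        return float(sum(self.values.values()))


def ase_values(
    transcript_id: str, fractional: Mapping[str, Sequence[float]]
) -> AseRecord:
    """Average each strain's fractional expression values into one ASE value.

    Only strictly positive values enter the average; if every value for a
    strain is zero, zero is the reported ASE. A strain with no dSNP
    observations at all is an upstream filtering error.
    """
    values: Dict[str, float] = {}
    for strain, vals in fractional.items():
        vals = list(vals)
        if not vals:
            raise ValueError(
                f"strain {strain} has no dSNP observations in {transcript_id}; "
                "transcript should have been filtered as dSNP-incomplete"
            )
        if any(v < 0 for v in vals):
            raise ValueError("fractional expression values must be non-negative")
        positive = [v for v in vals if v > 0]
        values[strain] = float(np.mean(positive)) if positive else 0.0
    return AseRecord(transcript_id, values)


def compare_expression_measures(
    g_values: Sequence[float], fragment_counts: Sequence[float]
) -> float:
    """Spearman rank correlation between two expression measures.

    Used to compare geometric-mean-depth expression against plain fragment
    counting; average ranks are assigned to ties.
    """
    if len(g_values) != len(fragment_counts):
        raise ValueError("paired vectors must have equal length")
    if len(g_values) < 2:
        raise ValueError("Spearman correlation needs at least two pairs")
    return float(stats.spearmanr(g_values, fragment_counts).statistic)
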