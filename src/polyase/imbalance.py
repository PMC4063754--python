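"""Allele-imbalance classification of per-transcript ASE values.

For a transcript with one ASE value per allele, three summaries are made:

* a chi-square goodness-of-fit test of the null that all alleles express
  equally (expected value = total / ploidy, df = ploidy - 1);
* the coefficient of variation c_v = sample standard deviation / mean of
  the ASE values, a normalized dispersion measure bounded by sqrt(3) for
  three alleles. c_v = sqrt(3)/2 ~ 0.87 marks one silenced allele with the
  other two roughly equal, and c_v = sqrt(3) ~ 1.73 marks two silenced
  alleles;
* a category: ``even`` when equality is not rejected, otherwise
  ``<strain>_up`` / ``<strain>_down`` when exactly one allele lies 2-fold
  above / below the median allele expression, else ``spread``.

Transcripts are also placed on a 2x2 quadrant grid crossing whole-gene
differential expression versus the parental average (2-fold threshold)
with allele dispersion (c_v threshold).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SQRT3",
    "CV_ONE_SILENCED",
    "ImbalanceRecord",
    "coefficient_of_variation",
    "equal_expression_test",
    "classify_category",
    "quadrant",
    "concordance",
    "chromosome_rank_table",
]

SQRT3 = math.sqrt(3.0)
#: c_v of an (x, x, 0) allele triple — the one-silenced-allele landmark.
CV_ONE_SILENCED = SQRT3 / 2.0


@dataclasses.dataclass
class ImbalanceRecord:
    """Imbalance summaries for one transcript in one individual."""

    transcript_id: str
    cv: float
    p_equal: float
    category: str
    quadrant: str
    fold_change: float  # log2(triploid / parental-average expression)


def coefficient_of_variation(values: Sequence[float]) -> float:
    """Sample (n-1) standard deviation over mean of the ASE values.

    Undefined (raises) for an all-zero input. The sample form is the one
    whose landmarks are sqrt(3)/2 for (x, x, 0) and sqrt(3) for (x, 0, 0).
    """
    v = np.asarray(values, dtype=float)
    if (v < 0).any():
        raise ValueError("ASE values must be non-negative")
    mean = v.mean()
    if mean == 0:
        raise ValueError("coefficient of variation undefined for all-zero values")
    return float(v.std(ddof=1) / mean)


def equal_expression_test(values: Sequence[float]) -> float:
    """Goodness-of-fit p-value for the null of equal allele expression.

    Pearson chi-square with expected value total/ploidy per allele and
    ploidy - 1 degrees of freedom, treating the ASE values as count-like
    quantities.
    """
    v = np.asarray(values, dtype=float)
    total = v.sum()
    if total <= 0:
        raise ValueError("equality test undefined when total expression is zero")
    expected = total / v.size
    statistic = float(((v - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(statistic, df=v.size - 1))


def classify_category(
    values: Mapping[str, float],
    p_value: float,
    alpha: float = 0.01,
    fold: float = 2.0,
) -> str:
    """Label one transcript's allele balance.

    ``even`` when the equality test is not rejected at ``alpha``; otherwise
    ``<strain>_up`` if exactly one allele exceeds ``fold`` times the median
    allele expression, else ``<strain>_down`` if exactly one allele falls
    below median/``fold``, else ``spread``. The median is used as the
    comparison basis because with so few observations a single outlying
    allele would drag the mean.
    """
    if p_value >= alpha:
        return "even"
    strains = list(values)
    v = np.asarray([values[s] for s in strains], dtype=float)
    med = float(np.median(v))
    ups = [s for s, x in zip(strains, v) if x > fold * med]
    if len(ups) == 1:
        return f"{ups[0]}_up"
    downs = [s for s, x in zip(strains, v) if x < med / fold]
    if len(downs) == 1:
        return f"{downs[0]}_down"
    return "spread"


def quadrant(
    triploid_expr: float,
    parental_mean_expr: float,
    cv: float,
    fold: float = 2.0,
    cv_threshold: float = CV_ONE_SILENCED,
) -> str:
    """Joint differential-expression / dispersion quadrant.

    Quadrant 0: expression similar to the parental average and low
    dispersion; I: dispersed alleles only; II: changed overall expression
    only; III: both.
    """
    if triploid_expr <= 0 or parental_mean_expr <= 0:
        raise ValueError("quadrant classification needs positive expression values")
    changed = abs(math.log2(triploid_expr / parental_mean_expr)) > math.log2(fold)
    dispersed = cv > cv_threshold
    return {(False, False): "0", (False, True): "I", (True, False): "II", (True, True): "III"}[
        (changed, dispersed)
    ]


def concordance(
    categories_a: Mapping[str, str], categories_b: Mapping[str, str]
) -> Tuple[int, Dict[str, int]]:
    """Count transcripts assigned the same category in two individuals.

    Returns the total concordant count and a per-category breakdown (the
    parenthesized per-category shared counts of the chromosomal map
    legend). Both inputs must cover the same transcript universe.
    """
    if set(categories_a) != set(categories_b):
        raise ValueError("category maps cover different transcript universes")
    per_category: Dict[str, int] = {}
    total = 0
    for tid, cat in categories_a.items():
        if categories_b[tid] == cat:
            total += 1
            per_category[cat] = per_category.get(cat, 0) + 1
    return total, per_category


def chromosome_rank_table(
    categories: Mapping[str, str],
    annotation: pd.DataFrame,
) -> pd.DataFrame:
    """Order classified transcripts along their chromosomes.

    ``annotation`` has columns ``transcript_id``, ``chromosome``, ``order``
    (any monotone within-chromosome coordinate). Within a chromosome,
    transcripts are sorted by ``order`` and given sequential ranks 1..n;
    coordinate ties keep input order and still receive sequential ranks.
    Transcripts absent from the annotation are omitted.
    """
    required = {"transcript_id", "chromosome", "order"}
    if not required.issubset(annotation.columns):
        raise ValueError(f"annotation needs columns {sorted(required)}")
    if annotation.duplicated(["chromosome", "order", "transcript_id"]).any():
        raise ValueError("duplicate (chromosome, order, transcript) in annotation")
    rows: List[dict] = []
    subset = annotation[annotation["transcript_id"].isin(categories)]
    for chrom, group in subset.groupby("chromosome", sort=True):
        ordered = group.sort_values("order", kind="stable")
        for rank, (_, row) in enumerate(ordered.iterrows(), start=1):
            tid = row["transcript_id"]
            rows.append(
                {
                    "chromosome": chrom,
                    "rank": rank,
                    "transcript_id": tid,
                    "category": categories[tid],
                }
            )
    return pd.DataFrame(rows, columns=["chromosome", "rank", "transcript_id", "category"])
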