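"""Discriminatory-SNP (dSNP) discovery from per-strain consensus tracks.

A dSNP is a transcript position at which one strain is homozygous for a
nucleotide that does not appear among the observed nucleotide possibilities
(IUPAC expansions) of any other strain — reads carrying that nucleotide can
then be attributed to that strain's allele. Sites where a strain is
heterozygous for the difference, where any strain's call is 'N', or where
all strains merely agree against the reference are uninformative. ASE can
only be computed for "dSNP-complete" transcripts: those with at least one
dSNP for every strain.
"""

from __future__ import annotations

import dataclasses
import enum
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

from .consensus import IUPAC_EXPAND, ConsensusCall

__all__ = [
    "Verdict",
    "DsnpStatus",
    "Dsnp",
    "classify_site",
    "find_dsnps",
    "select_complete_transcripts",
]

_NUCS = frozenset("ACGT")


class Verdict(str, enum.Enum):
    DSNP = "DSNP"
    HETEROZYGOUS_OVERLAP = "HETEROZYGOUS_OVERLAP"
    LOW_CONFIDENCE_N = "LOW_CONFIDENCE_N"
    ALL_AGREE_VS_REF = "ALL_AGREE_VS_REF"
    NO_DIFFERENCE = "NO_DIFFERENCE"


@dataclasses.dataclass(frozen=True)
class DsnpStatus:
    strain: str
    verdict: Verdict


@dataclasses.dataclass
class Dsnp:
    """One strain discriminated at one transcript position."""

    transcript_id: str
    position: int
    strain: str
    base: str
    other_bases: Dict[str, frozenset]

    def __post_init__(self) -> None:
        if self.base not in _NUCS:
            raise ValueError(f"dSNP base must be unambiguous, got {self.base!r}")
        for other, expansion in self.other_bases.items():
            if self.base in expansion:
                raise ValueError(
                    f"dSNP base {self.base} overlaps strain {other}'s possibilities"
                )


def _iupac_of(call: "str | ConsensusCall") -> str:
    return (call.iupac if isinstance(call, ConsensusCall) else call).upper()


def classify_site(
    calls: Mapping[str, "str | ConsensusCall"], ref_base: str
) -> List[DsnpStatus]:
    """Give every strain a verdict at one site.

    A strain is discriminated (DSNP) iff its own call is a single
    unambiguous base, every other strain's call is non-'N', and its base is
    absent from every other strain's IUPAC expansion. Multiple strains can
    be discriminated at one site independently.
    """
    if len(calls) < 2:
        raise ValueError("classify_site needs calls for at least two strains")
    iupacs = {s: _iupac_of(c) for s, c in calls.items()}
    for strain, code in iupacs.items():
        if code not in IUPAC_EXPAND:
            raise ValueError(f"strain {strain}: not an IUPAC code: {code!r}")
    ref = ref_base.upper()
    statuses = []
    for strain, own in iupacs.items():
        others = [code for s, code in iupacs.items() if s != strain]
        if own == "N" or "N" in others:
            verdict = Verdict.LOW_CONFIDENCE_N
        elif own in _NUCS and all(own not in IUPAC_EXPAND[o] for o in others):
            verdict = Verdict.DSNP
        elif own in _NUCS and all(o == own for o in others):
            verdict = Verdict.ALL_AGREE_VS_REF if own != ref else Verdict.NO_DIFFERENCE
        elif own == ref:
            verdict = Verdict.NO_DIFFERENCE
        else:
            verdict = Verdict.HETEROZYGOUS_OVERLAP
        statuses.append(DsnpStatus(strain, verdict))
    return statuses


def find_dsnps(
    tracks: Mapping[str, Mapping[str, str]],
    references: Mapping[str, str],
) -> List[Dsnp]:
    """Scan aligned consensus tracks for dSNPs.

    ``tracks`` maps strain -> transcript -> IUPAC string of the same length
    as the reference sequence (one code per position, 'N' where no call was
    possible). Results are grouped by transcript in reference order, and by
    position within each transcript.
    """
    strains = list(tracks)
    if len(strains) < 2:
        raise ValueError("need consensus tracks for at least two strains")
    universes = {s: set(t) for s, t in tracks.items()}
    reference_ids = set(references)
    mismatches = {
        s: sorted(u.symmetric_difference(reference_ids))
        for s, u in universes.items()
        if u != reference_ids
    }
    if mismatches:
        raise ValueError(f"tracks cover different transcript sets: {mismatches}")

    dsnps: List[Dsnp] = []
    for tid, ref_seq in references.items():
        per_strain = {s: tracks[s][tid] for s in strains}
        lengths = {len(t) for t in per_strain.values()}
        if lengths != {len(ref_seq)}:
            raise ValueError(f"track length mismatch for transcript {tid}")
        for i, ref in enumerate(ref_seq):
            codes = {s: per_strain[s][i] for s in strains}
            if all(c == ref for c in codes.values()):
                continue  # no strain differs from the reference
            for status in classify_site(codes, ref):
                if status.verdict is Verdict.DSNP:
                    strain = status.strain
                    dsnps.append(
                        Dsnp(
                            transcript_id=tid,
                            position=i + 1,
                            strain=strain,
                            base=codes[strain],
                            other_bases={
                                s: IUPAC_EXPAND[codes[s]]
                                for s in strains
                                if s != strain
                            },
                        )
                    )
    return dsnps


def select_complete_transcripts(
    dsnps: Sequence[Dsnp], strains: Iterable[str]
) -> Tuple[List[str], List[Dsnp]]:
    """Keep transcripts with at least one dSNP for every strain.

    Returns (kept transcript ids in first-seen order, dSNPs restricted to
    the kept transcripts).
    """
    required = set(strains)
    covered: Dict[str, set] = {}
    order: List[str] = []
    for d in dsnps:
        if d.transcript_id not in covered:
            covered[d.transcript_id] = set()
            order.append(d.transcript_id)
        covered[d.transcript_id].add(d.strain)
    kept = [tid for tid in order if covered[tid] >= required]
    kept_set = set(kept)
    return kept, [d for d in dsnps if d.transcript_id in kept_set]
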