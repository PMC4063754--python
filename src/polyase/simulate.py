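"""Synthetic RNA-seq data with known allele fractions, and recovery scoring.

The generator emulates the validation design used to test the ASE method:
strain-specific transcript sequences are built by substituting each
strain's SNP nucleotides into the reference, and paired 100 bp reads with a
250 bp fragment size are drawn at uniformly random start positions. The
total read count of a transcript is split between strains in proportion to
the chosen per-strain ASE values (largest-remainder rounding). Because the
generator knows every fragment's true placement, pileups are constructed
directly from the placements — no external aligner is involved — and the
pipeline's ASE estimates can be scored against the generating truth with a
per-transcript Pearson correlation.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .formats import TranscriptRecord, write_fasta, write_table

__all__ = [
    "StrainVariant",
    "FragmentPlacement",
    "build_strain_reference",
    "allocate_reads",
    "generate_fragments",
    "fragment_reads",
    "write_fastq",
    "placements_to_pileup",
    "evaluate_recovery",
    "simulate_experiment",
]

_NUCS = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclasses.dataclass(frozen=True)
class StrainVariant:
    """One strain-specific substitution: (transcript, 1-based position, base)."""

    transcript_id: str
    position: int
    strain: str
    base: str


@dataclasses.dataclass(frozen=True)
class FragmentPlacement:
    """Ground-truth placement of one sequenced fragment.

    A paired fragment of length F with reads of length R covers positions
    [start, start+R-1] on the forward strand and [start+F-R, start+F-1] on
    the reverse strand, leaving an inner gap (R + R < F). Transcripts
    shorter than the fragment length get unpaired forward reads instead.
    """

    transcript_id: str
    strain: str
    start: int
    fragment_length: int = 250
    read_length: int = 100
    paired: bool = True

    def covered_intervals(self) -> List[Tuple[int, int, bool]]:
        """(first, last, forward) 1-based inclusive intervals covered."""
        if not self.paired:
            return [(self.start, self.start + self.read_length - 1, True)]
        return [
            (self.start, self.start + self.read_length - 1, True),
            (
                self.start + self.fragment_length - self.read_length,
                self.start + self.fragment_length - 1,
                False,
            ),
        ]


def build_strain_reference(
    transcript: TranscriptRecord,
    variants: Iterable[Tuple[int, str]],
) -> TranscriptRecord:
    """Substitute a strain's SNP bases into the reference sequence."""
    seq = list(transcript.sequence)
    for position, base in variants:
        if not 1 <= position <= len(seq):
            raise ValueError(
                f"variant position {position} outside transcript {transcript.id}"
            )
        if seq[position - 1] == base:
            warnings.warn(
                f"substitution at {transcript.id}:{position} equals the reference "
                "base and will not discriminate",
                stacklevel=2,
            )
        seq[position - 1] = base
    return TranscriptRecord(transcript.id, "".join(seq))


def allocate_reads(total: int, ase: Sequence[float]) -> List[int]:
    """Split ``total`` fragments between strains in proportion to ASE.

    Largest-remainder integerization, so the counts always sum exactly to
    ``total``; remainder ties are broken by strain order.
    """
    if total < 0:
        raise ValueError("total must be non-negative")
    weights = np.asarray(ase, dtype=float)
    if (weights < 0).any():
        raise ValueError("ASE values must be non-negative")
    denom = weights.sum()
    if denom == 0:
        if total == 0:
            return [0] * len(weights)
        raise ValueError("cannot allocate reads when all ASE values are zero")
    quotas = total * weights / denom
    counts = np.floor(quotas).astype(int)
    remainder = total - int(counts.sum())
    by_fraction = sorted(range(len(weights)), key=lambda i: (-(quotas[i] - counts[i]), i))
    for i in by_fraction[:remainder]:
        counts[i] += 1
    return [int(c) for c in counts]


def generate_fragments(
    strain_ref: TranscriptRecord,
    n: int,
    strain: str,
    rng: np.random.Generator,
    read_length: int = 100,
    fragment_length: int = 250,
) -> List[FragmentPlacement]:
    """Draw ``n`` fragment placements at uniform random start positions.

    Transcripts shorter than the fragment length fall back to unpaired
    reads of min(length, read_length) drawn over the valid starts.
    """
    length = len(strain_ref)
    if n < 0:
        raise ValueError("n must be non-negative")
    if n == 0:
        return []
    if length >= fragment_length:
        starts = rng.integers(1, length - fragment_length + 2, size=n)
        return [
            FragmentPlacement(strain_ref.id, strain, int(s), fragment_length, read_length)
            for s in starts
        ]
    span = min(length, read_length)
    starts = rng.integers(1, length - span + 2, size=n)
    return [
        FragmentPlacement(strain_ref.id, strain, int(s), span, span, paired=False)
        for s in starts
    ]


def fragment_reads(placement: FragmentPlacement, sequence: str) -> Tuple[str, str | None]:
    """Extract the read pair (R2 reverse-complemented) for one placement."""
    s = placement.start - 1
    r1 = sequence[s : s + placement.read_length]
    if not placement.paired:
        return r1, None
    m2_start = s + placement.fragment_length - placement.read_length
    r2_fwd = sequence[m2_start : m2_start + placement.read_length]
    return r1, r2_fwd.translate(_COMPLEMENT)[::-1]


def write_fastq(
    placements: Sequence[FragmentPlacement],
    strain_sequences: Mapping[str, Mapping[str, str]],
    r1_path: str | Path,
    r2_path: str | Path,
    quality_char: str = "I",
) -> None:
    """Emit the reads of ``placements`` as a FASTQ pair with uniform quality.

    ``strain_sequences`` maps strain -> transcript -> strain-specific
    sequence. Unpaired placements go to R1 only.
    """
    with open(r1_path, "w") as h1, open(r2_path, "w") as h2:
        for i, p in enumerate(placements):
            seq = strain_sequences[p.strain][p.transcript_id]
            r1, r2 = fragment_reads(p, seq)
            name = f"frag_{i}_{p.transcript_id}_{p.strain}_{p.start}"
            h1.write(f"@{name}/1\n{r1}\n+\n{quality_char * len(r1)}\n")
            if r2 is not None:
                h2.write(f"@{name}/2\n{r2}\n+\n{quality_char * len(r2)}\n")


def placements_to_pileup(
    placements: Sequence[FragmentPlacement],
    reference: Sequence[TranscriptRecord],
    strain_sequences: Mapping[str, Mapping[str, str]],
    path: str | Path,
    quality_char: str = "I",
    error_rate: float = 0.0,
    rng: np.random.Generator | None = None,
) -> None:
    """Write the mpileup text implied by ground-truth placements.

    Replaces the alignment step: per-position depth and base observations
    follow directly from the known fragment coordinates and the
    strain-specific sequences. Forward-mate coverage is recorded as
    ``.``/uppercase, reverse-mate coverage as ``,``/lowercase. Optional
    uniform substitution errors (``error_rate``) replace individual
    observations with random bases for robustness experiments.
    """
    if error_rate and rng is None:
        raise ValueError("error injection requires an rng")
    by_transcript: Dict[str, List[FragmentPlacement]] = {}
    for p in placements:
        by_transcript.setdefault(p.transcript_id, []).append(p)

    with open(path, "w") as handle:
        for rec in reference:
            group = by_transcript.get(rec.id)
            if not group:
                continue
            _write_transcript_pileup(
                handle, rec, group, strain_sequences, quality_char, error_rate, rng
            )


def _write_transcript_pileup(
    handle,
    rec: TranscriptRecord,
    group: Sequence[FragmentPlacement],
    strain_sequences: Mapping[str, Mapping[str, str]],
    quality_char: str,
    error_rate: float,
    rng: np.random.Generator | None,
) -> None:
    length = len(rec)
    strains = sorted({p.strain for p in group})
    # Per-strain forward/reverse coverage via interval difference arrays.
    fwd = {s: np.zeros(length + 2, dtype=np.int32) for s in strains}
    rev = {s: np.zeros(length + 2, dtype=np.int32) for s in strains}
    for p in group:
        for first, last, forward in p.covered_intervals():
            target = fwd[p.strain] if forward else rev[p.strain]
            target[first] += 1
            target[last + 1] -= 1
    fwd_depth = {s: np.cumsum(fwd[s])[1 : length + 1].tolist() for s in strains}
    rev_depth = {s: np.cumsum(rev[s])[1 : length + 1].tolist() for s in strains}
    # Positions where each strain's sequence differs from the reference.
    diffs: Dict[str, Dict[int, str]] = {}
    for s in strains:
        seq = strain_sequences[s][rec.id]
        diffs[s] = {
            i + 1: seq[i] for i in range(length) if seq[i] != rec.sequence[i]
        }
    ref_seq = rec.sequence
    tid = rec.id
    for pos in range(1, length + 1):
        parts: List[str] = []
        depth = 0
        for s in strains:
            f = fwd_depth[s][pos - 1]
            r = rev_depth[s][pos - 1]
            if not (f or r):
                continue
            base = diffs[s].get(pos)
            if base is None:
                parts.append("." * f + "," * r)
            else:
                parts.append(base.upper() * f + base.lower() * r)
            depth += f + r
        if depth == 0:
            continue
        bases = "".join(parts)
        if error_rate:
            n_err = rng.binomial(depth, error_rate)
            if n_err:
                chars = list(bases)
                for idx in rng.choice(depth, size=n_err, replace=False):
                    wrong = _NUCS[rng.integers(4)]
                    chars[idx] = wrong if chars[idx] in ".ACGT" else wrong.lower()
                bases = "".join(chars)
        handle.write(
            f"{tid}\t{pos}\t{ref_seq[pos - 1]}\t{depth}\t{bases}\t{quality_char * depth}\n"
        )


def evaluate_recovery(
    true_ase: pd.DataFrame, estimated_ase: pd.DataFrame
) -> Tuple[pd.DataFrame, Dict[str, float]]:
    """Score recovered ASE values against the generating truth.

    Both frames are indexed by transcript with one column per strain. For
    each transcript the Pearson correlation across the per-strain value
    pairs is computed; it is undefined (NaN, flagged ``constant``) when
    either vector is constant — near-equal true values can then score near
    0 despite small absolute errors. The summary reports the fraction of
    transcripts with r > 0.8 and with r >= 0.9 over all scored transcripts.
    """
    if sorted(true_ase.index) != sorted(estimated_ase.index) or sorted(
        true_ase.columns
    ) != sorted(estimated_ase.columns):
        raise ValueError("truth and estimate tables must match in transcripts and strains")
    est = estimated_ase.loc[true_ase.index, true_ase.columns]
    t = true_ase.to_numpy(dtype=float)
    e = est.to_numpy(dtype=float)
    if t.shape[1] < 3:
        raise ValueError("recovery evaluation needs at least three alleles")
    t_c = t - t.mean(axis=1, keepdims=True)
    e_c = e - e.mean(axis=1, keepdims=True)
    t_sd = np.sqrt((t_c**2).sum(axis=1))
    e_sd = np.sqrt((e_c**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (t_c * e_c).sum(axis=1) / (t_sd * e_sd)
    flags = np.where((t_sd == 0) | (e_sd == 0), "constant", "")
    table = pd.DataFrame({"r": r, "flag": flags}, index=true_ase.index)
    n = len(table)
    summary = {
        "n": float(n),
        "n_defined": float(np.isfinite(r).sum()),
        "fraction_r_gt_0.8": float((r > 0.8).sum() / n) if n else math.nan,
        "fraction_r_ge_0.9": float((r >= 0.9).sum() / n) if n else math.nan,
    }
    return table, summary


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(_NUCS[i] for i in rng.integers(0, 4, size=length))


def simulate_experiment(
    out_dir: str | Path,
    seed: int,
    n_transcripts: int = 300,
    transcript_length: int = 1500,
    strains: Sequence[str] = ("HNI", "OR", "SOK"),
    dsnps_per_strain: int = 5,
    parental_fragments: int = 300,
    triploid_fragments: Tuple[int, int] = (200, 2000),
    read_length: int = 100,
    fragment_length: int = 250,
    error_rate: float = 0.0,
    write_reads: bool = False,
    allele_fractions: Sequence[float] | None = None,
) -> Dict[str, Path]:
    """Generate a complete synthetic study: reference, variants, pileups, truth.

    Per transcript, ``dsnps_per_strain`` strain-specific substitution sites
    are planted for each strain (distinct positions, one strain per site),
    per-strain allele fractions are drawn from Dirichlet(1, 1, 1) (or fixed
    to ``allele_fractions`` for every transcript when given), and the
    triploid sample's fragment total is drawn uniformly from
    ``triploid_fragments``. Each parental sample is sequenced at
    ``parental_fragments`` fragments per transcript. Outputs: a reference
    FASTA, a variants TSV, per-strain parental mpileups, one triploid
    mpileup, and a truth TSV of per-strain true ASE values (allele fraction
    times fragment total). The whole simulation is reproducible from
    ``seed``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    strains = list(strains)
    k = len(strains)

    reference: List[TranscriptRecord] = []
    variant_rows: List[dict] = []
    truth_rows: List[dict] = []
    strain_seqs: Dict[str, Dict[str, str]] = {s: {} for s in strains}
    parental_placements: Dict[str, List[FragmentPlacement]] = {s: [] for s in strains}
    triploid_placements: List[FragmentPlacement] = []

    for t in range(n_transcripts):
        tid = f"TSYN{t:05d}"
        rec = TranscriptRecord(tid, _random_sequence(rng, transcript_length))
        reference.append(rec)

        positions = rng.choice(
            transcript_length, size=k * dsnps_per_strain, replace=False
        )
        per_strain_variants: Dict[str, List[Tuple[int, str]]] = {s: [] for s in strains}
        for j, pos0 in enumerate(sorted(int(p) for p in positions)):
            strain = strains[j % k]
            ref_base = rec.sequence[pos0]
            alternatives = [b for b in _NUCS if b != ref_base]
            base = alternatives[rng.integers(3)]
            per_strain_variants[strain].append((pos0 + 1, base))
            variant_rows.append(
                {"transcript_id": tid, "position": pos0 + 1, "strain": strain, "base": base}
            )
        for s in strains:
            strain_seqs[s][tid] = build_strain_reference(
                rec, per_strain_variants[s]
            ).sequence

        if allele_fractions is None:
            fractions = rng.dirichlet(np.ones(k))
        else:
            fractions = np.asarray(allele_fractions, dtype=float)
            fractions = fractions / fractions.sum()
        total = int(rng.integers(triploid_fragments[0], triploid_fragments[1] + 1))
        counts = allocate_reads(total, fractions)
        truth_rows.append(
            {"transcript_id": tid, **{s: fractions[i] * total for i, s in enumerate(strains)}}
        )
        for i, s in enumerate(strains):
            strain_rec = TranscriptRecord(tid, strain_seqs[s][tid])
            parental_placements[s].extend(
                generate_fragments(
                    strain_rec, parental_fragments, s, rng, read_length, fragment_length
                )
            )
            triploid_placements.extend(
                generate_fragments(
                    strain_rec, counts[i], s, rng, read_length, fragment_length
                )
            )

    paths: Dict[str, Path] = {}
    paths["reference"] = out_dir / "reference.fasta"
    write_fasta(reference, paths["reference"])
    paths["variants"] = out_dir / "variants.tsv"
    write_table(
        variant_rows,
        paths["variants"],
        columns=["transcript_id", "position", "strain", "base"],
    )
    paths["truth"] = out_dir / "truth.tsv"
    write_table(
        truth_rows, paths["truth"], columns=["transcript_id", *strains], float_format="%.6f"
    )
    for s in strains:
        p = out_dir / f"parent_{s}.mpileup"
        placements_to_pileup(
            parental_placements[s], reference, strain_seqs, p,
            error_rate=error_rate, rng=rng,
        )
        paths[f"parent_{s}"] = p
    paths["triploid"] = out_dir / "triploid.mpileup"
    placements_to_pileup(
        triploid_placements, reference, strain_seqs, paths["triploid"],
        error_rate=error_rate, rng=rng,
    )
    if write_reads:
        paths["r1"] = out_dir / "triploid_R1.fastq"
        paths["r2"] = out_dir / "triploid_R2.fastq"
        write_fastq(triploid_placements, strain_seqs, paths["r1"], paths["r2"])
    return paths
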