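"""Text-format readers/writers shared by the ASE pipeline.

Three formats are touched: FASTA reference transcriptomes, the 6-column
``samtools mpileup`` text dialect (one sample per file), and tab-separated
report tables. Coordinates are 1-based inclusive everywhere, following the
mpileup convention; read strand is carried the way mpileup carries it, as
character case (uppercase/``.`` = forward, lowercase/``,`` = reverse).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "FormatError",
    "TranscriptRecord",
    "PileupColumn",
    "read_fasta",
    "write_fasta",
    "parse_mpileup_line",
    "serialize_column",
    "read_mpileup",
    "write_table",
    "read_table",
]


class FormatError(ValueError):
    """A file does not conform to the expected text format."""


@dataclasses.dataclass(frozen=True)
class TranscriptRecord:
    """One reference transcript: identifier plus nucleotide sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("transcript identifier must be non-empty")
        if not self.sequence:
            raise FormatError(f"transcript {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path: str | Path) -> list[TranscriptRecord]:
    """Read a FASTA file into a list of :class:`TranscriptRecord`.

    Sequences are uppercased and record order is preserved. Malformed
    headers and empty sequences raise :class:`FormatError` naming the
    offending line.
    """
    path = Path(path)
    _validate_fasta_lines(path)
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA identifier {rec.id!r}")
        seen.add(rec.id)
        records.append(TranscriptRecord(rec.id, str(rec.seq).upper()))
    return records


def _validate_fasta_lines(path: Path) -> None:
    """Light pre-scan so format errors can name a line number."""
    header_line = None
    have_sequence = False
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if header_line is not None and not have_sequence:
                    raise FormatError(
                        f"{path}:{header_line}: header with empty sequence"
                    )
                if len(line) == 1:
                    raise FormatError(f"{path}:{lineno}: malformed header '>'")
                header_line, have_sequence = lineno, False
            else:
                if header_line is None:
                    raise FormatError(
                        f"{path}:{lineno}: sequence data before any header"
                    )
                have_sequence = True
    if header_line is not None and not have_sequence:
        raise FormatError(f"{path}:{header_line}: header with empty sequence")


def write_fasta(records: Iterable[TranscriptRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                handle.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# mpileup
# ---------------------------------------------------------------------------

# Characters that force the slow, stateful grammar walk.
_PILEUP_SPECIAL = frozenset("^$+-*<>")
_BASE_CHARS = frozenset("ACGTNacgtn")


@dataclasses.dataclass
class PileupColumn:
    """One reference position of one sample's pileup.

    ``bases`` holds one resolved character per read covering the position:
    the actual nucleotide with case encoding strand (upper = forward,
    lower = reverse), or ``*`` for deletion/refskip placeholders, which
    count toward depth but never toward base tallies. ``quals`` is the raw
    phred+33 quality string, aligned with ``bases``.
    """

    transcript_id: str
    position: int
    ref_base: str
    bases: str
    quals: str

    @property
    def depth(self) -> int:
        return len(self.bases)

    @property
    def observations(self) -> list[tuple[str, str, int]]:
        """Per-read (base, strand, quality) tuples; strand is '+' or '-'."""
        out = []
        for b, q in zip(self.bases, self.quals):
            if b == "*":
                out.append(("*", "+", ord(q) - 33))
            elif b.isupper():
                out.append((b, "+", ord(q) - 33))
            else:
                out.append((b.upper(), "-", ord(q) - 33))
        return out


def parse_mpileup_line(line: str, line_number: int | None = None) -> PileupColumn:
    """Parse one 6-column mpileup line into a :class:`PileupColumn`.

    Handles the full read-base grammar: ``.``/``,`` reference matches,
    case-encoded mismatches, ``^X`` read starts (mapping-quality character
    skipped), ``$`` read ends, ``+n``/``-n`` indel strings (consumed, no
    observation emitted), and ``*``/``<``/``>`` placeholders (kept in depth,
    excluded from base tallies). A seventh (mapping quality) column, if
    present, is ignored.
    """
    where = f" at line {line_number}" if line_number is not None else ""
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 6:
        raise FormatError(f"expected >= 6 tab-separated mpileup fields{where}")
    tid, pos_s, ref, depth_s, raw, quals = fields[:6]
    ref = ref.strip().upper()
    if len(ref) != 1:
        raise FormatError(f"reference base {ref!r} is not a single character{where}")
    try:
        position = int(pos_s)
        depth = int(depth_s)
    except ValueError as exc:
        raise FormatError(f"non-integer position/depth field{where}") from exc
    if position < 1:
        raise FormatError(f"position {position} < 1{where}")

    if _PILEUP_SPECIAL.isdisjoint(raw):
        # Fast path: plain match/mismatch characters only.
        bases = raw.replace(".", ref).replace(",", ref.lower())
        if not _BASE_CHARS.issuperset(bases):
            bad = next(c for c in bases if c not in _BASE_CHARS)
            raise FormatError(f"unexpected pileup character {bad!r}{where}")
    else:
        bases = _walk_pileup_string(raw, ref, where)

    if len(bases) != len(quals):
        raise FormatError(
            f"{len(bases)} base observations vs {len(quals)} qualities{where}"
        )
    if len(bases) != depth:
        raise FormatError(
            f"depth field {depth} vs {len(bases)} base observations{where}"
        )
    return PileupColumn(tid, position, ref, bases, quals)


def _walk_pileup_string(raw: str, ref: str, where: str) -> str:
    out: list[str] = []
    i, n = 0, len(raw)
    while i < n:
        c = raw[i]
        if c == "^":
            i += 2  # '^' plus the mapping-quality character
            continue
        if c == "$":
            i += 1
            continue
        if c in "+-":
            j = i + 1
            while j < n and raw[j].isdigit():
                j += 1
            if j == i + 1:
                raise FormatError(f"indel marker without length{where}")
            i = j + int(raw[i + 1 : j])
            continue
        if c == ".":
            out.append(ref)
        elif c == ",":
            out.append(ref.lower())
        elif c in "*<>":
            out.append("*")
        elif c in _BASE_CHARS:
            out.append(c)
        else:
            raise FormatError(f"unexpected pileup character {c!r}{where}")
        i += 1
    return "".join(out)


def serialize_column(column: PileupColumn) -> str:
    """Render a column back to one mpileup text line (inverse of parsing)."""
    ref = column.ref_base
    raw = column.bases.replace(ref, ".").replace(ref.lower(), ",")
    return "\t".join(
        (
            column.transcript_id,
            str(column.position),
            ref,
            str(column.depth),
            raw,
            column.quals,
        )
    )


def read_mpileup(path: str | Path) -> Iterator[PileupColumn]:
    """Stream a one-sample mpileup text file as :class:`PileupColumn`s."""
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if line.strip():
                yield parse_mpileup_line(line, line_number=lineno)


# ---------------------------------------------------------------------------
# report tables
# ---------------------------------------------------------------------------

def write_table(
    records: Sequence[Mapping] | pd.DataFrame,
    path: str | Path,
    columns: Sequence[str] | None = None,
    float_format: str = "%.6g",
) -> None:
    """Write homogeneous records as a TSV with header and fixed precision.

    ``columns`` fixes the column order; a record missing a scheduled column
    raises :class:`FormatError`.
    """
    if isinstance(records, pd.DataFrame):
        frame = records
    else:
        frame = pd.DataFrame(list(records))
    if columns is not None:
        if len(frame) == 0:
            frame = pd.DataFrame(columns=list(columns))
        missing = [c for c in columns if c not in frame.columns]
        if missing:
            raise FormatError(f"records missing scheduled columns: {missing}")
        frame = frame[list(columns)]
    frame.to_csv(path, sep="\t", index=False, float_format=float_format)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
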