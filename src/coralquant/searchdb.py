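"""Six-frame translation search-database construction.

Builds a nonredundant protein search database from one or more nucleotide
transcriptome sets, the standard "proteomics informed by transcriptomics"
workaround for species without a reference genome: every contig is
translated in all six reading frames, stop codons split each frame into
stop-free segments, short segments are discarded, and exact duplicate
amino-acid sequences across all input sets are collapsed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "TranscriptRecord",
    "ProteinDbRecord",
    "DatabaseSummary",
    "six_frame_translate",
    "build_database",
    "read_fasta",
    "write_fasta",
    "read_transcript_fasta",
    "write_transcript_fasta",
]

_VALID_BASES = frozenset("ACGTN")
_FRAMES = (1, 2, 3, -1, -2, -3)

# Standard genetic code; codons containing N are looked up as 'X' below.
_CODON_TABLE = dict(standard_dna_table.forward_table)
_STOP_CODONS = frozenset(standard_dna_table.stop_codons)


class InvalidNucleotideError(ValueError):
    """A transcript contains a symbol outside {A, C, G, T, N}."""


@dataclass(frozen=True)
class TranscriptRecord:
    """A nucleotide contig from one transcriptome set."""

    id: str
    sequence: str
    source: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"transcript {self.id!r}: empty sequence")
        seq = self.sequence.upper()
        for pos, base in enumerate(seq):
            if base not in _VALID_BASES:
                raise InvalidNucleotideError(
                    f"transcript {self.id!r}: invalid nucleotide {base!r} "
                    f"at position {pos}"
                )
        object.__setattr__(self, "sequence", seq)


@dataclass(frozen=True)
class ProteinDbRecord:
    """One stop-free translated segment, a search-database entry.

    The id encodes provenance as ``source|transcript|frame|segment-index``
    so any identified peptide can be traced back to its contig and frame.
    """

    id: str
    sequence: str
    frame: int
    segment_index: int

    def __post_init__(self) -> None:
        if self.frame not in _FRAMES:
            raise ValueError(f"invalid frame {self.frame}")
        if "*" in self.sequence:
            raise ValueError(f"entry {self.id!r}: stop symbol in sequence")


@dataclass
class DatabaseSummary:
    """Counts reported by :func:`build_database`.

    ``frame_translations`` counts contigs x 6 frames; ``raw_segments``
    counts stop-delimited segments before the length filter, so either
    convention of "database entries" can be compared.
    """

    n_contigs: int = 0
    frame_translations: int = 0
    raw_segments: int = 0
    retained_segments: int = 0
    nonredundant_entries: int = 0
    duplicates_dropped: list[str] = field(default_factory=list)


def _translate_codon(codon: str) -> str:
    if "N" in codon:
        return "X"
    if codon in _STOP_CODONS:
        return "*"
    return _CODON_TABLE[codon]


def six_frame_translate(
    transcript: TranscriptRecord, min_len: int = 6
) -> list[ProteinDbRecord]:
    """Translate a contig in all six frames into stop-free segments.

    Parameters
    ----------
    transcript
        Validated nucleotide record.
    min_len
        Minimum segment length in residues; shorter segments are dropped.
        The default of 6 matches the shortest peptide the identification
        search accepts.

    Returns
    -------
    list of ProteinDbRecord
        Segments in frame order +1, +2, +3, -1, -2, -3; within a frame,
        segment indices count stop-delimited segments from the 5' end
        (of the frame's strand), starting at 1.

    Notes
    -----
    Trailing partial codons are dropped; codons containing N translate to
    'X' rather than breaking the segment.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    seq = transcript.sequence
    rc = str(Seq(seq).reverse_complement())
    out: list[ProteinDbRecord] = []
    for frame in _FRAMES:
        template = seq if frame > 0 else rc
        offset = abs(frame) - 1
        n_codons = (len(template) - offset) // 3
        aa = "".join(
            _translate_codon(template[offset + 3 * i : offset + 3 * i + 3])
            for i in range(n_codons)
        )
        for idx, segment in enumerate(aa.split("*"), start=1):
            if len(segment) >= min_len:
                out.append(
                    ProteinDbRecord(
                        id=f"{transcript.source}|{transcript.id}|{frame:+d}|{idx}",
                        sequence=segment,
                        frame=frame,
                        segment_index=idx,
                    )
                )
    return out


def _count_raw_segments(transcript: TranscriptRecord) -> int:
    # Same frame scan without the length filter, for the summary.
    return len(six_frame_translate(transcript, min_len=1)) + _n_empty_segments(
        transcript
    )


def _n_empty_segments(transcript: TranscriptRecord) -> int:
    # Adjacent stops produce empty segments; count them so raw_segments
    # reflects the full stop-split partition.
    seq = transcript.sequence
    rc = str(Seq(seq).reverse_complement())
    n = 0
    for frame in _FRAMES:
        template = seq if frame > 0 else rc
        offset = abs(frame) - 1
        n_codons = (len(template) - offset) // 3
        aa = "".join(
            _translate_codon(template[offset + 3 * i : offset + 3 * i + 3])
            for i in range(n_codons)
        )
        n += sum(1 for s in aa.split("*") if not s)
    return n


def build_database(
    sets: Sequence[Iterable[TranscriptRecord]], min_len: int = 6
) -> tuple[list[ProteinDbRecord], DatabaseSummary]:
    """Concatenate six-frame translations of several transcript sets and
    collapse exact duplicate amino-acid sequences.

    The first occurrence of each sequence is kept; ids of dropped
    duplicates are recorded in the summary. Duplicate transcript ids
    within one set are an error.
    """
    sets = [list(s) for s in sets]
    if not sets or all(not s for s in sets):
        raise ValueError("no input transcripts")
    summary = DatabaseSummary()
    seen: dict[str, str] = {}
    retained: list[ProteinDbRecord] = []
    for set_idx, transcripts in enumerate(sets):
        ids = [t.id for t in transcripts]
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        if dupes:
            raise ValueError(
                f"duplicate transcript ids in set {set_idx}: {', '.join(dupes)}"
            )
        for t in transcripts:
            summary.n_contigs += 1
            summary.frame_translations += 6
            summary.raw_segments += _count_raw_segments(t)
            for rec in six_frame_translate(t, min_len=min_len):
                summary.retained_segments += 1
                if rec.sequence in seen:
                    summary.duplicates_dropped.append(
                        f"{rec.id} (kept {seen[rec.sequence]})"
                    )
                else:
                    seen[rec.sequence] = rec.id
                    retained.append(rec)
    summary.nonredundant_entries = len(retained)
    return retained, summary


def write_fasta(records: Iterable[ProteinDbRecord], path) -> None:
    """Write database entries as 60-column-wrapped FASTA."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(seq_records)


def _parse_fasta_entry_fields(header: str) -> tuple[int, int]:
    parts = header.split("|")
    if len(parts) == 4:
        try:
            return int(parts[2]), int(parts[3])
        except ValueError:
            pass
    return 1, 1


def read_fasta(path) -> list[ProteinDbRecord]:
    """Read a protein FASTA, wrapping-agnostic; malformed input raises a
    parse error naming the offending line number."""
    with open(path) as fh:
        lines = fh.readlines()
    for lineno, line in enumerate(lines, start=1):
        if line.strip() and not line.startswith(">"):
            break
        if line.startswith(">"):
            break
    else:
        return []  # empty or whitespace-only file
    if not lines[lineno - 1].startswith(">"):
        raise ValueError(f"malformed FASTA: line {lineno} precedes any header")
    out = []
    for rec in SeqIO.parse(io.StringIO("".join(lines)), "fasta"):
        frame, seg = _parse_fasta_entry_fields(rec.id)
        out.append(
            ProteinDbRecord(
                id=rec.id, sequence=str(rec.seq), frame=frame, segment_index=seg
            )
        )
    return out


def read_transcript_fasta(path, source: str = "") -> list[TranscriptRecord]:
    """Read a nucleotide FASTA into transcript records, tagging each with
    the originating set label."""
    return [
        TranscriptRecord(id=rec.id, sequence=str(rec.seq), source=source)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_transcript_fasta(records: Iterable[TranscriptRecord], path) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(seq_records)
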