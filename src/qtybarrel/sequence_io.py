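"""Sequence and topology I/O with strict validation.

Every downstream stage (QTY substitution, pI/MW, hydropathy) assumes
uppercase sequences over the 20 canonical one-letter codes and 1-based,
inclusive, non-overlapping topology segments.  This module is the single
place where those conventions are enforced, so violations surface at load
time rather than as silently wrong physicochemical numbers.
"""

from __future__ import annotations

import csv
import json
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 canonical amino-acid one-letter codes.  B/J/O/U/X/Z and gap
#: characters are rejected: ambiguity codes have no defined mass or pKa.
CANONICAL_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Suffix appended to a native record id to name its QTY variant.
VARIANT_SUFFIX = "_QTY"

SEGMENT_KINDS = ("tm_strand", "other")


class SequenceFormatError(ValueError):
    """Malformed or empty sequence input file."""


class SequenceValidationError(ValueError):
    """A sequence violates the canonical-alphabet invariant."""


class TopologyError(ValueError):
    """A topology violates ordering, overlap or range invariants."""


def _validate_sequence(record_id: str, sequence: str) -> None:
    if not sequence:
        raise SequenceValidationError(f"record {record_id!r}: empty sequence")
    for pos, aa in enumerate(sequence, start=1):
        if aa not in CANONICAL_AA:
            raise SequenceValidationError(
                f"record {record_id!r}: illegal residue {aa!r} at position {pos} "
                "(only the 20 canonical one-letter codes are accepted)"
            )


@dataclass(frozen=True)
class ProteinRecord:
    """An identified amino-acid sequence with provenance.

    Parameters
    ----------
    id : short unique identifier (FASTA header token).
    description : free-text remainder of the FASTA header.
    sequence : uppercase string over the 20 canonical codes.
    source : one of ``file``, ``fetched``, ``synthetic``.
    """

    id: str
    description: str
    sequence: str
    source: str = "file"

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceValidationError("record id must be non-empty")
        if self.source not in ("file", "fetched", "synthetic"):
            raise SequenceValidationError(f"unknown source {self.source!r}")
        _validate_sequence(self.id, self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TopologySegment:
    """A contiguous annotated run of residues, 1-based inclusive."""

    kind: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.kind not in SEGMENT_KINDS:
            raise TopologyError(
                f"unknown segment kind {self.kind!r}; expected one of {SEGMENT_KINDS}"
            )
        if not (1 <= self.start <= self.end):
            raise TopologyError(
                f"segment must satisfy 1 <= start <= end, got [{self.start}, {self.end}]"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class Topology:
    """Ordered, non-overlapping segments over one protein sequence.

    The union of ``tm_strand`` segments defines the transmembrane residue
    set; its size is the denominator of the TM variation percentage.
    """

    protein_id: str
    segments: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        segments = tuple(self.segments)
        object.__setattr__(self, "segments", segments)
        prev = None
        for seg in segments:
            if prev is not None:
                if seg.start < prev.start:
                    raise TopologyError(
                        f"{self.protein_id}: segments not sorted by start "
                        f"({seg.start} after {prev.start})"
                    )
                if seg.start <= prev.end:
                    raise TopologyError(
                        f"{self.protein_id}: segments overlap: "
                        f"[{prev.start},{prev.end}] and [{seg.start},{seg.end}]"
                    )
            prev = seg

    def tm_positions(self) -> frozenset[int]:
        """1-based positions covered by tm_strand segments."""
        pos: set[int] = set()
        for seg in self.segments:
            if seg.kind == "tm_strand":
                pos.update(range(seg.start, seg.end + 1))
        return frozenset(pos)

    def tm_residue_count(self) -> int:
        return sum(len(s) for s in self.segments if s.kind == "tm_strand")

    def is_tm(self, position: int) -> bool:
        for seg in self.segments:
            if seg.kind == "tm_strand" and seg.start <= position <= seg.end:
                return True
        return False

    def max_end(self) -> int:
        return max((s.end for s in self.segments), default=0)

    def validate_against(self, record: ProteinRecord) -> None:
        """Check that every segment fits inside ``record``'s sequence."""
        if self.protein_id != record.id:
            raise TopologyError(
                f"topology {self.protein_id!r} does not belong to record {record.id!r}"
            )
        if self.max_end() > len(record):
            raise TopologyError(
                f"{self.protein_id}: segment end {self.max_end()} beyond "
                f"sequence length {len(record)}"
            )


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into validated :class:`ProteinRecord` objects.

    Sequences are uppercased; CR/LF and internal whitespace are stripped.
    An empty file raises :class:`SequenceFormatError`; any non-canonical
    residue raises :class:`SequenceValidationError` naming the record, the
    1-based position and the offending character.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = "".join(str(entry.seq).split()).upper()
        rec = ProteinRecord(
            id=entry.id,
            description=entry.description[len(entry.id):].strip(),
            sequence=seq,
            source="file",
        )
        if rec.id in seen:
            raise SequenceFormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(rec)
    if not records:
        raise SequenceFormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Sequence[ProteinRecord], path: str | Path) -> None:
    """Write records as 60-column wrapped FASTA.

    ``read_fasta(write_fasta(x))`` reproduces ids and sequences exactly.
    """
    if not records:
        raise ValueError("write_fasta: empty record list")
    seqrecords = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=60)
        writer.write_file(seqrecords)


def _segments_from_rows(
    rows: Iterable[tuple[str, str, str, str]],
    origin: str,
) -> dict[str, list[TopologySegment]]:
    per_protein: dict[str, list[TopologySegment]] = {}
    for protein_id, kind, start, end in rows:
        try:
            seg = TopologySegment(kind=kind, start=int(start), end=int(end))
        except ValueError as exc:
            raise TopologyError(f"{origin}: bad row for {protein_id!r}: {exc}") from exc
        per_protein.setdefault(protein_id, []).append(seg)
    return per_protein


def parse_topology(
    path: str | Path, records: Sequence[ProteinRecord]
) -> list[Topology]:
    """Parse topology annotations from TSV or JSON.

    TSV columns: ``protein_id  kind  start  end`` (header optional).
    JSON: ``{protein_id: [{"kind": ..., "start": ..., "end": ...}, ...]}``.
    All protein ids must resolve to ``records``; segments are sorted and
    checked for overlaps and sequence-range violations.
    """
    path = Path(path)
    by_id = {r.id: r for r in records}
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        rows = [
            (pid, seg["kind"], seg["start"], seg["end"])
            for pid, segs in data.items()
            for seg in segs
        ]
    else:
        rows = []
        with open(path, newline="") as handle:
            for raw in csv.reader(handle, delimiter="\t"):
                if not raw or raw[0].startswith("#") or raw[0] == "protein_id":
                    continue
                if len(raw) != 4:
                    raise TopologyError(f"{path}: expected 4 columns, got {raw!r}")
                rows.append(tuple(raw))

    per_protein = _segments_from_rows(rows, str(path))
    topologies: list[Topology] = []
    for protein_id, segments in per_protein.items():
        if protein_id not in by_id:
            raise TopologyError(
                f"{path}: topology references unknown protein {protein_id!r}"
            )
        topo = Topology(
            protein_id=protein_id,
            segments=tuple(sorted(segments, key=lambda s: s.start)),
        )
        topo.validate_against(by_id[protein_id])
        topologies.append(topo)
    return topologies


def write_topology(topologies: Sequence[Topology], path: str | Path) -> None:
    """Write topologies as the 4-column TSV accepted by :func:`parse_topology`."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["protein_id", "kind", "start", "end"])
        for topo in topologies:
            for seg in topo.segments:
                writer.writerow([topo.protein_id, seg.kind, seg.start, seg.end])


UNIPROT_FASTA_URL = "https://rest.uniprot.org/uniprotkb/{accession}.fasta"


def fetch_uniprot(accession: str, timeout: float = 30.0) -> ProteinRecord:
    """Fetch one sequence from UniProt (thin convenience; needs network).

    The returned record keeps the UniProt accession as its id and is
    marked ``source='fetched'``.
    """
    url = UNIPROT_FASTA_URL.format(accession=accession)
    with urllib.request.urlopen(url, timeout=timeout) as response:
        text = response.read().decode()
    lines = text.splitlines()
    if not lines or not lines[0].startswith(">"):
        raise SequenceFormatError(f"UniProt returned no FASTA for {accession!r}")
    seq = "".join(line.strip() for line in lines[1:]).upper()
    return ProteinRecord(
        id=accession,
        description=lines[0][1:].strip(),
        sequence=seq,
        source="fetched",
    )
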