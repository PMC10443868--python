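"""The five-protein reference set and its loaders.

The study set is five bacterial/organellar outer-membrane beta-barrel
transporters with experimental structures: BamA (PDB 4K3B), Omp85/Sam50
(6WUT), FecA (1KMO), Tsx (1TLY) and OmpC (2J1N), with sequences under
UniProt accessions Q5F5W8, G2QFF9, P13036, P0A927 and P06996.

Loaders look for plain-text copies under a local reference directory
(``data/reference`` at the repository root by default, populated by
``scripts/fetch_reference_data.py``) and fall back to fetching from
UniProt / RCSB, which requires network access.  Nothing in the core
pipeline depends on these loaders.
"""

from __future__ import annotations

import urllib.request
from dataclasses import dataclass
from pathlib import Path

from .sequence_io import ProteinRecord, fetch_uniprot

RCSB_PDB_URL = "https://files.rcsb.org/download/{pdb_id}.pdb"


@dataclass(frozen=True)
class ReferenceProtein:
    name: str
    uniprot: str
    pdb_id: str
    chain: str
    #: Signal-peptide length per UniProt; the mature chain drops this
    #: many N-terminal residues.  0 where no signal peptide is annotated.
    signal_len: int


REFERENCE_SET = (
    ReferenceProtein("BamA", "Q5F5W8", "4K3B", "A", 24),
    ReferenceProtein("Omp85", "G2QFF9", "6WUT", "A", 0),
    ReferenceProtein("FecA", "P13036", "1KMO", "A", 33),
    ReferenceProtein("Tsx", "P0A927", "1TLY", "A", 22),
    ReferenceProtein("OmpC", "P06996", "2J1N", "A", 21),
)


def default_reference_dir() -> Path:
    return Path(__file__).resolve().parents[2] / "data" / "reference"


def load_or_fetch_sequence(
    accession: str, reference_dir: Path | None = None
) -> ProteinRecord:
    """Return the precursor sequence for a UniProt accession.

    Reads ``<reference_dir>/<accession>.fasta`` when present, otherwise
    fetches from UniProt (network required).
    """
    reference_dir = reference_dir or default_reference_dir()
    local = reference_dir / f"{accession}.fasta"
    if local.exists():
        from .sequence_io import read_fasta

        record = read_fasta(local)[0]
        return ProteinRecord(
            id=accession, description=record.description,
            sequence=record.sequence, source="file",
        )
    return fetch_uniprot(accession)


def mature_sequence(record: ProteinRecord, signal_len: int) -> ProteinRecord:
    """Drop an N-terminal signal peptide of ``signal_len`` residues."""
    if signal_len == 0:
        return record
    return ProteinRecord(
        id=record.id + "_mature",
        description=(record.description + f" (mature chain, -{signal_len} aa signal)").strip(),
        sequence=record.sequence[signal_len:],
        source=record.source,
    )


def load_or_fetch_pdb(
    pdb_id: str, reference_dir: Path | None = None, cache_dir: Path | None = None
) -> Path:
    """Return a local path to a PDB-format file for ``pdb_id``.

    Reads ``<reference_dir>/<pdb_id>.pdb`` when present, otherwise
    downloads from RCSB into ``cache_dir`` (network required).
    """
    reference_dir = reference_dir or default_reference_dir()
    local = reference_dir / f"{pdb_id}.pdb"
    if local.exists():
        return local
    cache_dir = cache_dir or reference_dir
    cache_dir.mkdir(parents=True, exist_ok=True)
    target = cache_dir / f"{pdb_id}.pdb"
    url = RCSB_PDB_URL.format(pdb_id=pdb_id)
    with urllib.request.urlopen(url, timeout=60) as response:
        target.write_bytes(response.read())
    return target
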