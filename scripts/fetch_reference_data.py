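#!/usr/bin/env python
"""Download the five-protein reference set into data/reference/.

Fetches the UniProt FASTA sequences (Q5F5W8, G2QFF9, P13036, P0A927,
P06996) and the PDB-format structures (4K3B, 6WUT, 1KMO, 1TLY, 2J1N)
needed by the paper-value acceptance tests.  Requires network access;
run once, after which the tests work offline:

    python scripts/fetch_reference_data.py
"""

from __future__ import annotations

import sys
from pathlib import Path

from qtybarrel.reference import (
    REFERENCE_SET,
    default_reference_dir,
    load_or_fetch_pdb,
    load_or_fetch_sequence,
)
from qtybarrel.sequence_io import write_fasta


def main() -> int:
    target = default_reference_dir()
    target.mkdir(parents=True, exist_ok=True)
    failures = 0
    for protein in REFERENCE_SET:
        try:
            record = load_or_fetch_sequence(protein.uniprot, target)
            fasta_path = target / f"{protein.uniprot}.fasta"
            if not fasta_path.exists():
                write_fasta([record], fasta_path)
            print(f"{protein.name}: {protein.uniprot} ({len(record)} aa)")
        except OSError as exc:
            failures += 1
            print(f"{protein.name}: FAILED to fetch {protein.uniprot}: {exc}")
        try:
            pdb_path = load_or_fetch_pdb(protein.pdb_id, target)
            print(f"{protein.name}: {pdb_path}")
        except OSError as exc:
            failures += 1
            print(f"{protein.name}: FAILED to fetch {protein.pdb_id}: {exc}")
    return 1 if failures else 0


if __name__ == "__main__":
    sys.exit(main())
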