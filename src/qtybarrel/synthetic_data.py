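"""Synthetic beta-barrel generator with known ground truth.

Builds toy outer-membrane-barrel instances — sequence, transmembrane
strand topology, and idealized CA coordinates on a cylinder — so that
the whole design/characterization pipeline can be exercised offline with
exact bookkeeping of what was planted.

The sequence model mirrors the statistical structure of real barrels:
within a TM strand, side chains alternate between the lipid-facing and
lumen-facing sides, so membrane-facing positions (even offsets) are
drawn hydrophobic (L/I/V/F) with a controllable probability while
lumen-facing and loop residues are polar.  The geometry places strand k
at azimuth 2*pi*k/n on a cylinder whose radius follows from the 4.6 Å
inter-strand spacing, with a 3.3 Å axial rise per residue, antiparallel
strands alternating z-direction, and loops as arcs above and below the
barrel.  The barrel shear number is not modeled (strands run parallel
to the axis): the geometry exists to exercise superposition and region
bookkeeping, not fold realism.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio.SeqUtils import seq3

from .sequence_io import ProteinRecord, Topology, TopologySegment
from .structure_compare import CAResidue, StructureModel

HYDROPHOBIC_AA = "LIVF"
POLAR_AA = "SNGADEKR"

INTER_STRAND_SPACING = 4.6  # Å between adjacent strand axes
AXIAL_RISE = 3.3  # Å per residue along the barrel axis


@dataclass(frozen=True)
class BarrelSpec:
    """Parameters of one synthetic barrel; deterministic given ``seed``."""

    n_strands: int = 16
    strand_len: int = 10
    loop_len: int = 6
    hydrophobic_fraction: float = 0.55
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_strands < 8 or self.n_strands % 2:
            raise ValueError("n_strands must be an even integer >= 8")
        if self.strand_len < 6:
            raise ValueError("strand_len must be >= 6")
        if self.loop_len < 2:
            raise ValueError("loop_len must be >= 2")
        if not 0.0 <= self.hydrophobic_fraction <= 1.0:
            raise ValueError("hydrophobic_fraction must be in [0, 1]")

    @property
    def total_length(self) -> int:
        return self.n_strands * (self.strand_len + self.loop_len)


@dataclass(frozen=True)
class SyntheticBarrel:
    """A generated barrel: record, topology, coordinates, and ground truth.

    ``truth`` records, per 1-based position, whether it is membrane- or
    lumen-facing (or loop), plus the exact planted count of L/I/V/F
    among TM positions.
    """

    spec: BarrelSpec
    record: ProteinRecord
    topology: Topology
    structure: StructureModel
    truth: dict


def make_toy_barrel(spec: BarrelSpec) -> SyntheticBarrel:
    """Generate one barrel from ``spec``; same seed, same bits out."""
    rng = np.random.default_rng(spec.seed)
    n, slen, llen = spec.n_strands, spec.strand_len, spec.loop_len

    radius = INTER_STRAND_SPACING / (2.0 * np.sin(np.pi / n))
    z_top = (slen - 1) * AXIAL_RISE

    sequence: list[str] = []
    facing: list[str] = []
    coords: list[tuple] = []
    segments: list[TopologySegment] = []
    planted = 0

    for k in range(n):
        theta = 2.0 * np.pi * k / n
        theta_next = 2.0 * np.pi * (k + 1) / n
        upward = k % 2 == 0  # antiparallel: even strands run bottom-to-top
        start = len(sequence) + 1
        for j in range(slen):
            membrane_facing = j % 2 == 0
            if membrane_facing and rng.random() < spec.hydrophobic_fraction:
                aa = HYDROPHOBIC_AA[rng.integers(len(HYDROPHOBIC_AA))]
                planted += 1
            else:
                aa = POLAR_AA[rng.integers(len(POLAR_AA))]
            sequence.append(aa)
            facing.append("membrane" if membrane_facing else "lumen")
            z = j * AXIAL_RISE if upward else z_top - j * AXIAL_RISE
            coords.append((radius * np.cos(theta), radius * np.sin(theta), z))
        segments.append(TopologySegment(kind="tm_strand", start=start,
                                        end=start + slen - 1))
        # Loop arcs over the rim the strand just reached: above the
        # barrel after an upward strand, below after a downward one.
        z_rim = z_top if upward else 0.0
        z_sign = 1.0 if upward else -1.0
        for j in range(llen):
            frac = (j + 1) / (llen + 1)
            aa = POLAR_AA[rng.integers(len(POLAR_AA))]
            sequence.append(aa)
            facing.append("loop")
            theta_j = theta + frac * (theta_next - theta)
            z = z_rim + z_sign * 2.0 * AXIAL_RISE * np.sin(np.pi * frac)
            coords.append((radius * np.cos(theta_j), radius * np.sin(theta_j), z))

    seq = "".join(sequence)
    record = ProteinRecord(
        id=f"toy_barrel_n{n}s{slen}_seed{spec.seed}",
        description=(
            f"synthetic {n}-stranded beta-barrel, strand_len={slen}, "
            f"loop_len={llen}, phob={spec.hydrophobic_fraction}"
        ),
        sequence=seq,
        source="synthetic",
    )
    topology = Topology(protein_id=record.id, segments=tuple(segments))
    structure = StructureModel(
        structure_id=record.id,
        chain_id="A",
        residues=tuple(
            CAResidue(number=i + 1, icode="", aa=seq[i], xyz=coords[i])
            for i in range(len(seq))
        ),
    )
    truth = {"facing": tuple(facing), "planted_livf": planted}
    return SyntheticBarrel(
        spec=spec, record=record, topology=topology, structure=structure, truth=truth
    )


def perturb_structure(
    model: StructureModel,
    sigma_strand: float,
    sigma_loop: float,
    topology: Topology,
    seed: int,
) -> StructureModel:
    """Add per-coordinate Gaussian noise with region-specific sigma (Å)."""
    if sigma_strand < 0 or sigma_loop < 0:
        raise ValueError("perturb_structure: sigmas must be >= 0")
    rng = np.random.default_rng(seed)
    residues = []
    for res in model.residues:
        sigma = sigma_strand if topology.is_tm(res.number) else sigma_loop
        xyz = np.asarray(res.xyz) + rng.normal(0.0, 1.0, size=3) * sigma
        residues.append(
            CAResidue(number=res.number, icode=res.icode, aa=res.aa,
                      xyz=tuple(xyz))
        )
    return StructureModel(
        structure_id=model.structure_id + "_perturbed",
        chain_id=model.chain_id,
        residues=tuple(residues),
    )


def _sheet_record(strand_no: int, n_strands: int, chain: str,
                  res3_start: str, start: int, res3_end: str, end: int) -> str:
    sense = 0 if strand_no == 1 else -1
    return (
        f"SHEET  {strand_no:3d} BAR{n_strands:2d} "
        f"{res3_start:>3s} {chain}{start:4d}  "
        f"{res3_end:>3s} {chain}{end:4d} {sense:2d}"
    )


def write_pdb(model: StructureModel, topology: Topology, path: str | Path) -> None:
    """Write a CA-only PDB file with SHEET records for the TM strands.

    Minimal fixed-column output (SHEET, ATOM, TER, END) sufficient for
    ``read_pdb_ca`` and ``strand_ranges_from_pdb`` to round-trip it.
    """
    by_number = {res.number: res for res in model.residues}
    strands = [s for s in topology.segments if s.kind == "tm_strand"]
    lines = []
    for i, seg in enumerate(strands, start=1):
        lines.append(
            _sheet_record(
                i, len(strands), model.chain_id,
                seq3(by_number[seg.start].aa).upper(), seg.start,
                seq3(by_number[seg.end].aa).upper(), seg.end,
            )
        )
    for serial, res in enumerate(model.residues, start=1):
        x, y, z = res.xyz
        lines.append(
            f"ATOM  {serial:5d}  CA  {seq3(res.aa).upper():>3s} "
            f"{model.chain_id}{res.number:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{'C':>2s}"
        )
    lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
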