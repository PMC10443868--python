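"""CA-based structure comparison.

Parses alpha-carbon coordinates and SHEET records from PDB-format files
(via gemmi), pairs residues between a native structure and a variant
model, and computes the least-squares optimal rigid superposition with
the Kabsch algorithm.  RMSD is reported over all paired CA atoms with no
outlier rejection by default; an optional single-pass trimmed mode
(drop pairs deviating more than a cutoff, re-fit once) is provided for
comparability with refinement-cycle tools such as PyMOL ``align``, whose
published RMSDs are computed after discarding poorly fitting pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np

from .sequence_io import Topology, TopologySegment


class StructureFormatError(ValueError):
    """PDB file lacks the records this module needs."""


class ChainLookupError(LookupError):
    """Requested chain is not present in the file."""


class PairingError(ValueError):
    """No residues could be paired between the two models."""


@dataclass(frozen=True)
class CAResidue:
    """One residue's CA atom: number, insertion code, one-letter code, xyz (Å)."""

    number: int
    icode: str
    aa: str
    xyz: tuple

    @property
    def key(self) -> tuple:
        # Insertion codes sort alphabetically after their residue number.
        return (self.number, self.icode)


@dataclass(frozen=True)
class StructureModel:
    """Ordered CA coordinate set for one chain."""

    structure_id: str
    chain_id: str
    residues: tuple

    def __len__(self) -> int:
        return len(self.residues)

    def coords(self) -> np.ndarray:
        return np.array([r.xyz for r in self.residues], dtype=float)


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid map of the second (mobile) set onto the first (fixed)."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_matched: int

    def transform(self, coords: np.ndarray) -> np.ndarray:
        """Apply the fitted rigid map to mobile-frame coordinates."""
        return coords @ self.rotation.T + self.translation


def _one_letter(residue_name: str) -> str | None:
    info = gemmi.find_tabulated_residue(residue_name)
    if info is None or not info.is_amino_acid():
        return None
    code = info.one_letter_code.upper()
    return code if code.isalpha() else None


def read_pdb_ca(path: str | Path, chain_id: str) -> StructureModel:
    """Extract one CA atom per residue from a PDB file.

    ATOM records only (HETATM ignored), first MODEL only, altloc blank
    or 'A'; the first qualifying CA per (residue number, insertion code)
    is kept, in file order.
    """
    path = Path(path)
    structure = gemmi.read_structure(str(path))
    if len(structure) == 0:
        raise StructureFormatError(f"{path}: no models")
    model = structure[0]
    chains = [ch for ch in model if ch.name == chain_id]
    if not chains:
        available = sorted({ch.name for ch in model})
        raise ChainLookupError(
            f"{path}: chain {chain_id!r} not found (available: {available})"
        )
    residues: list[CAResidue] = []
    seen: set[tuple] = set()
    for chain in chains:
        for res in chain:
            if res.het_flag != "A":
                continue
            aa = _one_letter(res.name)
            if aa is None:
                continue
            icode = res.seqid.icode.strip()
            key = (res.seqid.num, icode)
            if key in seen:
                continue
            for atom in res:
                if atom.name == "CA" and atom.altloc in ("\0", "", "A"):
                    residues.append(
                        CAResidue(
                            number=res.seqid.num,
                            icode=icode,
                            aa=aa,
                            xyz=(atom.pos.x, atom.pos.y, atom.pos.z),
                        )
                    )
                    seen.add(key)
                    break
    if not residues:
        raise StructureFormatError(f"{path}: chain {chain_id!r} has no CA atoms")
    return StructureModel(
        structure_id=path.stem, chain_id=chain_id, residues=tuple(residues)
    )


def strand_ranges_from_pdb(path: str | Path, chain_id: str) -> Topology:
    """Derive tm_strand segments for a chain from PDB SHEET records.

    Each SHEET record contributes one segment (initial to terminal
    residue number); overlapping or directly adjacent segments are
    merged.  A file with no SHEET records for the chain yields an empty
    topology with a warning — beta-strand annotations derived this way
    are an approximation to curated transmembrane annotations (SHEET
    covers all sheet structure, membrane-spanning or not).
    """
    path = Path(path)
    structure = gemmi.read_structure(str(path))
    ranges: list[tuple[int, int]] = []
    for sheet in structure.sheets:
        for strand in sheet.strands:
            if strand.start.chain_name != chain_id:
                continue
            lo = strand.start.res_id.seqid.num
            hi = strand.end.res_id.seqid.num
            if lo > hi:
                lo, hi = hi, lo
            ranges.append((lo, hi))
    protein_id = f"{path.stem}_{chain_id}"
    if not ranges:
        warnings.warn(
            f"{path}: no SHEET records for chain {chain_id!r}; empty topology"
        )
        return Topology(protein_id=protein_id, segments=())
    ranges.sort()
    merged = [ranges[0]]
    for lo, hi in ranges[1:]:
        if lo <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    segments = tuple(
        TopologySegment(kind="tm_strand", start=lo, end=hi) for lo, hi in merged
    )
    return Topology(protein_id=protein_id, segments=segments)


def pair_residues(
    a: StructureModel, b: StructureModel, mode: str = "by_number"
) -> list[tuple[int, int]]:
    """Pair residues between two models.

    ``by_number``: intersection of (residue number, insertion code),
    ascending.  ``by_order``: positional zip truncated to the shorter
    model.  Returns index pairs into ``a.residues`` / ``b.residues``.
    """
    if not a.residues or not b.residues:
        raise PairingError("pair_residues: empty model")
    if mode == "by_order":
        n = min(len(a), len(b))
        return [(i, i) for i in range(n)]
    if mode != "by_number":
        raise ValueError(f"unknown pairing mode {mode!r}")
    index_b = {res.key: j for j, res in enumerate(b.residues)}
    pairs = [
        (i, index_b[res.key])
        for i, res in enumerate(a.residues)
        if res.key in index_b
    ]
    pairs.sort(key=lambda p: a.residues[p[0]].key)
    if not pairs:
        raise PairingError(
            f"pair_residues: no common residue numbers between "
            f"{a.structure_id}/{a.chain_id} and {b.structure_id}/{b.chain_id}"
        )
    return pairs


def kabsch_superpose(
    coords_fixed: np.ndarray, coords_mobile: np.ndarray
) -> SuperpositionResult:
    """Least-squares optimal rigid superposition (Kabsch, via SVD).

    Finds the proper rotation R and translation t minimizing
    ``sum_i || R x_mobile_i + t - x_fixed_i ||^2`` and reports the RMSD
    over all pairs after the fit.  Requires at least 3 non-collinear
    points; the determinant sign of the SVD product is corrected so a
    reflection is never returned.
    """
    fixed = np.asarray(coords_fixed, dtype=float)
    mobile = np.asarray(coords_mobile, dtype=float)
    if fixed.shape != mobile.shape or fixed.ndim != 2 or fixed.shape[1] != 3:
        raise ValueError("kabsch_superpose: inputs must be matched (n, 3) arrays")
    n = fixed.shape[0]
    if n < 3:
        raise ValueError("kabsch_superpose: need at least 3 paired atoms")

    centroid_fixed = fixed.mean(axis=0)
    centroid_mobile = mobile.mean(axis=0)
    x = fixed - centroid_fixed
    y = mobile - centroid_mobile

    # Collinear (or coincident) point sets leave the rotation about the
    # common axis undetermined.
    for centered, label in ((x, "fixed"), (y, "mobile")):
        s = np.linalg.svd(centered, compute_uv=False)
        if s[1] <= 1e-8 * max(s[0], 1.0):
            raise ValueError(f"kabsch_superpose: degenerate ({label} set collinear)")

    h = y.T @ x
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    correction = np.diag([1.0, 1.0, d])
    rotation = vt.T @ correction @ u.T
    translation = centroid_fixed - rotation @ centroid_mobile

    moved = mobile @ rotation.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((moved - fixed) ** 2, axis=1))))
    return SuperpositionResult(
        rotation=rotation, translation=translation, rmsd=rmsd, n_matched=n
    )


def superpose_models(
    fixed: StructureModel,
    mobile: StructureModel,
    pairing: str = "by_number",
    trim: bool = False,
    trim_cutoff: float = 2.0,
) -> tuple[SuperpositionResult, list[tuple[int, int]]]:
    """Pair two models and superpose their CA atoms.

    With ``trim=True`` a single trimming pass is applied: pairs farther
    than ``trim_cutoff`` Å after the first fit are dropped and the fit is
    repeated once on the survivors (at least 3 must remain).
    """
    pairs = pair_residues(fixed, mobile, mode=pairing)
    ca_fixed = fixed.coords()[[i for i, _ in pairs]]
    ca_mobile = mobile.coords()[[j for _, j in pairs]]
    result = kabsch_superpose(ca_fixed, ca_mobile)
    if trim:
        dist = np.linalg.norm(result.transform(ca_mobile) - ca_fixed, axis=1)
        keep = dist <= trim_cutoff
        if keep.sum() >= 3 and keep.sum() < len(pairs):
            pairs = [p for p, k in zip(pairs, keep) if k]
            result = kabsch_superpose(ca_fixed[keep], ca_mobile[keep])
    return result, pairs


def rmsd_by_region(
    result: SuperpositionResult,
    fixed: StructureModel,
    mobile: StructureModel,
    pairs: Sequence[tuple[int, int]],
    topology: Topology,
) -> dict:
    """Split the global superposition's RMSD into strand and loop parts.

    Uses the single global fit (no re-fit per region); a residue pair is
    a strand pair when the fixed model's residue number falls inside a
    ``tm_strand`` segment of ``topology``.  A region with no pairs maps
    to ``None`` (undefined), never to zero.
    """
    ca_fixed = fixed.coords()[[i for i, _ in pairs]]
    ca_mobile = mobile.coords()[[j for _, j in pairs]]
    sq = np.sum((result.transform(ca_mobile) - ca_fixed) ** 2, axis=1)
    in_strand = np.array(
        [topology.is_tm(fixed.residues[i].number) for i, _ in pairs], dtype=bool
    )
    out: dict = {}
    for label, mask in (("tm_strand", in_strand), ("other", ~in_strand)):
        out[label] = float(np.sqrt(sq[mask].mean())) if mask.any() else None
    return out
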