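"""PDB parsing, residue pairing, and Kabsch superposition — checked
against a rotation-grid brute-force oracle and scipy's independent
implementation."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from conftest import random_rotation
from qtybarrel.sequence_io import Topology, TopologySegment
from qtybarrel.structure_compare import (
    CAResidue,
    ChainLookupError,
    PairingError,
    StructureFormatError,
    StructureModel,
    kabsch_superpose,
    pair_residues,
    read_pdb_ca,
    rmsd_by_region,
    strand_ranges_from_pdb,
    superpose_models,
)


def make_model(coords, numbers=None, structure_id="m", chain_id="A"):
    numbers = numbers or list(range(1, len(coords) + 1))
    return StructureModel(
        structure_id=structure_id,
        chain_id=chain_id,
        residues=tuple(
            CAResidue(number=n, icode="", aa="A", xyz=tuple(c))
            for n, c in zip(numbers, coords)
        ),
    )


def _eval_rotations(x, y, angles):
    mats = Rotation.from_euler("zyz", angles).as_matrix()
    moved = np.einsum("rij,nj->rni", mats, y)
    return np.sqrt(np.mean(np.sum((moved - x) ** 2, axis=2), axis=1))


def grid_min_rmsd(fixed, mobile, beam=300, levels=10, points=5):
    """Oracle: rotation-grid beam search over zyz Euler angles.

    For a fixed rotation the optimal translation aligns centroids, so
    the search runs over rotation space only.  A coarse exhaustive grid
    seeds a beam of candidate cells; each level refines every surviving
    cell with a halved step, so multiple basins are tracked to
    convergence instead of committing to one early.
    """
    x = fixed - fixed.mean(axis=0)
    y = mobile - mobile.mean(axis=0)
    spans = np.array([np.pi, np.pi / 2, np.pi])
    ax_centers = np.array([0.0, np.pi / 2, 0.0])  # beta spans [0, pi]
    axes = [np.linspace(c - s, c + s, 25) for c, s in zip(ax_centers, spans)]
    centers = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    rmsd = _eval_rotations(x, y, centers)
    order = np.argsort(rmsd)
    centers, best = centers[order[:beam]], float(rmsd[order[0]])
    spans = spans * (2.0 / 24)
    for _ in range(levels):
        offs = [np.linspace(-s, s, points) for s in spans]
        offsets = np.stack(np.meshgrid(*offs, indexing="ij"), axis=-1).reshape(-1, 3)
        candidates = (centers[:, None, :] + offsets[None, :, :]).reshape(-1, 3)
        rmsd = _eval_rotations(x, y, candidates)
        order = np.argsort(rmsd)
        centers = candidates[order[:beam]]
        best = min(best, float(rmsd[order[0]]))
        spans = spans / 2.0
    return best


class TestReadPdb:
    def test_ca_extraction_in_file_order(self, mini_pdb):
        model = read_pdb_ca(mini_pdb, "A")
        assert [r.number for r in model.residues] == list(range(3, 11))
        assert [r.aa for r in model.residues[:3]] == ["A", "L", "G"]

    def test_altloc_a_retained_b_dropped(self, mini_pdb):
        model = read_pdb_ca(mini_pdb, "A")
        res4 = next(r for r in model.residues if r.number == 4)
        assert res4.xyz == (2.0, 1.0, 0.0)

    def test_hetatm_ignored(self, mini_pdb):
        model = read_pdb_ca(mini_pdb, "A")
        assert all(r.number != 101 for r in model.residues)

    def test_missing_chain_is_lookup_error(self, mini_pdb):
        with pytest.raises(ChainLookupError, match="'Z'"):
            read_pdb_ca(mini_pdb, "Z")

    def test_no_ca_atoms_is_format_error(self, tmp_path):
        path = tmp_path / "noca.pdb"
        path.write_text(
            "ATOM      1  N   ALA A   3      1.000   2.000   3.000"
            "  1.00  0.00           N\nEND\n"
        )
        with pytest.raises(StructureFormatError, match="no CA"):
            read_pdb_ca(path, "A")


class TestStrandRanges:
    def test_sheet_records_become_segments(self, mini_pdb):
        topo = strand_ranges_from_pdb(mini_pdb, "A")
        assert [(s.start, s.end) for s in topo.segments] == [(3, 5), (8, 10)]
        assert all(s.kind == "tm_strand" for s in topo.segments)

    def test_overlapping_sheet_rows_merged(self, tmp_path):
        path = tmp_path / "overlap.pdb"
        path.write_text(
            "SHEET    1   A 2 ALA A   3  GLY A  10  0\n"
            "SHEET    2   A 2 SER A   8  VAL A  14 -1\n"
            "ATOM      1  CA  ALA A   3      1.000   2.000   3.000"
            "  1.00  0.00           C\nEND\n"
        )
        topo = strand_ranges_from_pdb(path, "A")
        assert [(s.start, s.end) for s in topo.segments] == [(3, 14)]

    def test_helix_only_file_warns_and_yields_empty(self, helix_only_pdb):
        with pytest.warns(UserWarning, match="no SHEET"):
            topo = strand_ranges_from_pdb(helix_only_pdb, "A")
        assert topo.segments == ()


class TestPairing:
    def test_identical_numbering_pairs_everything(self):
        coords = np.arange(15, dtype=float).reshape(5, 3)
        a, b = make_model(coords), make_model(coords + 1)
        assert pair_residues(a, b, "by_number") == [(i, i) for i in range(5)]

    def test_offset_numbering_mode_contrast(self):
        coords = np.arange(15, dtype=float).reshape(5, 3)
        a = make_model(coords)
        b = make_model(coords, numbers=list(range(101, 106)))
        with pytest.raises(PairingError):
            pair_residues(a, b, "by_number")
        assert pair_residues(a, b, "by_order") == [(i, i) for i in range(5)]

    def test_extra_cterminal_residues_excluded_by_number(self):
        coords = np.arange(30, dtype=float).reshape(10, 3)
        a = make_model(coords)
        b = make_model(coords[:5])
        assert len(pair_residues(a, b, "by_number")) == len(a) - 5


class TestKabsch:
    def test_identity_gives_zero_rmsd_and_identity_rotation(self):
        coords = np.random.default_rng(0).normal(size=(10, 3))
        result = kabsch_superpose(coords, coords)
        assert result.rmsd < 1e-12
        assert np.allclose(result.rotation, np.eye(3), atol=1e-10)

    def test_rigid_transform_recovered_to_zero_rmsd(self, rng):
        coords = rng.normal(size=(20, 3)) * 5
        for _ in range(10):
            rot = random_rotation(rng)
            shift = rng.normal(size=3) * 10
            moved = coords @ rot.T + shift
            assert kabsch_superpose(coords, moved).rmsd < 1e-9

    def test_90_degree_z_rotation_plus_translation(self):
        coords = np.array(
            [[1.0, 0, 0], [0, 1, 0], [0, 0, 1], [2, 1, -1]], dtype=float
        )
        rz = np.array([[0.0, -1, 0], [1, 0, 0], [0, 0, 1]])
        moved = coords @ rz.T + np.array([5.0, -3.0, 2.0])
        assert kabsch_superpose(coords, moved).rmsd < 1e-9

    def test_rmsd_symmetry(self, rng):
        a = rng.normal(size=(12, 3)) * 4
        b = a + rng.normal(size=(12, 3)) * 0.5
        assert kabsch_superpose(a, b).rmsd == pytest.approx(
            kabsch_superpose(b, a).rmsd, abs=1e-9
        )

    def test_rotation_always_proper_and_orthonormal(self, rng):
        for _ in range(20):
            a = rng.normal(size=(6, 3))
            b = rng.normal(size=(6, 3))
            res = kabsch_superpose(a, b)
            assert np.allclose(res.rotation @ res.rotation.T, np.eye(3), atol=1e-8)
            assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-8)

    def test_matches_rotation_grid_oracle_on_4_point_sets(self, rng):
        for _ in range(5):
            fixed = rng.normal(size=(4, 3)) * 3
            mobile = rng.normal(size=(4, 3)) * 3
            kabsch = kabsch_superpose(fixed, mobile).rmsd
            oracle = grid_min_rmsd(fixed, mobile)
            assert kabsch == pytest.approx(oracle, abs=1e-3)
            assert kabsch <= oracle + 1e-9  # no sampled rotation beats Kabsch

    def test_matches_scipy_align_vectors(self, rng):
        fixed = rng.normal(size=(30, 3)) * 5
        mobile = fixed + rng.normal(size=(30, 3)) * 0.8
        res = kabsch_superpose(fixed, mobile)
        rot, rssd = Rotation.align_vectors(
            fixed - fixed.mean(0), mobile - mobile.mean(0)
        )
        assert res.rmsd == pytest.approx(rssd / np.sqrt(30), abs=1e-8)
        assert np.allclose(res.rotation, rot.as_matrix(), atol=1e-6)

    def test_degenerate_inputs_rejected(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        good = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
        with pytest.raises(ValueError, match="collinear"):
            kabsch_superpose(good, line)
        with pytest.raises(ValueError, match="at least 3"):
            kabsch_superpose(good[:2], good[:2])

    def test_noise_response_matches_sigma_sqrt3(self, rng):
        # Isotropic Gaussian CA noise of s.d. sigma per coordinate gives
        # an expected RMSD close to sigma * sqrt(3) for large N.
        sigma = 0.5
        coords = rng.normal(size=(500, 3)) * 20
        noisy = coords + rng.normal(size=(500, 3)) * sigma
        rmsd = kabsch_superpose(coords, noisy).rmsd
        assert 0.8 * sigma * np.sqrt(3) <= rmsd <= 1.2 * sigma * np.sqrt(3)


class TestRegions:
    def _topology(self):
        return Topology("m", (TopologySegment(kind="tm_strand", start=1, end=10),))

    def test_all_strand_region_equals_global(self, rng):
        coords = rng.normal(size=(10, 3)) * 5
        noisy = coords + rng.normal(size=(10, 3)) * 0.3
        fixed, mobile = make_model(coords), make_model(noisy)
        result, pairs = superpose_models(fixed, mobile)
        regions = rmsd_by_region(result, fixed, mobile, pairs, self._topology())
        assert regions["tm_strand"] == pytest.approx(result.rmsd, abs=1e-12)
        assert regions["other"] is None

    def test_global_ms_is_weighted_mean_of_region_ms(self, rng):
        coords = rng.normal(size=(30, 3)) * 5
        noisy = coords + rng.normal(size=(30, 3)) * 0.4
        fixed, mobile = make_model(coords), make_model(noisy)
        topo = Topology("m", (TopologySegment(kind="tm_strand", start=1, end=12),))
        result, pairs = superpose_models(fixed, mobile)
        regions = rmsd_by_region(result, fixed, mobile, pairs, topo)
        n_strand, n_other = 12, 18
        weighted = (
            n_strand * regions["tm_strand"] ** 2 + n_other * regions["other"] ** 2
        ) / 30
        assert result.rmsd**2 == pytest.approx(weighted, abs=1e-10)

    def test_trimmed_mode_drops_gross_outliers(self, rng):
        coords = rng.normal(size=(200, 3)) * 6
        noisy = coords + rng.normal(size=(200, 3)) * 0.1
        noisy[5] += 25.0  # one gross outlier
        fixed, mobile = make_model(coords), make_model(noisy)
        full, _ = superpose_models(fixed, mobile, trim=False)
        trimmed, pairs = superpose_models(fixed, mobile, trim=True)
        assert trimmed.rmsd < full.rmsd
        assert trimmed.n_matched == 199
        assert all(fixed.residues[i].number != 6 for i, _ in pairs)
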