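import numpy as np
import pytest

from shapedock import mol_io
from shapedock.ligand_frame import (
    ENSEMBLE_TAGS,
    GridBox,
    canonical_template,
    collate_scores,
    emit_docking_job,
    farthest_pair,
    parse_vina_affinity,
    rotation_ensemble,
)
from shapedock.synth import FixtureSpec, random_molecule

from conftest import build_molecule, random_rigid_motion


def _distance_matrix(coords):
    diff = coords[:, None, :] - coords[None, :, :]
    return np.sqrt((diff ** 2).sum(axis=2))


@pytest.fixture
def ligand():
    spec = FixtureSpec(k=9, elements=("C",) * 5 + ("O", "N", "H", "H"), seed=99)
    return random_molecule(spec)


class TestFarthestPair:
    def test_unit_square_tie_rule(self):
        square = build_molecule(
            ["C"] * 4, [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]]
        )
        i, j, d = farthest_pair(square)
        assert (i, j) == (0, 2)  # both diagonals tie at sqrt(2); smallest (i, j) wins
        assert d == pytest.approx(np.sqrt(2))

    def test_collinear(self):
        mol = build_molecule(["C"] * 3, [[0, 0, 0], [1, 0, 0], [3, 0, 0]])
        assert farthest_pair(mol)[:2] == (0, 2)
        assert farthest_pair(mol)[2] == pytest.approx(3.0)

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(11)
        coords = rng.uniform(0, 10, size=(50, 3))
        mol = build_molecule(["C"] * 50, coords)
        i, j, d = farthest_pair(mol)
        brute = max(
            ((a, b, np.linalg.norm(coords[a] - coords[b]))
             for a in range(50) for b in range(a + 1, 50)),
            key=lambda t: t[2],
        )
        assert (i, j) == brute[:2]
        assert d == pytest.approx(brute[2], rel=1e-12)


class TestCanonicalTemplate:
    def test_idempotence(self, ligand):
        _, template = canonical_template(ligand)
        frame2, template2 = canonical_template(template)
        assert np.allclose(frame2.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(frame2.translation, 0.0, atol=1e-9)
        assert np.allclose(template2.coords, template.coords, atol=1e-9)

    def test_invariance_under_rigid_motions(self, ligand):
        _, reference = canonical_template(ligand)
        rng = np.random.default_rng(17)
        for _ in range(100):
            rot, trans, _ = random_rigid_motion(rng)
            moved = ligand.with_coords(ligand.coords @ rot + trans)
            _, template = canonical_template(moved)
            assert np.allclose(template.coords, reference.coords, atol=1e-8)

    def test_variance_ordering_and_det(self, ligand):
        frame, template = canonical_template(ligand)
        vx, vy, vz = frame.axis_variances
        assert vx >= vy >= vz
        assert np.linalg.det(frame.rotation) == pytest.approx(1.0, abs=1e-10)
        observed = (template.coords ** 2).mean(axis=0)
        assert np.allclose(observed, [vx, vy, vz], atol=1e-10)

    def test_variances_match_covariance_eigenvalues(self):
        mol = build_molecule(
            ["C"] * 5,
            [[0, 0, 0], [3.0, 0.2, 0.1], [-2.5, 1.0, -0.4], [0.5, -1.8, 0.9], [1.1, 0.6, -1.5]],
        )
        frame, _ = canonical_template(mol)
        centered = mol.coords - mol.coords.mean(axis=0)
        evals = np.sort(np.linalg.eigvalsh(centered.T @ centered / len(centered)))[::-1]
        assert np.allclose(frame.axis_variances, evals, atol=1e-10)

    def test_scale_equivariance(self, ligand):
        _, template = canonical_template(ligand)
        scaled = ligand.with_coords(ligand.coords * 3.5)
        _, template_scaled = canonical_template(scaled)
        assert np.allclose(template_scaled.coords, template.coords * 3.5, atol=1e-8)

    def test_chirality_preserved(self, chiral_molecule):
        # pad to k >= 4 with distinct variances is already satisfied
        _, canon = canonical_template(chiral_molecule)
        mirrored = chiral_molecule.coords.copy()
        mirrored[:, 0] = -mirrored[:, 0]
        _, canon_mirror = canonical_template(
            chiral_molecule.with_coords(mirrored)
        )
        # canonical forms of a chiral ligand and its mirror image must differ
        assert not np.allclose(canon.coords, canon_mirror.coords, atol=1e-6)

    def test_baseline_sign_convention(self, ligand):
        frame, template = canonical_template(ligand)
        i, _ = frame.baseline
        assert template.coords[i, 0] <= 1e-12

    def test_variance_tie_falls_back_to_baseline(self):
        # perfect square + apex: x/y variances tie exactly
        mol = build_molecule(
            ["C"] * 5,
            [[1, 0, 0], [0, 1, 0], [-1, 0, 0], [0, -1, 0], [0, 0, 0.3]],
        )
        with pytest.warns(UserWarning, match="degenerate"):
            frame, template = canonical_template(mol)
        vx, vy, vz = frame.axis_variances
        assert vx >= vy >= vz
        assert np.linalg.det(frame.rotation) == pytest.approx(1.0, abs=1e-10)

    def test_too_small_rejected(self):
        mol = build_molecule(["C"] * 3, np.eye(3))
        with pytest.raises(ValueError, match="k >= 4"):
            canonical_template(mol)


class TestRotationEnsemble:
    def test_tags(self, ligand):
        _, template = canonical_template(ligand)
        ensemble = rotation_ensemble(template)
        assert [t for t, _ in ensemble] == list(ENSEMBLE_TAGS)
        assert ensemble.template is template

    def test_group_closure_xy90(self, ligand):
        _, template = canonical_template(ligand)
        ensemble = rotation_ensemble(template)
        coords = template.coords
        once = ensemble["xy90"].coords
        # applying the xy90 member construction four times returns exactly
        rotated = coords
        for _ in range(4):
            rotated = rotation_ensemble(template.with_coords(rotated))["xy90"].coords
        assert np.array_equal(rotated, coords) or np.allclose(rotated, coords, atol=1e-12)
        assert not np.allclose(once, coords)

    def test_xy180_equals_xy90_twice(self, ligand):
        _, template = canonical_template(ligand)
        ensemble = rotation_ensemble(template)
        twice = rotation_ensemble(
            template.with_coords(ensemble["xy90"].coords)
        )["xy90"].coords
        assert np.allclose(ensemble["xy180"].coords, twice, atol=1e-12)

    def test_members_share_centroid_and_distances(self, ligand):
        _, template = canonical_template(ligand)
        ensemble = rotation_ensemble(template)
        ref_centroid = template.coords.mean(axis=0)
        ref_dists = np.sort(_distance_matrix(template.coords), axis=None)
        for tag, member in ensemble:
            assert np.allclose(member.coords.mean(axis=0), ref_centroid, atol=1e-12), tag
            dists = np.sort(_distance_matrix(member.coords), axis=None)
            assert np.allclose(dists, ref_dists, atol=1e-12), tag


class TestGridBox:
    def test_defaults(self):
        box = GridBox()
        assert box.center == (26.0, 10.0, 118.0)
        assert box.size == (20.0, 20.0, 20.0)

    def test_positive_sizes(self):
        with pytest.raises(ValueError):
            GridBox(size=(0.0, 20.0, 20.0))


class TestEmitDockingJob:
    @pytest.fixture
    def receptor(self, tmp_path):
        path = tmp_path / "receptor.pdbqt"
        path.write_text("ATOM      1  C   REC C   1       0.000   0.000   0.000  0.00  0.00    +0.000 C\n")
        return path

    def test_default_box_config_lines(self, ligand, receptor, tmp_path):
        _, template = canonical_template(ligand)
        ensemble = rotation_ensemble(template)
        outdir = tmp_path / "job"
        emit_docking_job(ensemble, GridBox(), receptor, outdir, ligand_format="xyz")
        config = (outdir / "config_none.txt").read_text()
        for line in ("center_x = 26", "center_y = 10", "center_z = 118",
                     "size_x = 20", "size_y = 20", "size_z = 20"):
            assert line in config

    def test_ligand_files_match_members(self, ligand, receptor, tmp_path):
        _, template = canonical_template(ligand)
        ensemble = rotation_ensemble(template)
        outdir = tmp_path / "job"
        manifest = emit_docking_job(ensemble, GridBox(), receptor, outdir,
                                    ligand_format="xyz")
        assert len(manifest) == 10
        for tag, member in ensemble:
            written = mol_io.read_structure(outdir / f"ligand_{tag}.xyz")
            assert np.allclose(written.coords, member.coords, atol=1e-7)

    def test_manifest_unique_tags(self, ligand, receptor, tmp_path):
        _, template = canonical_template(ligand)
        ensemble = rotation_ensemble(template)
        manifest = emit_docking_job(ensemble, GridBox(), receptor, tmp_path / "j",
                                    ligand_format="xyz")
        assert manifest["tag"].is_unique
        assert (tmp_path / "j" / "manifest.tsv").exists()

    def test_missing_receptor_rejected(self, ligand, tmp_path):
        _, template = canonical_template(ligand)
        ensemble = rotation_ensemble(template)
        with pytest.raises(FileNotFoundError):
            emit_docking_job(ensemble, GridBox(), tmp_path / "absent.pdbqt", tmp_path / "j")


VINA_LOG = """mode |   affinity | dist from best mode
     | (kcal/mol) | rmsd l.b.| rmsd u.b.
-----+------------+----------+----------
   1       {best}      0.000      0.000
   2       -6.9      1.521      2.842
   3       -6.1      3.011      4.220
"""


class TestCollateScores:
    def _write_logs(self, tmp_path, affinities):
        files = {}
        for tag, aff in affinities.items():
            path = tmp_path / f"result_{tag}.log"
            path.write_text(VINA_LOG.format(best=aff))
            files[tag] = path
        return files

    def test_constant_affinities_zero_spread(self, tmp_path):
        files = self._write_logs(tmp_path, {tag: -7.5 for tag in ENSEMBLE_TAGS})
        frame = collate_scores(files)
        assert len(frame) == 10
        assert frame.attrs["summary"]["spread"] == pytest.approx(0.0)

    def test_mixed_affinities(self, tmp_path):
        files = self._write_logs(tmp_path, {"none": -8.1, "xy90": -8.0, "xy180": -7.3})
        frame = collate_scores(files)
        summary = frame.attrs["summary"]
        assert summary["min"] == pytest.approx(-8.1)
        assert summary["max"] == pytest.approx(-7.3)
        assert summary["spread"] == pytest.approx(0.8)

    def test_pdbqt_remark_parsing(self, tmp_path):
        path = tmp_path / "out.pdbqt"
        path.write_text(
            "REMARK VINA RESULT:      -8.0      0.000      0.000\n"
            "REMARK VINA RESULT:      -7.1      2.100      3.000\n"
        )
        assert parse_vina_affinity(path) == pytest.approx(-8.0)

    def test_unparseable_file_warned_and_omitted(self, tmp_path):
        good = self._write_logs(tmp_path, {"none": -7.0})
        bad = tmp_path / "result_xy90.log"
        bad.write_text("no results here\n")
        with pytest.warns(UserWarning, match="xy90"):
            frame = collate_scores({**good, "xy90": bad})
        assert list(frame["tag"]) == ["none"]
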