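"""Torsions, pucker, frames and Cambridge-convention helical parameters."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from tetradna import geometry as g
from tetradna._standard_bases import STANDARD_BASES

FLIP = np.diag([1.0, -1.0, -1.0])


def random_frame(rng):
    return g.Frame(rng.normal(size=3), Rotation.random(random_state=rng).as_matrix())


class TestTorsion:
    def test_cis_trans(self):
        assert g.torsion([1, 1, 0], [0, 0, 0], [1, 0, 0], [2, 1, 0]) == pytest.approx(0.0)
        assert g.torsion([1, 1, 0], [0, 0, 0], [1, 0, 0], [2, -1, 0]) == pytest.approx(180.0)

    def test_mirror_image_flips_chirality(self, rng):
        pts = rng.normal(size=(4, 3))
        t = g.torsion(*pts)
        mirrored = pts * np.array([1, 1, -1])
        assert g.torsion(*mirrored) == pytest.approx((360.0 - t) % 360.0, abs=1e-9)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError, match="coincident"):
            g.torsion([0, 0, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0])
        with pytest.raises(ValueError, match="collinear"):
            g.torsion([0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0])


class TestPucker:
    def test_planar_ring(self):
        phase, amp = g.pucker(0, 0, 0, 0, 0)
        assert phase is None and amp == 0.0

    @pytest.mark.parametrize("phase,amp", [(162.0, 40.0), (18.0, 38.0), (300.0, 25.0)])
    def test_round_trip(self, phase, amp):
        nus = g.pucker_torsions(phase, amp)
        p, a = g.pucker(*nus)
        assert p == pytest.approx(phase, abs=1e-9)
        assert a == pytest.approx(amp, abs=1e-9)


class TestBasePairFrame:
    def test_preflipped_identity(self, rng):
        fw = random_frame(rng)
        fc = g.Frame(fw.origin, fw.axes @ FLIP)  # flips back onto fw
        mean, warn = g.base_pair_frame(fw, fc)
        assert not warn
        np.testing.assert_allclose(mean.axes, fw.axes, atol=1e-12)

    def test_symmetric_perturbation_cancels(self):
        base = np.eye(3)
        plus = Rotation.from_euler("x", 7, degrees=True).as_matrix()
        minus = Rotation.from_euler("x", -7, degrees=True).as_matrix()
        fw = g.Frame(np.zeros(3), base @ plus)
        fc = g.Frame(np.zeros(3), (base @ minus) @ FLIP)
        mean, _ = g.base_pair_frame(fw, fc)
        np.testing.assert_allclose(mean.axes, base, atol=1e-12)

    def test_against_quaternion_average_oracle(self, rng):
        for _ in range(20):
            fw, fc = random_frame(rng), random_frame(rng)
            fcf = g.Frame(fc.origin, fc.axes @ FLIP)
            # keep the pair within the averaging chart
            rel = Rotation.from_matrix(fw.axes.T @ fcf.axes)
            if np.linalg.norm(rel.as_rotvec()) > np.radians(150):
                continue
            mean, _ = g.base_pair_frame(fw, fc)
            # independent oracle: normalized mean of sign-aligned quaternions
            q1 = Rotation.from_matrix(fw.axes).as_quat()
            q2 = Rotation.from_matrix(fcf.axes).as_quat()
            if np.dot(q1, q2) < 0:
                q2 = -q2
            q = (q1 + q2) / np.linalg.norm(q1 + q2)
            oracle = Rotation.from_quat(q).as_matrix()
            np.testing.assert_allclose(mean.axes, oracle, atol=1e-8)


class TestInterBP:
    def test_identity(self, rng):
        f = random_frame(rng)
        assert np.allclose(g.inter_bp_params(f, f).as_tuple(), 0.0)

    def test_canonical_step(self):
        f1 = g.Frame(np.zeros(3), np.eye(3))
        f2 = g.Frame([0, 0, 3.4], Rotation.from_euler("z", 36, degrees=True).as_matrix())
        p = g.inter_bp_params(f1, f2)
        assert p.as_tuple() == pytest.approx((0, 0, 3.4, 0, 0, 36.0), abs=1e-12)

    def test_strand_flip_sign_rule(self, rng):
        for _ in range(20):
            f1, f2 = random_frame(rng), random_frame(rng)
            p = g.inter_bp_params(f1, f2)
            q = g.inter_bp_params(
                g.Frame(f2.origin, f2.axes @ FLIP), g.Frame(f1.origin, f1.axes @ FLIP)
            )
            np.testing.assert_allclose(
                q.as_tuple(),
                (-p.shift, p.slide, p.rise, -p.tilt, p.roll, p.twist),
                atol=1e-9,
            )

    def test_round_trip(self, rng):
        for _ in range(20):
            f1, f2 = random_frame(rng), random_frame(rng)
            p = g.inter_bp_params(f1, f2)
            f2b = g.reconstruct_frame(f1, p)
            np.testing.assert_allclose(f2b.origin, f2.origin, atol=1e-8)
            np.testing.assert_allclose(f2b.axes, f2.axes, atol=1e-8)

    def test_gimbal_safe_near_180(self):
        f1 = g.Frame(np.zeros(3), np.eye(3))
        f2 = g.Frame([0, 0, 3.4], Rotation.from_euler("z", 179, degrees=True).as_matrix())
        p = g.inter_bp_params(f1, f2)
        assert p.twist == pytest.approx(179.0, abs=1e-9)


class TestIntraBP:
    def test_coincident_preflip(self, rng):
        fw = random_frame(rng)
        fc = g.Frame(fw.origin, fw.axes @ FLIP)
        assert np.allclose(g.intra_bp_params(fw, fc).as_tuple(), 0.0, atol=1e-12)

    def test_pure_buckle(self):
        fw = g.Frame(np.zeros(3), np.eye(3))
        rot = Rotation.from_euler("x", 12, degrees=True).as_matrix()
        fc = g.Frame(np.zeros(3), rot @ FLIP)
        p = g.intra_bp_params(fw, fc)
        assert p.buckle == pytest.approx(12.0, abs=1e-9)
        assert (p.shear, p.stretch, p.stagger, p.propeller, p.opening) == pytest.approx(
            (0, 0, 0, 0, 0), abs=1e-9
        )

    def test_strand_swap_negates_shear_buckle_only(self, rng):
        for _ in range(20):
            fw, fc = random_frame(rng), random_frame(rng)
            p = g.intra_bp_params(fw, fc)
            q = g.intra_bp_params(fc, fw)
            np.testing.assert_allclose(
                q.as_tuple(),
                (-p.shear, p.stretch, p.stagger, -p.buckle, p.propeller, p.opening),
                atol=1e-9,
            )


class TestWCDistances:
    @staticmethod
    def ideal_pair(watson, crick):
        w = {k: np.array(v) for k, v in STANDARD_BASES[watson].items()}
        c = {k: FLIP @ np.array(v) for k, v in STANDARD_BASES[crick].items()}
        return w, c

    def test_ideal_pair_below_cutoff(self):
        for pt in ("AT", "GC", "CG", "TA"):
            w, c = self.ideal_pair(pt[0], pt[1])
            assert all(d < 3.5 for d in g.wc_heavy_atom_distances(pt, w, c))

    def test_separated_pair_above_cutoff(self):
        w, c = self.ideal_pair("A", "T")
        c = {k: v + np.array([0, 10.0, 0]) for k, v in c.items()}
        assert all(d > 3.5 for d in g.wc_heavy_atom_distances("AT", w, c))

    def test_bond_counts(self):
        w, c = self.ideal_pair("G", "C")
        assert len(g.wc_heavy_atom_distances("GC", w, c)) == 3
        w, c = self.ideal_pair("A", "T")
        assert len(g.wc_heavy_atom_distances("AT", w, c)) == 2

    def test_missing_atom_named(self):
        w, c = self.ideal_pair("A", "T")
        del w["N6"]
        with pytest.raises(KeyError, match="N6"):
            g.wc_heavy_atom_distances("AT", w, c)


class TestFitStandardFrame:
    def test_exact_recovery(self, rng):
        rot = Rotation.random(random_state=rng).as_matrix()
        t = rng.normal(size=3)
        obs = {k: rot @ np.array(v) + t for k, v in STANDARD_BASES["G"].items()}
        frame, rmsd = g.fit_standard_frame(obs, "G")
        np.testing.assert_allclose(frame.origin, t, atol=1e-8)
        np.testing.assert_allclose(frame.axes, rot, atol=1e-8)
        assert rmsd < 1e-8

    def test_noisy_recovery(self, rng):
        t = np.array([5.0, -2.0, 1.0])
        obs = {
            k: np.array(v) + t + rng.normal(0, 0.05, 3)
            for k, v in STANDARD_BASES["A"].items()
        }
        frame, _ = g.fit_standard_frame(obs, "A")
        assert np.linalg.norm(frame.origin - t) < 0.05

    def test_rmsd_matches_scipy_kabsch_oracle(self, rng):
        from tetradna._standard_bases import RING_ATOMS

        obs = {
            k: np.array(v) + rng.normal(0, 0.1, 3) for k, v in STANDARD_BASES["C"].items()
        }
        _, rmsd = g.fit_standard_frame(obs, "C")
        std = np.array([STANDARD_BASES["C"][a] for a in RING_ATOMS["C"]])
        pts = np.array([obs[a] for a in RING_ATOMS["C"]])
        _, rssd = Rotation.align_vectors(
            pts - pts.mean(axis=0), std - std.mean(axis=0)
        )
        assert rmsd == pytest.approx(rssd / np.sqrt(len(std)), rel=1e-6)

    def test_too_few_atoms(self):
        with pytest.raises(ValueError, match="at least 3"):
            g.fit_standard_frame({"N1": np.zeros(3), "C2": np.ones(3)}, "C")


class TestPDBRoundTrip:
    def test_fixture_read(self, tmp_path, rng):
        # write a minimal one-pair PDB from the standard geometry and re-read
        lines = []
        serial = 1
        for chain, base, flip in (("A", "G", False), ("B", "C", True)):
            for name, xyz in STANDARD_BASES[base].items():
                x, y, z = (FLIP @ np.array(xyz)) if flip else np.array(xyz)
                atom = name.replace("'", "'")
                lines.append(
                    f"ATOM  {serial:5d} {atom:<4s} D{base:<2s} {chain}   1    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
                )
                serial += 1
        path = tmp_path / "pair.pdb"
        path.write_text("\n".join(lines) + "\nEND\n")
        residues = g.read_pdb_residues(path)
        assert len(residues) == 2
        w = next(r for r in residues if r["chain"] == "A")
        c = next(r for r in residues if r["chain"] == "B")
        dists = g.wc_heavy_atom_distances("GC", w["atoms"], c["atoms"])
        assert all(d < 3.5 for d in dists)
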