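import numpy as np
import pytest

from scaffoldmatch.motif import HelixLoopHelixMotif
from scaffoldmatch.superpose import (
    ce_style_align,
    framework_align,
    kabsch,
    rank_candidates,
)
from scaffoldmatch.synthetic import FixtureRecipe, HelixParams, build_hlh

from conftest import ca_structure, horn_rmsd


class TestKabsch:
    def test_identity(self):
        P = np.random.default_rng(0).normal(size=(10, 3))
        res = kabsch(P, P)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(res.rotation, np.eye(3), atol=1e-9)

    def test_exact_recovery_of_rigid_copy(self, random_rigid):
        rng = np.random.default_rng(1)
        P = rng.normal(size=(12, 3)) * 5
        R, t = random_rigid(2)
        Q = (P - t) @ R  # so that R Q + t = P
        res = kabsch(P, Q)
        assert res.rmsd < 1e-9
        assert np.allclose(res.apply(Q), P, atol=1e-8)

    def test_agrees_with_quaternion_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            P = rng.normal(size=(10, 3)) * 8
            Q = rng.normal(size=(10, 3)) * 8
            assert kabsch(P, Q).rmsd == pytest.approx(horn_rmsd(P, Q), abs=1e-8)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        P, Q = rng.normal(size=(2, 15, 3))
        assert kabsch(P, Q).rmsd == pytest.approx(kabsch(Q, P).rmsd, abs=1e-9)

    def test_invariance_under_common_transform(self, random_rigid):
        rng = np.random.default_rng(4)
        P, Q = rng.normal(size=(2, 9, 3)) * 4
        base = kabsch(P, Q).rmsd
        R, t = random_rigid(5)
        assert kabsch(P @ R.T + t, Q @ R.T + t).rmsd == pytest.approx(base, abs=1e-9)

    def test_rotation_is_proper(self):
        # reflection-prone case: nearly planar point sets
        rng = np.random.default_rng(6)
        P = rng.normal(size=(8, 3)); P[:, 2] *= 1e-4
        Q = rng.normal(size=(8, 3)); Q[:, 2] *= 1e-4
        res = kabsch(P, Q)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="at least 3"):
            kabsch(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_flagged(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        assert kabsch(line, line).ill_conditioned


class TestFrameworkAlign:
    def test_rigid_copy_rmsd_zero(self, hlh_clean):
        s, truth = hlh_clean
        recipe = FixtureRecipe(
            helix1=HelixParams(10), loop_len=5, helix2=HelixParams(10),
            cys_positions=(2, 9, 18, 25), disulfide_pairs=((1, 4), (2, 3)),
            transform_seed=11,
        )
        s2, _ = build_hlh(recipe)
        motif = HelixLoopHelixMotif(chain="A", helix1=truth.helix1,
                                    loop=truth.loop, helix2=truth.helix2)
        res = framework_align(motif, s, motif, s2)
        assert res.rmsd < 1e-9
        assert res.loop_rmsd < 1e-9
        assert res.mode == "framework"

    def test_offset_optimization_beats_end_anchoring(self, hlh_clean):
        """A candidate whose helix2 is one residue longer must be matched at
        the offset minimizing RMSD, found by exhaustive enumeration."""
        s, truth = hlh_clean
        longer = FixtureRecipe(helix1=HelixParams(10), loop_len=5,
                               helix2=HelixParams(11))
        s2, t2 = build_hlh(longer)
        qmotif = HelixLoopHelixMotif(chain="A", helix1=truth.helix1,
                                     loop=truth.loop, helix2=truth.helix2)
        cmotif = HelixLoopHelixMotif(chain="A", helix1=t2.helix1,
                                     loop=t2.loop, helix2=t2.helix2)
        res = framework_align(qmotif, s, cmotif, s2)
        # oracle: try both possible helix2 offsets with fixed correspondence
        rmsds = []
        for off in (0, 1):
            q_ids = qmotif.helix1_ids + qmotif.helix2_ids
            c_ids = cmotif.helix1_ids + [i + off for i in cmotif.helix2_ids[:10]]
            P = s.ca_coords("A", q_ids)
            Q = s2.ca_coords("A", c_ids)
            rmsds.append(kabsch(P, Q).rmsd)
        assert res.rmsd == pytest.approx(min(rmsds), abs=1e-9)

    def test_correspondence_strictly_increasing(self, hlh_clean):
        s, truth = hlh_clean
        motif = HelixLoopHelixMotif(chain="A", helix1=truth.helix1,
                                    loop=truth.loop, helix2=truth.helix2)
        res = framework_align(motif, s, motif, s)
        qs = [q for q, _ in res.correspondence]
        cs = [c for _, c in res.correspondence]
        assert qs == sorted(qs) and len(set(qs)) == len(qs)
        assert cs == sorted(cs) and len(set(cs)) == len(cs)
        # loop residues never enter the fitted correspondence
        assert not set(qs) & set(motif.loop_ids)


class TestCeStyle:
    def test_identical_chains_full_path(self, hlh_clean):
        s, _ = hlh_clean
        P = s.ca_coords("A")
        res = ce_style_align(P, P)
        assert res.rmsd < 1e-9
        assert res.aligned_length >= len(P) - 7

    def test_unrelated_random_coils(self):
        rng = np.random.default_rng(7)
        # self-avoiding-ish random walks with 3.8 A steps
        def walk(seed):
            r = np.random.default_rng(seed)
            steps = r.normal(size=(40, 3))
            steps = 3.8 * steps / np.linalg.norm(steps, axis=1, keepdims=True)
            return np.cumsum(steps, axis=0)
        res = ce_style_align(walk(1), walk(2))
        assert res is None or res.rmsd > 1.0

    def test_noisy_helix_rmsd_band(self):
        h = __import__("scaffoldmatch.synthetic", fromlist=["build_helix_coords"])
        P = h.build_helix_coords(HelixParams(20))
        rmsds = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            Q = P + rng.normal(0, 0.3, P.shape)
            res = ce_style_align(P, Q)
            assert res is not None
            rmsds.append(res.rmsd)
        assert 0.2 <= float(np.median(rmsds)) <= 0.5


class TestRanking:
    def _motif(self, truth):
        return HelixLoopHelixMotif(chain="A", helix1=truth.helix1,
                                   loop=truth.loop, helix2=truth.helix2)

    def test_exact_copy_ranks_first(self, hlh_clean):
        s, truth = hlh_clean
        qm = self._motif(truth)
        noisy = []
        for i, sigma in enumerate([0.0, 0.5, 1.0]):
            r = FixtureRecipe(helix1=HelixParams(10), loop_len=5,
                              helix2=HelixParams(10), noise_sigma=sigma,
                              transform_seed=100 + i)
            cs, ct = build_hlh(r)
            cs.id = f"CAND{i}"
            noisy.append((self._motif(ct), cs))
        df = rank_candidates(qm, s, noisy, mode="framework")
        assert df.iloc[0]["source"] == "CAND0"
        assert df.iloc[0]["rmsd"] < 1e-9
        assert list(df["rmsd"]) == sorted(df["rmsd"])

    def test_candidates_without_motif_skipped(self, hlh_clean):
        s, truth = hlh_clean
        df = rank_candidates(self._motif(truth), s, [(None, s)], mode="framework")
        assert len(df) == 0

    def test_noise_order_mostly_preserved(self, hlh_clean):
        s, truth = hlh_clean
        qm = self._motif(truth)
        agree = 0
        n_trials = 30
        sigmas = [0.1, 0.4, 0.8, 1.2]
        for trial in range(n_trials):
            lib = []
            for i, sig in enumerate(sigmas):
                r = FixtureRecipe(helix1=HelixParams(10), loop_len=5,
                                  helix2=HelixParams(10), noise_sigma=sig,
                                  transform_seed=1000 + trial * 10 + i)
                cs, ct = build_hlh(r)
                cs.id = f"N{i}"
                lib.append((self._motif(ct), cs))
            df = rank_candidates(qm, s, lib, mode="framework")
            agree += list(df["source"]) == ["N0", "N1", "N2", "N3"]
        assert agree / n_trials >= 0.9
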