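"""Ensemble reading, pair-class distances, orientation statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from deeroligo.geometry import (
    CuSite,
    PairClass,
    coordination_normal,
    distance_distribution,
    orientation_distribution,
    pair_distances,
    read_ensemble,
    summarize_distances,
    write_ensemble,
)
from deeroligo.synthetic import EnsembleSpec, generate_ensemble


def _random_rotation(rng):
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


class TestReadEnsemble:
    def test_round_trip_preserves_models_and_sites(self, small_cub_ensemble, tmp_path):
        path = tmp_path / "ens.pdb"
        write_ensemble(small_cub_ensemble, path)
        back = read_ensemble(path)
        assert len(back) == 5
        assert all(len(c.cu_sites) == 4 for c in back)
        orig = small_cub_ensemble.configurations[0]
        assert np.allclose(
            back.configurations[0].chains["A"], orig.chains["A"], atol=1e-3
        )

    def test_model_missing_ligand_is_skipped(self, small_cub_ensemble, tmp_path):
        path = tmp_path / "ens.pdb"
        write_ensemble(small_cub_ensemble, path)
        text = path.read_text().splitlines(keepends=True)
        # drop the first His13 ligand record of the second model
        out, in_model2, dropped = [], False, False
        for line in text:
            if line.startswith("MODEL") and line.split()[1] == "2":
                in_model2 = True
            if in_model2 and not dropped and "L13" in line:
                dropped = True
                continue
            out.append(line)
        path.write_text("".join(out))
        back = read_ensemble(path)
        assert len(back) == 4

    def test_angstrom_to_nm_conversion(self, tmp_path, small_cub_ensemble):
        path = tmp_path / "ens.pdb"
        write_ensemble(small_cub_ensemble, path)
        back = read_ensemble(path)
        # PDB stores Angstrom: a Cu pair written 10x further apart in the
        # file than the nm distance the API reports
        conf = back.configurations[0]
        sA, sB = conf.site("A"), conf.site("B")
        d_nm = np.linalg.norm(sA.cu - sB.cu)
        with open(path) as fh:
            cu_lines = [
                line for line in fh if line.startswith("HETATM") and " CU " in line
            ]
        xyzA = np.array([float(cu_lines[0][30 + 8 * i : 38 + 8 * i]) for i in range(3)])
        xyzB = np.array([float(cu_lines[1][30 + 8 * i : 38 + 8 * i]) for i in range(3)])
        assert np.linalg.norm(xyzA - xyzB) == pytest.approx(10.0 * d_nm, rel=1e-3)


class TestPairDistances:
    def test_partition_covers_all_pairs_once(self, small_cub_ensemble):
        n_intra = pair_distances(small_cub_ensemble, PairClass.INTRA_DIMER).size
        n_inter = pair_distances(small_cub_ensemble, PairClass.INTER_DIMER).size
        n_cu = 4
        assert n_intra + n_inter == len(small_cub_ensemble) * (n_cu * (n_cu - 1) // 2)

    def test_rigid_motion_invariance(self, small_cub_ensemble):
        rng = np.random.default_rng(5)
        ref = pair_distances(small_cub_ensemble, PairClass.INTER_DIMER)
        moved = generate_ensemble(EnsembleSpec(n_configs=5, seed=11))
        for conf in moved:
            R, t = _random_rotation(rng), rng.uniform(-5, 5, 3)
            conf.chains = {k: v @ R.T + t for k, v in conf.chains.items()}
            conf.cu_sites = [
                CuSite(s.chain, R @ s.cu + t, R @ s.n_his6 + t, R @ s.n_his13 + t)
                for s in conf.cu_sites
            ]
        assert np.allclose(pair_distances(moved, PairClass.INTER_DIMER), ref, atol=1e-9)

    def test_inter_mean_recovery(self, cub_ensemble_1k):
        # the four cross distances of a configuration share one rigid
        # placement, so the honest standard error is the cluster SE over
        # per-configuration means
        per_conf = np.array(
            [
                np.mean(
                    [
                        np.linalg.norm(c.site(a).cu - c.site(b).cu)
                        for a, b in (("A", "C"), ("A", "D"), ("B", "C"), ("B", "D"))
                    ]
                )
                for c in cub_ensemble_1k
            ]
        )
        se = per_conf.std(ddof=1) / np.sqrt(per_conf.size)
        assert abs(per_conf.mean() - 3.6) <= 3 * se


class TestDistanceDistribution:
    def test_unit_integral_regardless_of_sample_size(self):
        rng = np.random.default_rng(0)
        for n in (100, 10000):
            centers, dens = distance_distribution(rng.normal(3.0, 0.5, n))
            assert np.trapezoid(dens, centers) == pytest.approx(1.0, abs=1e-9)

    def test_single_value_bin_height(self):
        centers, dens = distance_distribution(np.full(7, 2.34), bin_width=0.1)
        assert dens.max() == pytest.approx(10.0)
        assert (dens > 0).sum() == 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            distance_distribution(np.array([]))


class TestSummarizeDistances:
    def test_hand_computed_example(self):
        mean, sd = summarize_distances(np.array([1.0, 2.0, 3.0]))
        assert mean == pytest.approx(2.0)
        assert sd == pytest.approx(np.sqrt(2.0 / 3.0))

    def test_constant_list_zero_sd(self):
        assert summarize_distances(np.full(5, 1.7))[1] == 0.0

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            summarize_distances(np.array([1.0]))


class TestCoordinationNormal:
    def test_right_hand_rule(self):
        site = CuSite("A", np.zeros(3), np.array([0.2, 0, 0]), np.array([0, 0.2, 0]))
        assert np.allclose(coordination_normal(site), [0, 0, 1])

    def test_ligand_swap_negates_normal(self):
        cu = np.array([1.0, 1.0, 1.0])
        l1, l2 = cu + [0.2, 0, 0], cu + [0.1, 0.15, 0]
        a = coordination_normal(CuSite("A", cu, l1, l2))
        b = coordination_normal(CuSite("A", cu, l2, l1))
        assert np.allclose(a, -b)

    def test_collinear_bonds_rejected(self):
        site = CuSite("A", np.zeros(3), np.array([0.2, 0, 0]), np.array([0.3, 0, 0]))
        with pytest.raises(ValueError):
            coordination_normal(site)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(seed=st.integers(min_value=0, max_value=10_000))
    def test_rotation_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        cu = rng.uniform(-1, 1, 3)
        l1 = cu + 0.2 * rng.standard_normal(3) * 0.5
        l2 = cu + 0.2 * rng.standard_normal(3) * 0.5
        try:
            n = coordination_normal(CuSite("A", cu, l1, l2))
        except ValueError:
            return  # collinear draw
        R = _random_rotation(rng)
        n_rot = coordination_normal(CuSite("A", R @ cu, R @ l1, R @ l2))
        assert np.allclose(n_rot, R @ n, atol=1e-10)


class TestOrientationDistribution:
    def test_scalar_products_bounded_and_normals_unit(self, cub_ensemble_1k):
        stats = orientation_distribution(cub_ensemble_1k, PairClass.INTRA_DIMER)
        assert np.all(stats.scalar_products >= -1.0)
        assert np.all(stats.scalar_products <= 1.0)
        conf = cub_ensemble_1k.configurations[0]
        for site in conf.cu_sites:
            assert np.linalg.norm(coordination_normal(site)) == pytest.approx(
                1.0, abs=1e-12
            )

    def test_angle_spread_recovery(self, cub_ensemble_1k):
        stats = orientation_distribution(cub_ensemble_1k, PairClass.INTRA_DIMER)
        assert stats.angle_sd_deg == pytest.approx(20.0, abs=2.0)

    def test_antiparallel_pair_scalar_product(self):
        cu = np.zeros(3)
        s1 = CuSite("A", cu, np.array([0.2, 0, 0]), np.array([0, 0.2, 0]))
        s2 = CuSite("B", cu + 2.0, cu + 2.0 + np.array([0, 0.2, 0]), cu + 2.0 + np.array([0.2, 0, 0]))
        d = float(np.dot(coordination_normal(s1), coordination_normal(s2)))
        assert d == pytest.approx(-1.0)
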