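"""Titration solvers against closed forms and exact enumeration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phfold.constants import DEFAULT_KT, LN10
from phfold.structures import with_intrinsic_pkas
from phfold.titration import (
    ApparentPka,
    PhGrid,
    apparent_pka,
    enumerate_titration,
    independent_titration,
    interaction_matrix,
    mc_titration,
    meanfield_titration,
    read_pka_table,
    unfolded_titration,
)

from conftest import make_site, oracle_fixture


class TestPhGrid:
    def test_inclusive_endpoints(self):
        g = PhGrid(4.0, 8.0, 0.1)
        assert g.n_points == 41
        assert g.values[0] == 4.0
        assert g.values[-1] == pytest.approx(8.0)

    @pytest.mark.parametrize("start,end,step", [
        (8.0, 4.0, 0.1), (4.0, 8.0, -0.1), (4.0, 8.0, 0.3),
    ])
    def test_invalid_grids_rejected(self, start, end, step):
        with pytest.raises(ValueError):
            PhGrid(start, end, step)


class TestInteractionMatrix:
    def test_two_sites_direct_formula(self):
        sites = [make_site("ASP", 2), make_site("GLU", 4, center=(10, 0, 0))]
        W = interaction_matrix(sites, dielectric=20.0, ionic_strength=0.0)
        assert W[0, 1] == pytest.approx(332.0636 / (20.0 * 10.0), rel=1e-12)
        assert W[0, 0] == 0.0

    def test_infinite_dielectric_limit(self):
        sites = [make_site("ASP", 2), make_site("GLU", 4, center=(10, 0, 0))]
        W = interaction_matrix(sites, dielectric=1e9, ionic_strength=0.0)
        assert np.all(np.abs(W) < 1e-6)

    def test_three_site_hand_matrix(self):
        sites = [
            make_site("ASP", 2, center=(0, 0, 0)),
            make_site("GLU", 4, center=(10, 0, 0)),
            make_site("HIS", 6, center=(0, 5, 0)),
        ]
        W = interaction_matrix(sites, dielectric=20.0, ionic_strength=0.0)
        expected_01 = 332.0636 / (20.0 * 10.0)
        expected_02 = 332.0636 / (20.0 * 5.0)
        expected_12 = 332.0636 / (20.0 * math.sqrt(125.0))
        np.testing.assert_allclose(
            W, [[0, expected_01, expected_02],
                [expected_01, 0, expected_12],
                [expected_02, expected_12, 0]], rtol=1e-12,
        )

    def test_screening_reduces_coupling(self):
        sites = [make_site("ASP", 2), make_site("GLU", 4, center=(10, 0, 0))]
        bare = interaction_matrix(sites, 20.0, ionic_strength=0.0)
        screened = interaction_matrix(sites, 20.0, ionic_strength=0.15)
        assert screened[0, 1] < bare[0, 1]

    def test_coincident_centers_error_names_pair(self):
        sites = [make_site("ASP", 2), make_site("GLU", 4)]
        with pytest.raises(ValueError, match="coincident"):
            interaction_matrix(sites, 20.0)

    def test_clash_floor_clamps_short_distances(self):
        sites = [make_site("ASP", 2), make_site("GLU", 4, center=(0.5, 0, 0))]
        W = interaction_matrix(sites, 20.0, ionic_strength=0.0)
        assert W[0, 1] == pytest.approx(332.0636 / (20.0 * 2.0))


class TestEnumerate:
    def test_henderson_hasselbalch_midpoint(self, grid):
        site = make_site("ASP", 2, intrinsic_pka=5.0)
        res = enumerate_titration([site], np.zeros((1, 1)), grid)
        k = 10  # pH 5.0
        assert res.theta[k, 0] == pytest.approx(0.5)
        assert res.Q[k] == pytest.approx(-0.5)

    def test_decoupled_limit_equals_independent(self, grid):
        sites = [make_site("ASP", 2, intrinsic_pka=4.2),
                 make_site("HIS", 4, intrinsic_pka=6.8, center=(10, 0, 0)),
                 make_site("LYS", 6, intrinsic_pka=10.5, center=(0, 10, 0))]
        res = enumerate_titration(sites, np.zeros((3, 3)), grid)
        ind = independent_titration(sites, [4.2, 6.8, 10.5], grid)
        np.testing.assert_allclose(res.theta, ind.theta, atol=1e-12)

    def test_coupled_acid_pair_against_hand_enumeration(self):
        # two acids, intrinsic pKa 4.0, W = 1.36 kcal/mol, at pH 4.0:
        # the pH term vanishes for all four microstates and only the
        # doubly-deprotonated state pays the coupling penalty, so
        # theta = 2 / (3 + exp(-W/kT)).
        W_val, kT = 1.36, DEFAULT_KT
        sites = [make_site("ASP", 2, intrinsic_pka=4.0),
                 make_site("ASP", 4, intrinsic_pka=4.0, center=(5, 0, 0))]
        W = np.array([[0.0, W_val], [W_val, 0.0]])
        res = enumerate_titration(sites, W, PhGrid(4.0, 8.0, 0.1), kT=kT)
        expected = 2.0 / (3.0 + math.exp(-W_val / kT))
        assert res.theta[0, 0] == pytest.approx(expected, abs=1e-12)
        assert res.theta[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_site_cap_enforced(self, grid):
        sites = [make_site("ASP", 2 * i, center=(7.0 * i, 0, 0))
                 for i in range(1, 18)]
        with pytest.raises(ValueError, match="cap"):
            enumerate_titration(sites, np.zeros((17, 17)), grid)

    def test_permutation_symmetry(self, grid):
        sites = oracle_fixture(4)
        W = interaction_matrix(sites, 20.0)
        res = enumerate_titration(sites, W, grid)
        perm = np.random.default_rng(0).permutation(len(sites))
        res_p = enumerate_titration(
            [sites[i] for i in perm], W[np.ix_(perm, perm)], grid)
        np.testing.assert_allclose(res_p.theta, res.theta[:, perm], atol=1e-10)
        np.testing.assert_allclose(res_p.Q, res.Q, atol=1e-10)


class TestMeanField:
    def test_decoupled_limit_machine_precision(self, grid):
        sites = [make_site("ASP", 2, intrinsic_pka=4.2),
                 make_site("HIS", 4, intrinsic_pka=6.8, center=(10, 0, 0))]
        mf = meanfield_titration(sites, np.zeros((2, 2)), grid)
        ind = independent_titration(sites, [4.2, 6.8], grid)
        np.testing.assert_allclose(mf.theta, ind.theta, atol=1e-9)
        assert mf.converged.all()

    def test_strong_acid_pair_net_charge_near_oracle(self):
        grid = PhGrid(2.0, 8.0, 0.1)
        sites = [make_site("ASP", 2, intrinsic_pka=4.0),
                 make_site("ASP", 4, intrinsic_pka=4.0, center=(5, 0, 0))]
        W = np.array([[0.0, 1.36], [1.36, 0.0]])
        ex = enumerate_titration(sites, W, grid)
        mf = meanfield_titration(sites, W, grid)
        assert np.max(np.abs(mf.Q - ex.Q)) <= 0.1

    def test_twelve_site_fixture_within_band(self, grid, twelve_site_sites):
        W = interaction_matrix(twelve_site_sites, 20.0)
        ex = enumerate_titration(twelve_site_sites, W, grid)
        mf = meanfield_titration(twelve_site_sites, W, grid)
        assert np.max(np.abs(mf.theta - ex.theta)) <= 0.05


class TestMonteCarlo:
    def test_single_site_midpoint(self):
        grid = PhGrid(5.0, 6.0, 0.5)
        site = make_site("ASP", 2, intrinsic_pka=5.0)
        mc = mc_titration([site], np.zeros((1, 1)), grid, sweeps=10_000, seed=42)
        assert mc.theta[0, 0] == pytest.approx(0.5, abs=0.02)

    def test_twelve_site_fixture_within_errorbars(self, grid, twelve_site_sites):
        W = interaction_matrix(twelve_site_sites, 20.0)
        ex = enumerate_titration(twelve_site_sites, W, grid)
        mc = mc_titration(twelve_site_sites, W, grid, sweeps=10_000, seed=7)
        err = np.abs(mc.theta - ex.theta)
        within3 = err <= 3.0 * mc.theta_se
        # a single fixture has ~500 comparisons, so the 3-SE coverage
        # fraction carries its own sampling noise; the hard envelope below
        # is the binding check
        assert within3.mean() >= 0.98
        assert np.all(err <= np.maximum(5.0 * mc.theta_se, 0.01))

    def test_same_seed_bitwise_identical(self, grid):
        sites = oracle_fixture(3)
        W = interaction_matrix(sites, 20.0)
        a = mc_titration(sites, W, grid, sweeps=2_000, seed=11)
        b = mc_titration(sites, W, grid, sweeps=2_000, seed=11)
        assert np.array_equal(a.theta, b.theta)

    def test_seed_required_and_sweep_check(self, grid):
        site = make_site("ASP", 2, intrinsic_pka=5.0)
        with pytest.raises(ValueError):
            mc_titration([site], np.zeros((1, 1)), grid, seed=None)
        with pytest.raises(ValueError):
            mc_titration([site], np.zeros((1, 1)), grid,
                         sweeps=100, burn_in=100, seed=1)


class TestUnfolded:
    def test_single_asp_midpoint(self):
        grid = PhGrid(3.8, 4.8, 0.5)
        site = make_site("ASP", 2)  # model pKa 3.8
        res = unfolded_titration([site], grid=grid)
        assert res.Q[0] == pytest.approx(-0.5)
        assert res.state == "unfolded"

    def test_bases_only_nonnegative_charge(self, grid):
        sites = [make_site("LYS", 2), make_site("ARG", 4, center=(10, 0, 0))]
        res = unfolded_titration(sites, grid=grid)
        assert np.all(res.Q >= 0.0)

    def test_matches_enumeration_at_model_pkas(self, grid, twelve_site_sites):
        from dataclasses import replace

        model_sites = [replace(s, intrinsic_pka=s.model_pka)
                       for s in twelve_site_sites]
        ex = enumerate_titration(
            model_sites, np.zeros((12, 12)), grid)
        unf = unfolded_titration(twelve_site_sites, grid=grid)
        np.testing.assert_allclose(unf.theta, ex.theta, atol=1e-12)

    def test_missing_class_in_table_errors(self, grid):
        site = make_site("HIS", 2)
        with pytest.raises(ValueError, match="HIS"):
            unfolded_titration([site], model_table={"ASP": 3.8}, grid=grid)


class TestApparentPka:
    def test_independent_site_recovers_intrinsic(self, grid):
        site = make_site("ASP", 2, intrinsic_pka=5.3)
        res = enumerate_titration([site], np.zeros((1, 1)), grid)
        pka = apparent_pka(res, site.site_id)
        assert pka.in_range
        assert pka.value == pytest.approx(5.3, abs=0.01)

    def test_coupled_pair_straddles_intrinsic(self):
        grid = PhGrid(2.0, 8.0, 0.05)
        sites = [make_site("ASP", 2, intrinsic_pka=4.0),
                 make_site("ASP", 4, intrinsic_pka=4.0, center=(5, 0, 0))]
        W = np.array([[0.0, 1.36], [1.36, 0.0]])
        res = enumerate_titration(sites, W, grid)
        # the coupled pair titrates over a widened range; the apparent pKa
        # of the symmetric curve sits above the intrinsic value because
        # deprotonating the second site costs the coupling energy
        pka = apparent_pka(res, sites[0].site_id)
        assert pka.value > 4.0

    def test_out_of_range_sentinel(self, grid):
        site = make_site("LYS", 2)  # pKa 10.5, never crosses in 4-8
        res = enumerate_titration([site], np.zeros((1, 1)), grid)
        pka = apparent_pka(res, site.site_id)
        assert not pka.in_range
        assert pka.bracket == ">8"
        assert math.isnan(pka.value)


class TestPkaTable:
    def _write(self, tmp_path, rows):
        path = tmp_path / "pka.tsv"
        lines = ["chain\tresnum\tresname\tpka"] + rows
        path.write_text("\n".join(lines) + "\n")
        return path

    def test_override_shifts_midpoint(self, tmp_path, grid):
        site = make_site("ASP", 2)
        path = self._write(tmp_path, ["A\t2\tASP\t5.5"])
        table = read_pka_table(path, [site])
        shifted = with_intrinsic_pkas([site], table)
        res = independent_titration(shifted, [s.intrinsic_pka for s in shifted], grid)
        pka = apparent_pka(res, site.site_id)
        assert pka.value == pytest.approx(5.5, abs=0.01)

    def test_partial_table_errors_naming_missing(self, tmp_path):
        sites = [make_site("ASP", 2), make_site("HIS", 4, center=(9, 0, 0))]
        path = self._write(tmp_path, ["A\t2\tASP\t5.5"])
        with pytest.raises(ValueError, match="missing sites"):
            read_pka_table(path, sites)

    def test_unmatched_and_duplicate_rows_error(self, tmp_path):
        site = make_site("ASP", 2)
        bad = self._write(tmp_path, ["A\t9\tASP\t5.5"])
        with pytest.raises(ValueError, match="no known site"):
            read_pka_table(bad, [site])
        dup = self._write(tmp_path, ["A\t2\tASP\t5.5", "A\t2\tASP\t5.6"])
        with pytest.raises(ValueError, match="duplicate"):
            read_pka_table(dup, [site])


# --- solver-equivalence properties --------------------------------------


@settings(max_examples=15, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=3.0, max_value=11.0),
                min_size=1, max_size=6))
def test_all_solvers_agree_when_decoupled(pkas):
    """With W = 0 every solver reduces to Henderson-Hasselbalch."""
    grid = PhGrid(4.0, 8.0, 0.5)
    sites = [make_site("ASP", 2 * (i + 1), intrinsic_pka=p,
                       center=(8.0 * i, 0, 0))
             for i, p in enumerate(pkas)]
    n = len(sites)
    ind = independent_titration(sites, pkas, grid)
    ex = enumerate_titration(sites, np.zeros((n, n)), grid)
    mf = meanfield_titration(sites, np.zeros((n, n)), grid)
    np.testing.assert_allclose(ex.theta, ind.theta, atol=1e-12)
    np.testing.assert_allclose(mf.theta, ind.theta, atol=1e-9)


@pytest.mark.parametrize("seed", range(8))
def test_net_charge_monotone_and_bounded(seed, grid):
    """Q(pH) decreases with pH and stays within the acid/base count bounds."""
    sites = oracle_fixture(seed)
    W = interaction_matrix(sites, 20.0)
    res = enumerate_titration(sites, W, grid)
    n_acid = sum(1 for s in sites if s.polarity == "acid")
    n_base = len(sites) - n_acid
    assert np.all(np.diff(res.Q) <= 1e-9)
    assert np.all(res.Q >= -n_acid - 1e-9)
    assert np.all(res.Q <= n_base + 1e-9)
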