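"""Occupancy partition function vs brute-force enumeration; expression rules."""

from dataclasses import replace
from itertools import combinations

import numpy as np
import pytest

import slmdesign as sd
from slmdesign.motifs import BindingSite
from slmdesign.params import Cooperativity, ParameterSet, TfParams
from slmdesign.thermo import _coop_strength, compute_occupancy, predict_expression


def simple_set(**overrides) -> ParameterSet:
    factors = {
        "act": TfParams("act", binding_scale=1.0, role="activator",
                        activation_strength=2.0),
        "rep": TfParams("rep", binding_scale=1.0, role="repressor",
                        quench_efficiency=0.9, quench_range=50,
                        direct_repression_strength=0.1),
    }
    defaults = dict(id=1, factors=factors, r_max=255.0,
                    response_midpoint=3.0, response_steepness=1.5)
    defaults.update(overrides)
    return ParameterSet(**defaults)


def site(factor, start, length=6, llr=0.0, strand="+"):
    return BindingSite(factor, start, start + length, strand, llr, 0.5)


def brute_force_occupancy(sites, conc, params):
    """Enumerate all non-overlapping configurations explicitly; weight =
    product of site weights times cooperativity per consecutively bound
    pair.  Independent of the DP implementation."""
    import math

    w = [
        params.factors[s.factor_name].binding_scale
        * conc[s.factor_name]
        * math.exp(s.llr)
        for s in sites
    ]
    n = len(sites)
    z = 0.0
    marg = np.zeros(n)
    for r in range(n + 1):
        for combo in combinations(range(n), r):
            ok = all(
                sites[combo[i]].end <= sites[combo[i + 1]].start
                for i in range(len(combo) - 1)
            )
            # also reject overlapping non-adjacent pairs (sorted by start,
            # so adjacency check is sufficient only if ends are ordered;
            # check all pairs to stay assumption-free)
            ok = ok and all(
                sites[a].end <= sites[b].start
                for a, b in combinations(combo, 2)
            )
            if not ok:
                continue
            weight = 1.0
            for i in combo:
                weight *= w[i]
            for i in range(len(combo) - 1):
                weight *= _coop_strength(sites[combo[i]], sites[combo[i + 1]], params)
            z += weight
            for i in combo:
                marg[i] += weight
    return marg / z


class TestOccupancy:
    def test_single_site_isotherm(self):
        ps = simple_set()
        w = 3.0
        occ = compute_occupancy([site("act", 0, llr=np.log(w))],
                                {"act": 1.0, "rep": 0.0}, ps)
        assert occ[0] == pytest.approx(w / (1 + w))

    def test_two_overlapping_identical_sites(self):
        ps = simple_set()
        w = 2.5
        sites = [site("act", 0, llr=np.log(w)), site("act", 3, llr=np.log(w))]
        occ = compute_occupancy(sites, {"act": 1.0, "rep": 0.0}, ps)
        assert np.allclose(occ, w / (1 + 2 * w))

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_enumeration(self, seed):
        """Random instances of up to 12 sites, with overlaps and a
        cooperativity rule, agree with exhaustive 2^n enumeration."""
        rng = np.random.default_rng(seed)
        coop = Cooperativity(partner="act", strength=4.0, max_gap=8)
        ps = simple_set()
        ps = replace(ps, factors={
            **ps.factors,
            "act": replace(ps.factors["act"], cooperativity=coop),
        })
        n = int(rng.integers(2, 13))
        starts = np.sort(rng.choice(60, size=n, replace=False))
        sites = [
            site(rng.choice(["act", "rep"]), int(s), length=int(rng.integers(4, 8)),
                 llr=float(rng.normal(0, 1)))
            for s in starts
        ]
        conc = {"act": 2.0, "rep": 1.5}
        occ = compute_occupancy(sites, conc, ps)
        expected = brute_force_occupancy(sites, conc, ps)
        assert np.allclose(occ, expected, atol=1e-10)
        assert np.all((occ >= 0) & (occ <= 1))

    def test_rejects_unsorted_sites(self):
        ps = simple_set()
        with pytest.raises(ValueError, match="sorted"):
            compute_occupancy([site("act", 10), site("act", 0)],
                              {"act": 1.0, "rep": 0.0}, ps)

    def test_rejects_unknown_factor(self):
        ps = simple_set()
        with pytest.raises(ValueError, match="no TF parameters"):
            compute_occupancy([site("mystery", 0)], {"mystery": 1.0}, ps)


class TestPredictExpression:
    def test_zero_concentrations_give_flat_basal(self, bundle, parameter_sets):
        ps = parameter_sets[1]
        grid = bundle.atlas[0].grid
        zero_atlas = [
            sd.TfProfile(f, grid, np.zeros(grid.size)) for f in ps.factors
        ]
        prof = predict_expression(bundle.reference, zero_atlas, ps, bundle.catalogue)
        assert np.allclose(prof.values, prof.values[0])
        basal = ps.r_max / (1 + np.exp(ps.response_steepness * ps.response_midpoint))
        assert prof.values[0] == pytest.approx(basal, rel=1e-6)

    def test_siteless_sequence_is_basal(self, bundle, parameter_sets):
        ps = parameter_sets[1]
        seq = "CG" * 40  # CpG repeat carries no site above threshold
        prof = predict_expression(seq, bundle.atlas, ps, bundle.catalogue)
        assert prof.values.max() < 0.05 * ps.r_max

    def test_monotone_in_activator_without_repressors(self, toy_system, toy_grid):
        cat, atlas, ps = toy_system
        seq = "TT" + cat["bcd"].consensus() + "AT" * 10
        prof = predict_expression(seq, atlas, ps, cat)
        # anterior gradient: expression decreases along AP
        assert np.all(np.diff(prof.values) <= 1e-9)
        # doubling activator concentration never decreases output
        boosted = (sd.TfProfile("bcd", toy_grid,
                                2 * atlas[0].concentrations),)
        prof2 = predict_expression(seq, boosted, ps, cat)
        assert np.all(prof2.values >= prof.values - 1e-9)

    def test_disabled_repressor_has_no_effect(self, toy_grid):
        from slmdesign.params import TfParams, ParameterSet

        cat = sd.make_pwm_catalogue(["bcd", "Kr"])
        base = {
            "bcd": TfParams("bcd", 3e-5, "activator", activation_strength=2.0),
            "Kr": TfParams("Kr", 5e-7, "repressor", quench_efficiency=0.0,
                           direct_repression_strength=0.0),
        }
        ps = ParameterSet(id=1, factors=base, response_midpoint=2.0)
        seq = "TT" + cat["bcd"].consensus() + "AA" + cat["Kr"].consensus() + "TT"
        grad = 100.0 * np.exp(-(toy_grid - 35.5) / 12.0)
        for kr_level in (0.0, 50.0, 500.0):
            atlas = (sd.TfProfile("bcd", toy_grid, grad),
                     sd.TfProfile("Kr", toy_grid, np.full(toy_grid.size, kr_level)))
            prof = predict_expression(seq, atlas, ps, cat)
            if kr_level == 0.0:
                ref = prof.values
            else:
                assert np.allclose(prof.values, ref)

    def test_repressor_carves_trough(self, toy_grid):
        """A central repressor dome with quench range covering the activator
        site carves a trough at the dome."""
        from slmdesign.params import TfParams, ParameterSet

        cat = sd.make_pwm_catalogue(["bcd", "Kr"])
        base = {
            "bcd": TfParams("bcd", 3e-5, "activator", activation_strength=2.0),
            "Kr": TfParams("Kr", 6e-7, "repressor", quench_efficiency=0.95,
                           quench_range=100, direct_repression_strength=0.2),
        }
        ps = ParameterSet(id=1, factors=base, response_midpoint=2.0)
        seq = "TT" + cat["bcd"].consensus() + "AA" + cat["Kr"].consensus() + "TT"
        grad = np.full(toy_grid.size, 80.0)
        dome = 90.0 * np.exp(-(((toy_grid - 45.0) / 3.0) ** 2))
        atlas = (sd.TfProfile("bcd", toy_grid, grad),
                 sd.TfProfile("Kr", toy_grid, dome))
        prof = predict_expression(seq, atlas, ps, cat)
        dome_bin = int(np.argmin(np.abs(toy_grid - 45.0)))
        assert prof.values[dome_bin] < 0.5 * prof.values[0]
        assert prof.values[dome_bin] < 0.5 * prof.values[-1]

    def test_stripe_property_all_parameter_sets(self, bundle, parameter_sets):
        """The reference element drives a single contiguous stripe peaking
        at 37-43% embryo length under every parameter set."""
        for ps in parameter_sets.values():
            prof = predict_expression(bundle.reference, bundle.atlas, ps,
                                      bundle.catalogue)
            assert 37.0 <= prof.peak_position <= 43.0, f"set {ps.id}"
            above = prof.values > 0.5 * prof.peak
            idx = np.flatnonzero(above)
            assert np.all(np.diff(idx) == 1), f"set {ps.id}: stripe not contiguous"

    def test_atlas_grid_mismatch_rejected(self, bundle, parameter_sets):
        ps = parameter_sets[1]
        bad_atlas = list(bundle.atlas)
        short = bad_atlas[0]
        bad_atlas[0] = sd.TfProfile(short.factor_name, short.grid[:-1],
                                    short.concentrations[:-1])
        with pytest.raises(ValueError, match="mismatched AP grids"):
            predict_expression(bundle.reference, bad_atlas, ps, bundle.catalogue)
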