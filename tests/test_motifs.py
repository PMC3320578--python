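import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qtlpath.motifs import (
    MOTIF_NAMES,
    EpistasisRule,
    FluxSpec,
    PathwayMotif,
    bisubstrate_flux,
    build_motif,
    mm_flux,
    net_rate,
    substrate_inhibited_flux,
)


class TestMMFlux:
    def test_half_saturation(self):
        assert mm_flux(1.0, 1.0, 1.0) == pytest.approx(0.5)

    def test_zero_substrate(self):
        assert mm_flux(2.0, 0.5, 0.0) == 0.0

    def test_saturation_limit(self):
        assert mm_flux(1.0, 1.0, 1e6) == pytest.approx(1.0, abs=1e-5)

    def test_negative_substrate_rejected(self):
        with pytest.raises(ValueError):
            mm_flux(1.0, 1.0, -0.1)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            mm_flux(0.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            mm_flux(1.0, -1.0, 1.0)

    @given(
        vmax=st.floats(0.01, 100),
        km=st.floats(0.01, 100),
        s1=st.floats(0, 1e4),
        s2=st.floats(0, 1e4),
    )
    @settings(max_examples=200)
    def test_bounded_and_monotone(self, vmax, km, s1, s2):
        lo, hi = sorted([s1, s2])
        v_lo, v_hi = mm_flux(vmax, km, lo), mm_flux(vmax, km, hi)
        assert 0 <= v_lo <= v_hi <= vmax


class TestBisubstrateFlux:
    def test_missing_substrate(self):
        assert bisubstrate_flux(1, 1, 1, 0.0, 5.0) == 0.0

    def test_double_half_saturation(self):
        assert bisubstrate_flux(1, 1, 1, 1.0, 1.0) == pytest.approx(0.25)

    def test_saturation_limit(self):
        assert bisubstrate_flux(1, 1, 1, 1e6, 1e6) == pytest.approx(1.0, abs=1e-5)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            bisubstrate_flux(1, 1, 1, -1.0, 1.0)

    @given(
        s1=st.floats(0, 1e4), s2=st.floats(0, 1e4),
        vmax=st.floats(0.01, 10),
    )
    @settings(max_examples=100)
    def test_bounded(self, s1, s2, vmax):
        assert 0 <= bisubstrate_flux(vmax, 1, 2, s1, s2) <= vmax


class TestSubstrateInhibitedFlux:
    def test_large_ki_equals_mm(self):
        assert substrate_inhibited_flux(1, 1, 1e9, 1.0) == pytest.approx(
            mm_flux(1, 1, 1.0), abs=1e-6
        )

    def test_zero_substrate(self):
        assert substrate_inhibited_flux(1, 1, 1.0, 0.0) == 0.0

    def test_peak_location_brute_force(self):
        # independent oracle: dense grid search for the maximizer
        km, ki = 1.0, 4.0
        grid = np.linspace(0.0, 20.0, 200001)
        rates = substrate_inhibited_flux(1.0, km, ki, grid)
        maximizer = grid[np.argmax(rates)]
        assert maximizer == pytest.approx(np.sqrt(km * ki), abs=1e-3)
        assert maximizer == pytest.approx(2.0, abs=1e-3)

    def test_ki_limit_over_range(self):
        s = np.linspace(0.0, 100.0, 501)
        inhibited = substrate_inhibited_flux(1.0, 1.0, 1e9, s)
        plain = mm_flux(1.0, 1.0, s)
        mask = plain > 0
        assert np.all(
            np.abs(inhibited[mask] - plain[mask]) / plain[mask] < 1e-6
        )

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            substrate_inhibited_flux(1, 1, 1, -2.0)


class TestFluxSpecValidation:
    def test_bi_substrate_needs_two_of_each(self):
        with pytest.raises(ValueError):
            FluxSpec("v", "bi_substrate", ("A",), 1.0, (1.0,))

    def test_ki_only_for_inhibited(self):
        with pytest.raises(ValueError):
            FluxSpec("v", "uni_substrate", ("A",), 1.0, (1.0,), ki=1.0)
        with pytest.raises(ValueError):
            FluxSpec("v", "substrate_inhibited", ("A",), 1.0, (1.0,))

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            FluxSpec("v", "hill", ("A",), 1.0, (1.0,))


class TestEpistasisRule:
    def test_invalid_combination_rejected(self):
        with pytest.raises(ValueError):
            EpistasisRule(("Qa", "Qb"), frozenset({(0, 1)}), "v1")


class TestBuildMotif:
    @pytest.mark.parametrize("name", MOTIF_NAMES)
    def test_all_motifs_valid(self, name):
        motif = build_motif(name)
        assert motif.name == name
        kinds = [f.kind for f in motif.fluxes]
        assert "input" in kinds and "sink" in kinds

    def test_unknown_name(self):
        with pytest.raises(ValueError):
            build_motif("cycle")

    def test_linear_chain_structure(self):
        motif = build_motif("linear")
        for sp in motif.species:
            assert len(motif.production[sp]) == 1
            assert len(motif.utilization[sp]) == 1

    def test_branch_point_feeds_two_fluxes(self):
        motif = build_motif("branch")
        consumers = [f for f in motif.fluxes if "S1" in f.substrates]
        assert len(consumers) == 2

    def test_merge_has_one_bisubstrate_flux(self):
        motif = build_motif("merge_bisubstrate")
        bi = [f for f in motif.fluxes if f.kind == "bi_substrate"]
        assert len(bi) == 1
        assert len(bi[0].substrates) == 2
        # the merge reaction is not genetically controlled
        assert bi[0].id not in motif.genetic_loci

    def test_epistasis_motif_rule(self):
        motif = build_motif("branch_epistasis")
        assert motif.epistasis is not None
        assert motif.epistasis.target_flux in [f.id for f in motif.fluxes]
        assert motif.epistasis.loci[0] in motif.loci

    def test_parameter_override(self):
        motif = build_motif("linear", {"v1": {"vmax": 2.5}})
        v1 = next(f for f in motif.fluxes if f.id == "v1")
        assert v1.vmax == 2.5

    def test_each_locus_controls_one_flux(self):
        for name in MOTIF_NAMES:
            motif = build_motif(name)
            loci = list(motif.genetic_loci.values())
            assert len(loci) == len(set(loci))


def closed_cycle_motif():
    """Three species in a closed loop (no input or sink): mass conserving."""
    fluxes = [
        FluxSpec("a", "uni_substrate", ("A",), 1.0, (1.0,)),
        FluxSpec("b", "uni_substrate", ("B",), 0.7, (0.5,)),
        FluxSpec("c", "uni_substrate", ("C",), 1.3, (2.0,)),
    ]
    production = {"B": [("a", 1.0)], "C": [("b", 1.0)], "A": [("c", 1.0)]}
    utilization = {"A": [("a", 1.0)], "B": [("b", 1.0)], "C": [("c", 1.0)]}
    return PathwayMotif("closed", ["A", "B", "C"], fluxes, production, utilization)


class TestNetRate:
    def test_mass_conservation_closed(self):
        motif = closed_cycle_motif()
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.uniform(0, 5, size=3)
            rates = net_rate(motif, x, np.ones(3))
            assert abs(rates.sum()) < 1e-12

    def test_zero_state_only_input_species_moves(self):
        motif = build_motif("linear")
        rates = net_rate(motif, np.zeros(3), np.ones(len(motif.fluxes)))
        assert rates[0] > 0
        assert np.allclose(rates[1:], 0.0)

    def test_linear_against_hand_evaluation(self):
        # independent oracle: evaluate each mm flux by hand
        motif = build_motif("linear")
        rng = np.random.default_rng(42)
        x = rng.uniform(0.1, 3.0, size=3)
        m = rng.uniform(0.5, 1.5, size=4)
        v0 = 0.2 * m[0]
        v1 = m[1] * mm_flux(1.0, 1.0, x[0])
        v2 = m[2] * mm_flux(1.0, 1.0, x[1])
        v3 = m[3] * mm_flux(1.0, 1.0, x[2])
        expected = np.array([v0 - v1, v1 - v2, v2 - v3])
        assert np.allclose(net_rate(motif, x, m), expected, atol=1e-12)

    def test_input_perturbation_offsets_input(self):
        motif = build_motif("linear")
        x = np.full(3, 0.5)
        base = net_rate(motif, x, np.ones(4))
        up = net_rate(motif, x, np.ones(4), input_perturbation=0.1)
        assert up[0] == pytest.approx(base[0] + 0.1)
        assert np.allclose(up[1:], base[1:])

    def test_perturbed_input_floored_at_zero(self):
        motif = build_motif("linear")
        x = np.zeros(3)
        rates = net_rate(motif, x, np.ones(4), input_perturbation=-10.0)
        assert np.allclose(rates, 0.0)

    def test_negative_state_rejected(self):
        motif = build_motif("linear")
        with pytest.raises(ValueError):
            net_rate(motif, np.array([-0.1, 0.2, 0.2]), np.ones(4))

    def test_dimension_mismatch(self):
        motif = build_motif("linear")
        with pytest.raises(ValueError):
            net_rate(motif, np.zeros(4), np.ones(4))

    def test_flux_bounds(self):
        motif = build_motif("branch")
        rng = np.random.default_rng(1)
        for _ in range(50):
            x = rng.uniform(0, 10, size=3)
            m = rng.uniform(0, 2, size=len(motif.fluxes))
            rates = motif.flux_rates(x, m)
            caps = np.array([f.vmax for f in motif.fluxes]) * m
            assert np.all(rates >= -1e-15)
            assert np.all(rates <= caps + 1e-12)


class TestSerialization:
    @pytest.mark.parametrize("name", MOTIF_NAMES)
    def test_json_round_trip(self, name):
        motif = build_motif(name)
        restored = PathwayMotif.from_json(motif.to_json())
        assert restored.to_dict() == motif.to_dict()

    def test_yaml_round_trip(self, tmp_path):
        motif = build_motif("branch_epistasis")
        path = tmp_path / "motif.yaml"
        motif.to_yaml(path)
        restored = PathwayMotif.from_yaml(path)
        assert restored.to_dict() == motif.to_dict()
        assert restored.epistasis == motif.epistasis
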