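import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from skcam.binding import (
    BindingModel,
    ComplexSpec,
    Composition,
    MonomerSpecies,
    OpticalConstants,
    complex_label,
    excess_rayleigh,
    kstar,
    mole_fraction_curves,
    mw_from_rayleigh,
    no_interaction_mw,
    solve_speciation,
    weight_average_mass,
)
from skcam.study import skp_species, cam_species


def quadratic_bound_fraction(p_tot, c_tot, ka):
    """Closed-form [PC] for P + C <-> PC from conservation + mass action."""
    s = p_tot + c_tot + 1.0 / ka
    return (s - math.sqrt(s * s - 4.0 * p_tot * c_tot)) / 2.0


class TestComplexMass:
    def test_named_stoichiometry_masses(self, wt_ca_model):
        assert round(wt_ca_model.complex_mass(1, 1)) == 28
        assert wt_ca_model.complex_mass(2, 1) == pytest.approx(38.9)

    def test_skp_n_cam_one_to_one(self):
        m = BindingModel(skp_species(), cam_species("N-CaM"), ())
        assert round(m.complex_mass(1, 1)) == 20

    def test_labels(self):
        assert complex_label(2, 1) == "P-C-P"
        assert complex_label(1, 2) == "C-P-C"
        assert complex_label(3, 1) == "3P1C"


class TestSolveSpeciation:
    def test_no_complexes_returns_totals(self, wt_ca_model):
        empty = BindingModel(wt_ca_model.peptide, wt_ca_model.cam, ())
        s = solve_speciation(empty, Composition(2e-6, 3e-6))
        assert s.free_peptide == pytest.approx(2e-6)
        assert s.free_cam == pytest.approx(3e-6)
        # concentration-weighted monomer average
        expect = (2e-6 * 11.1**2 + 3e-6 * 16.7**2) / (2e-6 * 11.1 + 3e-6 * 16.7)
        assert s.m_w == pytest.approx(expect, rel=1e-12)

    def test_peptide_only_is_monomer_mass(self, wt_ca_model):
        s = solve_speciation(wt_ca_model, Composition(8.65e-6, 0.0))
        assert s.m_w == pytest.approx(11.1, rel=1e-12)

    @pytest.mark.parametrize("log_ka", [2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 14.0])
    def test_matches_quadratic_oracle(self, single_complex_model, log_ka):
        """1:1-only solver agrees with the closed-form quadratic over a wide
        K_A sweep (free concentrations to 1e-10 relative)."""
        p_tot, c_tot = 5e-6, 3e-6
        s = solve_speciation(
            single_complex_model(log_ka), Composition(p_tot, c_tot), tol=1e-12
        )
        pc = quadratic_bound_fraction(p_tot, c_tot, 10.0**log_ka)
        assert s.free_peptide == pytest.approx(p_tot - pc, rel=1e-10)
        assert s.free_cam == pytest.approx(c_tot - pc, rel=1e-10)

    def test_conservation_randomized_models(self):
        """Mass conservation holds to 1e-9 relative over 1000 random models."""
        rng = np.random.default_rng(42)
        pool = [(1, 1), (2, 1), (1, 2), (2, 2), (3, 1)]
        for _ in range(1000):
            n = rng.integers(1, 4)
            picks = rng.choice(len(pool), size=n, replace=False)
            complexes = tuple(
                ComplexSpec(*pool[k], float(rng.uniform(2, 24))) for k in picks
            )
            model = BindingModel(
                MonomerSpecies("P", float(rng.uniform(5, 30))),
                MonomerSpecies("C", float(rng.uniform(5, 30))),
                complexes,
            )
            p_tot = float(10 ** rng.uniform(-8, -4))
            c_tot = float(10 ** rng.uniform(-8, -4))
            s = solve_speciation(model, Composition(p_tot, c_tot))
            p_sum = s.free_peptide + sum(
                i * v for (i, j), v in s.complex_concentrations.items()
            )
            c_sum = s.free_cam + sum(
                j * v for (i, j), v in s.complex_concentrations.items()
            )
            assert abs(p_sum - p_tot) <= 1e-9 * p_tot
            assert abs(c_sum - c_tot) <= 1e-9 * c_tot

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        log_ka=st.floats(min_value=2.0, max_value=20.0),
        p_um=st.floats(min_value=0.01, max_value=50.0),
        c_um=st.floats(min_value=0.01, max_value=50.0),
    )
    def test_label_symmetry(self, log_ka, p_um, c_um):
        """Swapping peptide <-> CaM and transposing (i, j) mirrors speciation."""
        mp = MonomerSpecies("P", 11.1)
        mc = MonomerSpecies("C", 16.7)
        fwd = BindingModel(mp, mc, (ComplexSpec(2, 1, log_ka),))
        rev = BindingModel(mc, mp, (ComplexSpec(1, 2, log_ka),))
        s1 = solve_speciation(fwd, Composition(p_um * 1e-6, c_um * 1e-6))
        s2 = solve_speciation(rev, Composition(c_um * 1e-6, p_um * 1e-6))
        assert s1.free_peptide == pytest.approx(s2.free_cam, rel=1e-8)
        assert s1.free_cam == pytest.approx(s2.free_peptide, rel=1e-8)
        assert s1.m_w == pytest.approx(s2.m_w, rel=1e-8)

    def test_mw_monotone_in_log_ka(self, single_complex_model):
        comp = Composition(4e-6, 4e-6)
        mws = [
            solve_speciation(single_complex_model(k), comp).m_w
            for k in np.linspace(2, 16, 30)
        ]
        assert np.all(np.diff(mws) >= -1e-12)

    def test_mw_bounded_by_species_masses(self, wt_ca_model):
        for p, c in [(1e-6, 1e-6), (8e-6, 1e-7), (1e-7, 5e-6)]:
            s = solve_speciation(wt_ca_model, Composition(p, c))
            assert 11.1 - 1e-9 <= s.m_w <= wt_ca_model.complex_mass(2, 1) + 1e-9

    def test_all_zero_composition_has_no_mw(self, wt_ca_model):
        s = solve_speciation(wt_ca_model, Composition(0.0, 0.0))
        with pytest.raises(ValueError):
            weight_average_mass(s)


class TestOptics:
    def test_kstar_zero_dndc(self):
        assert kstar(OpticalConstants(dn_dc=0.0)) == 0.0

    def test_kstar_quadratic_in_dndc(self):
        k1 = kstar(OpticalConstants(dn_dc=0.1))
        k2 = kstar(OpticalConstants(dn_dc=0.2))
        assert k2 == pytest.approx(4 * k1, rel=1e-12)

    def test_kstar_hand_evaluation(self):
        # 4 pi^2 (0.186)^2 (1.33)^2 / (N_A (660e-7 cm)^2), evaluated by hand
        optics = OpticalConstants(dn_dc=0.186, n0=1.33, lambda0_nm=660.0)
        expect = (
            4 * math.pi**2 * 0.186**2 * 1.33**2
        ) / (6.02214076e23 * (660e-7) ** 2)
        assert kstar(optics) == pytest.approx(expect, rel=1e-9)

    def test_rayleigh_round_trip(self, wt_ca_model):
        optics = OpticalConstants()
        s = solve_speciation(wt_ca_model, Composition(4e-6, 4e-6))
        w_tot = sum(
            conc * mass for _, mass, conc in s.species()
        )  # kDa * M == g/L / 1000 == g/ml
        r = excess_rayleigh(s, optics)
        assert mw_from_rayleigh(r, w_tot, optics) == pytest.approx(
            s.m_w, rel=1e-12
        )

    def test_rayleigh_linear_in_dilution(self, wt_ca_model):
        optics = OpticalConstants()
        s = solve_speciation(wt_ca_model, Composition(4e-6, 4e-6))
        diluted = type(s)(
            free_peptide=s.free_peptide / 2,
            free_cam=s.free_cam / 2,
            complex_concentrations={
                k: v / 2 for k, v in s.complex_concentrations.items()
            },
            m_w=s.m_w,
            model=s.model,
        )
        assert excess_rayleigh(diluted, optics) == pytest.approx(
            excess_rayleigh(s, optics) / 2, rel=1e-12
        )

    def test_zero_concentration_inverse_errors(self):
        with pytest.raises(ValueError):
            mw_from_rayleigh(1.0, 0.0, OpticalConstants())


class TestMoleFractions:
    def test_peptide_only_point(self, wt_ca_model):
        df = mole_fraction_curves(
            wt_ca_model, [Composition(5e-6, 0.0)], basis="particle_molar"
        )
        assert df.loc[0, "P"] == pytest.approx(1.0)

    @pytest.mark.parametrize("basis", ["particle_molar", "peptide_monomer", "cam_monomer"])
    def test_fractions_sum_to_one(self, wt_ca_model, standard_gradient, basis):
        comps = standard_gradient.compositions()[::8]
        df = mole_fraction_curves(wt_ca_model, comps, basis=basis)
        frac_cols = [c for c in df.columns if not c.endswith("_M")]
        sums = df[frac_cols].sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)
        assert (df[frac_cols] >= -1e-12).all().all()

    def test_pcp_dominates_at_peptide_excess(self, wt_ca_model):
        # at a 2:1 SKp:CaM total ratio the 2SKp/1CaM complex is the most
        # populated complex in the saturating-Ca2+ model
        df = mole_fraction_curves(
            wt_ca_model, [Composition(4e-6, 2e-6)], basis="particle_molar"
        )
        complexes = {"P-C", "P-C-P", "C-P-C"}
        top = max(complexes, key=lambda k: df.loc[0, k])
        assert top == "P-C-P"

    def test_invalid_basis(self, wt_ca_model):
        with pytest.raises(ValueError):
            mole_fraction_curves(wt_ca_model, [Composition(1e-6, 1e-6)], basis="bogus")

    def test_no_interaction_reference(self, wt_ca_model, standard_gradient):
        # the reference curve equals the monomers-only m_w at every point
        for comp in standard_gradient.compositions()[::10]:
            empty = BindingModel(wt_ca_model.peptide, wt_ca_model.cam, ())
            assert no_interaction_mw(wt_ca_model, comp) == pytest.approx(
                solve_speciation(empty, comp).m_w, rel=1e-12
            )


def test_model_json_round_trip(wt_ca_model):
    back = BindingModel.from_json(wt_ca_model.to_json())
    assert back == wt_ca_model
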