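"""PK-PD coupling: active/inactive split, saturation, drug effects,
coupled fluxes and the six model variants."""

import numpy as np
import pytest

from bonepkpd.bcpm import initialize_site, specific_surface
from bonepkpd.coupling import (N_STATE, PDParams, VariantSpec, active_amount,
                               active_surface_factor, coupled_rhs,
                               effective_apoptosis, effective_kres, kel_bc,
                               simulate_treatment, skeleton_average_fbm)
from bonepkpd.pk import CC, GUT, NCT, BC, IC, URINE, N_COMP
from bonepkpd.reference import PKPD_VARIANT_FITS
from bonepkpd.pk import PKParams


@pytest.fixture(scope="module")
def pd_default():
    return PDParams()


class TestSkeletonAverage:
    def test_default_composition(self):
        assert skeleton_average_fbm() == pytest.approx(43.7, abs=0.05)

    def test_recomputed_from_composition(self):
        # a different skeleton composition gives a different average
        assert skeleton_average_fbm(90.0, 0.5, 20.0, 0.5) == \
            pytest.approx(1 / (0.5 / 90 + 0.5 / 20))
        with pytest.raises(ValueError):
            skeleton_average_fbm(93, 0.7, 14, 0.2)


class TestActiveSplit:
    def test_fully_superficial_below_reference(self, pd_default):
        assert active_surface_factor(5.0, pd_default) == 1.0
        assert active_surface_factor(2.0, pd_default) == 1.0

    def test_no_surface_at_full_compaction(self, pd_default):
        assert active_surface_factor(100.0, pd_default) == \
            pytest.approx(0.0, abs=1e-12)

    def test_polynomial_ratio_value(self, pd_default):
        # independent evaluation of the surface-over-matrix normalization
        sv25 = specific_surface(0.75)
        sv0 = specific_surface(0.95)
        expected = (sv25 / 25.0) * (5.0 / sv0)
        g = active_surface_factor(25.0, pd_default)
        assert g == pytest.approx(expected)
        assert g == pytest.approx(0.66, abs=0.01)

    def test_bounded_and_decreasing_in_compaction(self, pd_default):
        f = np.linspace(5.0, 100.0, 96)
        g = active_surface_factor(f, pd_default)
        assert np.all((g >= 0) & (g <= 1))
        assert np.all(np.diff(g) <= 1e-12)

    def test_active_amount_split(self, pd_default):
        assert active_amount(0.0, 25.0, pd_default) == 0.0
        g = active_surface_factor(25.0, pd_default)
        assert active_amount(4.0, 25.0, pd_default, saturation=False) == \
            pytest.approx(g * 4.0)
        with pytest.raises(ValueError):
            active_amount(-1.0, 25.0, pd_default)

    def test_saturation_caps_active_concentration(self, pd_default):
        """Beyond the cap the active amount is pinned at f_sat*g converted
        to mass, independent of further loading."""
        g = active_surface_factor(25.0, pd_default)
        cap_mg = pd_default.amount_mg(pd_default.f_sat * g)
        big = 10 * cap_mg / g
        a1 = active_amount(big, 25.0, pd_default, saturation=True)
        a2 = active_amount(5 * big, 25.0, pd_default, saturation=True)
        assert a1 == pytest.approx(cap_mg)
        assert a2 == a1
        # the active part never exceeds the total
        for amount in (0.0, 0.1, cap_mg, big):
            assert active_amount(amount, 25.0, pd_default) <= amount + 1e-12


class TestDrugEffects:
    def test_release_rate_product(self):
        assert kel_bc(0.5, 0.0) == 0.0
        assert kel_bc(0.0, 1e-3) == 0.0
        assert kel_bc(0.5, 2e-3) == pytest.approx(2 * kel_bc(0.5, 1e-3))
        with pytest.raises(ValueError):
            kel_bc(-1.0, 1.0)

    def test_no_drug_no_effect(self, pd_default):
        assert effective_kres(1e-3, 0.0, pd_default, 7.3) == 7.3
        assert effective_apoptosis(1e-3, 0.0, 0.5, pd_default, 0.35) == 0.35

    def test_disabled_constants_are_neutral(self):
        pd = PDParams(pi_rep=0.0, pi_act=0.0)
        assert effective_kres(1e-3, 0.05, pd, 7.3) == 7.3
        assert effective_apoptosis(1e-3, 0.05, 7.3e-3, pd, 0.35) == 0.35

    def test_kres_fixed_point_identity(self, pd_default):
        """The closed form solves the implicit self-inhibition relation
        k_res = k_nom·(1 - Π·k_res·Oca·[Ale]) ... rearranged, i.e.
        k_res·(1 + Π·k_nom·Oca·[Ale]) = k_nom, to machine precision."""
        rng = np.random.default_rng(42)
        for _ in range(200):
            oca = rng.uniform(0, 5e-3)
            c = rng.uniform(0, 0.2)
            k_nom = rng.uniform(0.1, 20.0)
            k = effective_kres(oca, c, pd_default, k_nom)
            lhs = k_nom / (1.0 + pd_default.pi_rep * pd_default.effect_scale
                           * k_nom * oca * c)
            assert abs(k - lhs) <= 1e-12 * k_nom
            # substituted back into the implicit form it reproduces itself
            implicit = k_nom - pd_default.pi_rep * pd_default.effect_scale \
                * k_nom * k * oca * c
            assert abs(k - implicit) <= 1e-12 * k_nom

    def test_apoptosis_monotone_in_drug(self, pd_default):
        cs = np.linspace(0, 0.1, 50)
        vals = [effective_apoptosis(1e-3, c,
                                    effective_kres(1e-3, c, pd_default, 7.3),
                                    pd_default, 0.35) for c in cs]
        assert np.all(np.diff(vals) > 0)


class TestVariants:
    def test_flag_table(self):
        flags = {v: VariantSpec.from_id(v) for v in
                 ("pkpd1", "pkpd2", "pkpd3", "pkpd4", "pkpd5", "pkpd6")}
        assert (flags["pkpd1"].affects_kres, flags["pkpd1"].affects_apoptosis,
                flags["pkpd1"].active_split, flags["pkpd1"].saturation) == \
            (True, True, True, True)
        assert flags["pkpd2"].affects_apoptosis is False
        assert flags["pkpd3"].affects_kres is False
        assert flags["pkpd4"].saturation is False
        assert flags["pkpd5"].active_split is False
        assert flags["pkpd5"].saturation is False
        assert flags["pkpd6"].active_split is False
        assert flags["pkpd6"].saturation is True
        with pytest.raises(ValueError):
            VariantSpec.from_id("pkpd7")


class TestCoupledRHS:
    def test_reduces_to_uncoupled_models_without_drug(self, bcpm_default,
                                                      pkpd1_pk, pd_default):
        """With zero drug everywhere the coupled derivative equals the
        drug-free bone model stacked on the drug-free PK model."""
        from bonepkpd.bcpm import cell_rhs, mechanical_stimulus
        site = initialize_site(bcpm_default, 15.0)
        y = np.concatenate([np.zeros(N_COMP), site.state0.as_vector()])
        dy = coupled_rhs(y, 100.0, pkpd1_pk, bcpm_default, pd_default,
                         VariantSpec.from_id("pkpd1"), site,
                         site.state0.histogram.mean_ash)
        assert np.all(dy[:N_COMP] == 0.0)
        mech = mechanical_stimulus(site.load_MPa, 15.0,
                                   site.state0.histogram.mean_ash,
                                   bcpm_default, site.psi_ref)
        expected = cell_rhs(site.state0.as_vector(), 100.0, bcpm_default,
                            site.k_form, bcpm_default.k_res_nom,
                            bcpm_default.A_Oca_nom, mech["catabolic"], True)
        assert np.allclose(dy[N_COMP:], expected, rtol=1e-12)

    def test_total_drug_mass_balance(self, bcpm_default, pkpd1_pk,
                                     pd_default):
        """The osteoclast-mediated return flux moves drug between BC and
        CC without creating or destroying any: body + urine still gain
        exactly the absorbed gut flow plus the infusion."""
        site = initialize_site(bcpm_default, 15.0)
        rng = np.random.default_rng(7)
        for variant in ("pkpd1", "pkpd4", "pkpd5", "pkpd6"):
            v = VariantSpec.from_id(variant)
            y = np.concatenate([rng.random(N_COMP) * 5,
                                site.state0.as_vector()])
            dy = coupled_rhs(y, 50.0, pkpd1_pk, bcpm_default, pd_default,
                             v, site, 0.6, infusion_rate=2.5)
            gain = dy[[CC, NCT, BC, IC, URINE]].sum()
            expected = pkpd1_pk.F * pkpd1_pk.k_CC * y[GUT] + 2.5
            assert gain == pytest.approx(expected, rel=1e-12)

    def test_pkpd2_keeps_nominal_apoptosis(self, bcpm_default, pkpd1_pk):
        """Variant 2: the drug lowers resorbing capacity but leaves the
        osteoclast apoptosis rate untouched."""
        from bonepkpd.coupling import _drug_effects
        pd = PDParams()
        kres, apo, _, _ = _drug_effects(5.0, 15.0, 1.5e-3, bcpm_default, pd,
                                        VariantSpec.from_id("pkpd2"))
        assert apo == bcpm_default.A_Oca_nom
        assert kres < bcpm_default.k_res_nom


@pytest.fixture(scope="module")
def short_kwargs(pre_cache):
    return dict(years_treat=0.25, pre_cache=pre_cache)


class TestVariantReductions:
    """Parameter restrictions collapse the full model onto the reduced
    variants exactly (identical trajectories)."""

    def _run(self, variant, pd, bcpm_default, pkpd1_pk, kw):
        return simulate_treatment(15.0, "weekly70", variant, pkpd1_pk,
                                  bcpm_default, pd, **kw)

    def test_no_apoptosis_effect_is_variant2(self, bcpm_default, pkpd1_pk,
                                             short_kwargs):
        pd = PDParams(pi_act=0.0)
        a = self._run("pkpd1", pd, bcpm_default, pkpd1_pk, short_kwargs)
        b = self._run("pkpd2", pd, bcpm_default, pkpd1_pk, short_kwargs)
        assert np.allclose(a.cells, b.cells, rtol=1e-9, atol=1e-15)
        assert np.allclose(a.pk_amounts, b.pk_amounts, rtol=1e-9, atol=1e-12)

    def test_no_kres_effect_is_variant3(self, bcpm_default, pkpd1_pk,
                                        short_kwargs):
        pd = PDParams(pi_rep=0.0)
        a = self._run("pkpd1", pd, bcpm_default, pkpd1_pk, short_kwargs)
        b = self._run("pkpd3", pd, bcpm_default, pkpd1_pk, short_kwargs)
        assert np.allclose(a.cells, b.cells, rtol=1e-9, atol=1e-15)

    def test_no_split_no_saturation_is_variant5(self, bcpm_default,
                                                pkpd1_pk, short_kwargs):
        # g == 1 everywhere once the superficial threshold covers the site
        pd = PDParams(f_sat=None, f_bm0=99.0)
        a = self._run("pkpd1", pd, bcpm_default, pkpd1_pk, short_kwargs)
        b = self._run("pkpd5", pd, bcpm_default, pkpd1_pk, short_kwargs)
        assert np.allclose(a.cells, b.cells, rtol=1e-9, atol=1e-15)
        assert np.allclose(a.pk_amounts, b.pk_amounts, rtol=1e-9, atol=1e-12)


class TestTreatment:
    def test_active_never_exceeds_total(self, treat15_weekly, pd_default):
        act = np.array([active_amount(a, f, pd_default)
                        for a, f in zip(treat15_weekly.pk_amounts[:, BC],
                                        treat15_weekly.f_bm)])
        assert np.all(act <= treat15_weekly.pk_amounts[:, BC] + 1e-12)
        assert np.all(act >= 0)

    def test_zero_dose_continues_disease(self, bcpm_default, pkpd1_pk,
                                         pkpd1_pd, pre_cache):
        ts = simulate_treatment(15.0, "none", "pkpd1", pkpd1_pk,
                                bcpm_default, pkpd1_pd, years_treat=1.0,
                                pre_cache=pre_cache)
        post = ts.t >= ts.treatment_start
        assert np.nanmax(ts.bdg_pct[post]) <= 0.0

    def test_regimen_must_fit_horizon(self, bcpm_default, pkpd1_pk,
                                      pkpd1_pd, pre_cache):
        from bonepkpd.pk import build_schedule
        sch = build_schedule("weekly70", 730)
        with pytest.raises(ValueError):
            simulate_treatment(15.0, sch, "pkpd1", pkpd1_pk, bcpm_default,
                               pkpd1_pd, years_treat=0.5,
                               pre_cache=pre_cache)

    def test_output_frame_has_union_of_columns(self, treat15_weekly):
        df = treat15_weekly.to_frame()
        for col in ("time_d", "cc_mg", "bc_mg", "urine_mg", "serum_ng_ml",
                    "obp", "oba", "ocp", "oca", "ot", "f_bm_pct",
                    "ash_mean", "rho_g_cm3", "bdg_pct"):
            assert col in df.columns

    def test_first_integral_through_treatment(self, treat15_weekly,
                                              bcpm_default):
        inv = treat15_weekly.ot - bcpm_default.eta * treat15_weekly.f_bm
        assert np.max(np.abs(inv - inv[0])) < 1e-6 * treat15_weekly.ot[0]
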