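"""Constant refinement: exact recovery, noisy recovery, SD calibration."""

import numpy as np
import pytest

from metallospec import (
    NoiseSpec,
    RefinementSpec,
    UsageError,
    fixture_model,
    fixture_spectral_profile,
    generate_campaign,
    refine,
    refine_shifts,
    refine_spectra,
)
from metallospec.refine import _emf_weights, WeightSpec

from helpers import joint_spectra_least_squares


def acid_base_campaign(seed, replicates=4, noise=None):
    model = fixture_model("gmt_acid_base_25C")
    spec = noise or NoiseSpec(seed=seed)
    spec.seed = seed
    return model, generate_campaign("potentiometry acid-base", model, spec, replicates)


class TestPotentiometricRefinement:
    def test_noiseless_exact_recovery(self):
        model, dss = acid_base_campaign(0, replicates=1, noise=NoiseSpec(0, 0, 0, 0))
        start = model.with_log_betas({"(GMT)H": 3.9})
        res = refine(dss, start, RefinementSpec(["log_beta:(GMT)H", "E0:0"]))
        assert res.converged
        assert res.values["log_beta:(GMT)H"] == pytest.approx(3.60, abs=1e-6)
        assert res.sigma_fit < 1e-6

    def test_noisy_recovery_within_three_sd(self):
        """4 replicates at instrument noise recover the protonation constant."""
        model, dss = acid_base_campaign(101)
        start = model.with_log_betas({"(GMT)H": 3.8})
        res = refine(dss, start, RefinementSpec(["log_beta:(GMT)H", "E0:*"]))
        assert res.converged
        err = abs(res.values["log_beta:(GMT)H"] - 3.60)
        assert err <= 3.0 * res.sd["log_beta:(GMT)H"]
        assert err <= 0.02
        # sigma_fit ~ 1 when the weight model matches the noise model
        assert 0.7 < res.sigma_fit < 1.4

    def test_metal_constants_recovered(self):
        """Zn 1:1 titrations recover both the MLH and MLOH constants."""
        model = fixture_model("zn_gmt_45C")
        dss = generate_campaign("potentiometry 1:1", model, NoiseSpec(seed=7), 4)
        start = model.with_log_betas({"Zn(GMT)H": 7.2, "Zn(GMT)OH": -5.3})
        res = refine(
            dss, start,
            RefinementSpec(["log_beta:Zn(GMT)H", "log_beta:Zn(GMT)OH", "E0:*"]),
        )
        assert res.converged
        for lab, truth in (("Zn(GMT)H", 7.63), ("Zn(GMT)OH", -4.40)):
            tok = f"log_beta:{lab}"
            assert abs(res.values[tok] - truth) <= 3.0 * res.sd[tok]

    def test_reported_sd_matches_empirical_scatter(self):
        """Reported SD within a factor of 2 of scatter over 20 noise seeds."""
        values, sds = [], []
        for seed in range(20):
            model, dss = acid_base_campaign(1000 + seed, replicates=1)
            res = refine(dss, model, RefinementSpec(["log_beta:(GMT)H", "E0:0"]))
            values.append(res.values["log_beta:(GMT)H"])
            sds.append(res.sd["log_beta:(GMT)H"])
        empirical = np.std(values, ddof=1)
        reported = np.median(sds)
        assert reported == pytest.approx(empirical, rel=1.0)  # factor of 2
        assert 0.5 <= reported / empirical <= 2.0

    def test_estimator_consistency_with_replicates(self):
        """Precision improves 1 -> 4 -> 16 replicates; errors stay in 3 SD."""
        sds = {}
        for n in (1, 4, 16):
            model, dss = acid_base_campaign(55, replicates=n)
            res = refine(
                dss, model, RefinementSpec(["log_beta:(GMT)H"] + [f"E0:{i}" for i in range(n)])
            )
            assert res.converged
            err = abs(res.values["log_beta:(GMT)H"] - 3.60)
            assert err <= 3.0 * res.sd["log_beta:(GMT)H"]
            sds[n] = res.sd["log_beta:(GMT)H"]
        assert sds[16] < sds[4] < sds[1]

    def test_invariant_to_dataset_and_observation_order(self):
        model, dss = acid_base_campaign(3, replicates=2)
        spec = RefinementSpec(["log_beta:(GMT)H", "E0:*"])
        a = refine(dss, model, spec)
        b = refine(dss[::-1], model, spec)
        assert a.values["log_beta:(GMT)H"] == pytest.approx(
            b.values["log_beta:(GMT)H"], abs=1e-8
        )
        # reversing the rows of one dataset
        import copy

        dss2 = copy.deepcopy(dss)
        for ds in dss2:
            ds.volumes = ds.volumes[::-1].copy()
            ds.emf = ds.emf[::-1].copy()
            ds.design.additions = list(ds.design.additions)
        c = refine(dss2, model, spec)
        assert a.values["log_beta:(GMT)H"] == pytest.approx(
            c.values["log_beta:(GMT)H"], abs=1e-8
        )

    def test_steep_equivalence_points_downweighted(self):
        model, dss = acid_base_campaign(9, replicates=1)
        w = _emf_weights(dss[0], WeightSpec())
        # flat buffer region carries near-maximal weight, the jump far less
        assert w.max() / w.min() > 100.0
        assert np.argmin(w) not in (0, len(w) - 1)

    def test_too_few_observations_rejected(self):
        model, dss = acid_base_campaign(1, replicates=1)
        ds = dss[0]
        ds.volumes = ds.volumes[:4]
        ds.emf = ds.emf[:4]
        with pytest.raises(UsageError):
            refine([ds], model, RefinementSpec(["log_beta:(GMT)H", "E0:0"]))


class TestSpectraRefinement:
    def test_noiseless_epsilon_recovery(self):
        model = fixture_model("gmt_acid_base_37C")
        dss = generate_campaign(
            "spectrophotometry acid-base", model, NoiseSpec(0, 0, 0, 0, seed=0), 1
        )
        truth = fixture_spectral_profile()
        start = model.with_log_betas({"(GMT)H": 3.8})
        res = refine_spectra(dss, start, RefinementSpec(["log_beta:(GMT)H"]))
        assert res.converged
        assert res.values["log_beta:(GMT)H"] == pytest.approx(3.51, abs=1e-6)
        for lab in ("(GMT)H", "GMT"):
            rec = res.extras["epsilon"][lab]
            ref = truth.epsilon[lab]
            assert np.allclose(rec, ref, rtol=1e-6, atol=1e-6 * ref.max())

    def test_noisy_epsilon_maxima_recovered(self):
        """sigma_Abs = 0.002: band maxima recovered within 2% of 14000/9500."""
        model = fixture_model("gmt_acid_base_37C")
        dss = generate_campaign(
            "spectrophotometry acid-base", model, NoiseSpec(seed=21), 4
        )
        res = refine_spectra(
            dss, model.with_log_betas({"(GMT)H": 3.3}),
            RefinementSpec(["log_beta:(GMT)H"]),
        )
        assert res.converged
        assert res.extras["epsilon"]["(GMT)H"].max() == pytest.approx(14000, rel=0.02)
        assert res.extras["epsilon"]["GMT"].max() == pytest.approx(9500, rel=0.02)
        tok = "log_beta:(GMT)H"
        assert abs(res.values[tok] - 3.51) <= 3.0 * res.sd[tok]

    def test_separable_solution_equals_joint_least_squares(self):
        """Variable projection lands on the full joint optimum of a small grid."""
        from metallospec.titration import _species_concentration_matrix

        model = fixture_model("gmt_acid_base_37C")
        wl = np.arange(250.0, 301.0, 5.0)
        profile = fixture_spectral_profile(wavelengths=wl)
        dss = generate_campaign(
            "spectrophotometry acid-base", model, NoiseSpec(seed=5), 1,
            profile=profile, pH_grid=np.arange(2.0, 6.1, 0.5),
        )
        ds = dss[0]

        def conc_of(logb):
            m = model.with_log_betas({"(GMT)H": logb})
            return _species_concentration_matrix(
                ds.pH, m, ds.totals, ["(GMT)H", "GMT"]
            )

        grid = np.arange(3.40, 3.62, 0.001)
        logb_joint, _ = joint_spectra_least_squares(
            ds.pH, ds.absorbance, ds.path_length, conc_of, grid
        )
        res = refine_spectra(
            [ds], model.with_log_betas({"(GMT)H": 3.45}),
            RefinementSpec(["log_beta:(GMT)H"]),
        )
        assert res.values["log_beta:(GMT)H"] == pytest.approx(logb_joint, abs=2e-3)


class TestShiftRefinement:
    def test_noiseless_shift_recovery(self):
        model = fixture_model("gmt_acid_base_25C")
        dss = generate_campaign("nmr acid-base", model, NoiseSpec(0, 0, 0, 0, 0), 1)
        res = refine_shifts(
            dss, model.with_log_betas({"(GMT)H": 3.3}),
            RefinementSpec(["log_beta:(GMT)H"]),
        )
        assert res.converged
        assert res.values["log_beta:(GMT)H"] == pytest.approx(3.60, abs=1e-6)
        assert res.extras["delta"]["(GMT)H"]["CH-6p"] == pytest.approx(7.90, abs=1e-8)
        assert res.extras["delta"]["GMT"]["CH-6p"] == pytest.approx(7.70, abs=1e-8)

    def test_noisy_shift_recovery_within_001_ppm(self):
        model = fixture_model("gmt_acid_base_25C")
        dss = generate_campaign("nmr acid-base", model, NoiseSpec(seed=13), 4)
        res = refine_shifts(
            dss, model.with_log_betas({"(GMT)H": 3.4}),
            RefinementSpec(["log_beta:(GMT)H"]),
        )
        assert res.converged
        for nuc, hl, l in (("CH-6p", 7.90, 7.70), ("CH-5p", 6.20, 6.00)):
            assert res.extras["delta"]["(GMT)H"][nuc] == pytest.approx(hl, abs=0.01)
            assert res.extras["delta"]["GMT"][nuc] == pytest.approx(l, abs=0.01)

    def test_nmr_and_potentiometry_agree_on_shared_truth(self):
        """Technique-specific estimates of the same constant are compatible."""
        model = fixture_model("gmt_acid_base_25C")
        nmr = generate_campaign("nmr acid-base", model, NoiseSpec(seed=31), 2)
        pot = generate_campaign("potentiometry acid-base", model, NoiseSpec(seed=32), 2)
        r_nmr = refine_shifts(
            nmr, model.with_log_betas({"(GMT)H": 3.4}),
            RefinementSpec(["log_beta:(GMT)H"]),
        )
        r_pot = refine(
            pot, model.with_log_betas({"(GMT)H": 3.8}),
            RefinementSpec(["log_beta:(GMT)H", "E0:*"]),
        )
        tok = "log_beta:(GMT)H"
        gap = abs(r_nmr.values[tok] - r_pot.values[tok])
        assert gap <= 2.0 * np.hypot(r_nmr.sd[tok], r_pot.sd[tok])


class TestCrossTechnique:
    def test_zn_constants_agree_between_potentiometry_and_uv(self):
        """Joint truth, independent techniques: estimates within combined 2 SD."""
        model = fixture_model("zn_gmt_45C")
        pot = generate_campaign("potentiometry 1:1", model, NoiseSpec(seed=71), 2)
        uv = generate_campaign("spectrophotometry 1:1", model, NoiseSpec(seed=72), 2)
        toks = ["log_beta:Zn(GMT)H", "log_beta:Zn(GMT)OH"]
        r_pot = refine(
            pot, model.with_log_betas({"Zn(GMT)H": 7.4, "Zn(GMT)OH": -4.7}),
            RefinementSpec(toks + ["E0:*"]),
        )
        r_uv = refine_spectra(
            uv, model.with_log_betas({"Zn(GMT)H": 7.4, "Zn(GMT)OH": -4.7}),
            RefinementSpec(toks),
        )
        assert r_pot.converged and r_uv.converged
        for tok in toks:
            gap = abs(r_pot.values[tok] - r_uv.values[tok])
            assert gap <= 2.0 * np.hypot(r_pot.sd[tok], r_uv.sd[tok])


def test_unidentifiable_parameter_is_flagged():
    """A species that never forms leaves a rank-deficient Jacobian."""
    import dataclasses

    from metallospec.model import SpeciesDef

    model = fixture_model("ca_gmt_45C")
    extended = dataclasses.replace(
        model,
        species=list(model.species)
        + [SpeciesDef("Ca(GMT)OH", {"Ca": 1, "GMT": 1, "H": -1}, -12.0)],
    )
    dss = generate_campaign("potentiometry 1:1", model, NoiseSpec(seed=2), 1)
    ds = dss[0]
    # acid-side observations only: a log beta of -12 hydroxo species has
    # zero influence there, leaving its Jacobian column empty
    keep = 40
    ds.volumes = ds.volumes[:keep]
    ds.emf = ds.emf[:keep]
    res = refine(
        [ds], extended,
        RefinementSpec(["log_beta:Ca(GMT)H", "log_beta:Ca(GMT)OH", "E0:0"]),
    )
    assert "log_beta:Ca(GMT)OH" in res.flagged_parameters
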