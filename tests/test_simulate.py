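"""Generator determinism, truth-in-manifest, and statistical calibration."""

import numpy as np
import pytest

from halokit.doseresponse import predict_response
from halokit.errors import ConstructionError, ParameterError
from halokit.simulate import (
    DEFAULT_CONCENTRATIONS,
    build_synthetic_ck2_complex,
    build_synthetic_complex,
    gen_contact_distances,
    gen_dose_response,
    gen_qsar_table,
    mixture_truncated_cdf,
)
from halokit.structure import parse_structure, scan_contacts


class TestDeterminism:
    def test_dose_response_reproducible(self):
        a, ma = gen_dose_response(0.56, 1000.0, 100.0, cv=0.05, replicates=3, seed=13)
        b, mb = gen_dose_response(0.56, 1000.0, 100.0, cv=0.05, replicates=3, seed=13)
        assert a.equals(b) and ma == mb

    def test_contact_distances_reproducible(self):
        a, _ = gen_contact_distances(200, seed=99)
        b, _ = gen_contact_distances(200, seed=99)
        np.testing.assert_array_equal(a, b)

    def test_complex_bytes_identical(self):
        planted = [(3.1, 160.0, 135.0, "sidechain_O")]
        t1, m1 = build_synthetic_complex(planted, seed=5)
        t2, m2 = build_synthetic_complex(planted, seed=5)
        assert t1 == t2 and m1 == m2

    def test_qsar_table_reproducible(self):
        a, _ = gen_qsar_table(8, noise_sd=0.1, seed=3)
        b, _ = gen_qsar_table(8, noise_sd=0.1, seed=3)
        assert a.equals(b)


class TestDoseResponseGenerator:
    def test_noiseless_points_lie_on_curve(self):
        df, m = gen_dose_response(1.0, 1000.0, 100.0, cv=0.0, seed=0)
        expected = predict_response(1.0, 1000.0, 100.0, df.concentration_uM.values)
        np.testing.assert_allclose(df.counts.values, expected, rtol=1e-12)

    def test_default_grid_is_seven_point_geometric_series(self):
        x = np.asarray(DEFAULT_CONCENTRATIONS)
        assert x.size == 7
        assert x[0] == pytest.approx(0.016)
        assert x[-1] == pytest.approx(250.0)
        ratios = x[1:] / x[:-1]
        np.testing.assert_allclose(ratios, ratios[0], rtol=1e-9)

    def test_sample_mean_matches_model_within_clt_error(self):
        n_rep = 4000
        df, _ = gen_dose_response(0.56, 1000.0, 100.0, cv=0.05, replicates=n_rep, seed=17)
        model = predict_response(0.56, 1000.0, 100.0, np.asarray(DEFAULT_CONCENTRATIONS))
        for xi, mi in zip(DEFAULT_CONCENTRATIONS, model):
            sample = df[df.concentration_uM == xi].counts
            se = 0.05 * mi / np.sqrt(n_rep)
            assert abs(sample.mean() - mi) < 4 * se

    def test_poisson_option_and_bad_noise_name(self):
        df, m = gen_dose_response(1.0, 500.0, 50.0, noise="poisson", seed=2)
        assert np.allclose(df.counts, np.round(df.counts))
        with pytest.raises(ParameterError):
            gen_dose_response(1.0, 500.0, 50.0, noise="laplace")


class TestContactDistanceGenerator:
    def test_pure_gaussian_mode_loops_back_through_cdf_fit(self):
        from halokit.distfit import fit_gaussian_cdf

        d, _ = gen_contact_distances(5000, w2=0.0, window=(2.0, 5.0), seed=31)
        fit = fit_gaussian_cdf(d)
        assert fit.mu_ == pytest.approx(3.34, abs=0.02)
        assert fit.sigma_ == pytest.approx(0.28, abs=0.02)

    def test_samples_confined_to_window(self):
        d, _ = gen_contact_distances(1000, seed=7)
        assert d.min() >= 2.5 and d.max() <= 4.0

    def test_empirical_fraction_matches_analytic_truncated_cdf(self):
        n = 20000
        d, m = gen_contact_distances(n, seed=23)
        p = mixture_truncated_cdf(3.0, 3.34, 0.28, 2.90, 0.04, 0.15, (2.5, 4.0))
        frac = np.mean(d <= 3.0)
        binom_sd = np.sqrt(p * (1 - p) / n)
        assert abs(frac - p) < 4 * binom_sd

    def test_parameter_validation(self):
        with pytest.raises(ParameterError):
            gen_contact_distances(10, w2=1.5)
        with pytest.raises(ParameterError):
            gen_contact_distances(10, window=(4.0, 2.5))
        with pytest.raises(ParameterError):
            gen_contact_distances(10, mu1=50.0, mu2=50.0, window=(2.5, 4.0))


class TestSyntheticComplex:
    def test_scanner_recovers_planted_contacts_exactly(self):
        planted = [
            (3.0, 170.0, 130.0, "backbone_carbonyl_O"),
            (3.2, 150.0, None, "water_O"),
        ]
        text, manifest = build_synthetic_complex(planted, seed=1)
        contacts = scan_contacts(parse_structure(text), ligand_selector="LIG")
        assert len(contacts) == len(manifest["planted"])
        for c, p in zip(
            sorted(contacts, key=lambda c: c.site.x_atom.serial), manifest["planted"]
        ):
            assert c.acceptor_class.value == p["acceptor_class"]
            assert c.d == pytest.approx(p["d"], abs=1e-9)
            assert c.theta_cxa == pytest.approx(p["theta_cxa"], abs=1e-9)
            if p["theta_xac"] is None:
                assert c.theta_xac is None
            else:
                assert c.theta_xac == pytest.approx(p["theta_xac"], abs=1e-9)

    def test_achieved_geometry_close_to_requested(self):
        text, manifest = build_synthetic_complex(
            [(3.25, 162.0, 144.0, "sidechain_N")], seed=9
        )
        p = manifest["planted"][0]
        assert p["d"] == pytest.approx(p["requested"]["d"], abs=2e-3)
        assert p["theta_cxa"] == pytest.approx(p["requested"]["theta_cxa"], abs=0.1)
        assert p["theta_xac"] == pytest.approx(p["requested"]["theta_xac"], abs=0.1)

    def test_zero_planted_contacts_scan_empty(self):
        text, _ = build_synthetic_complex([], seed=0)
        contacts = scan_contacts(parse_structure(text), ligand_selector="LIG")
        assert contacts == []

    def test_infeasible_geometry_rejected(self):
        with pytest.raises(ConstructionError):
            build_synthetic_complex([(1.0, 160.0, 130.0, "water_O")])
        with pytest.raises(ConstructionError):
            build_synthetic_complex([(3.0, 200.0, 130.0, "backbone_carbonyl_O")])
        with pytest.raises(ConstructionError):
            # anchored acceptor requires a defined anchor angle
            build_synthetic_complex([(3.0, 160.0, None, "backbone_carbonyl_O")])
        with pytest.raises(ConstructionError):
            # water has no anchor; an anchor angle is meaningless
            build_synthetic_complex([(3.0, 160.0, 120.0, "water_O")])

    def test_decoys_beyond_halogen_exclusion_zone(self):
        text, _ = build_synthetic_complex(
            [(3.0, 160.0, 130.0, "backbone_carbonyl_O")], seed=2, decoys=4
        )
        atoms = parse_structure(text)
        halogens = [a for a in atoms if a.element == "BR"]
        decoy_waters = [a for a in atoms if a.residue_name == "HOH" and a.residue_number >= 800]
        assert len(decoy_waters) == 4
        for w in decoy_waters:
            for x in halogens:
                assert np.linalg.norm(w.xyz - x.xyz) > 4.5


class TestStandInComplex:
    def test_ligand_carries_four_bromine_sites(self):
        text, manifest = build_synthetic_ck2_complex()
        atoms = parse_structure(text)
        from halokit.structure import find_halogen_sites

        sites = find_halogen_sites(atoms, manifest["planted"]["ligand_resname"])
        assert len(sites) == 4
        assert all(s.bonded for s in sites)

    def test_short_arginine_contact_and_triazole_asymmetry(self):
        text, manifest = build_synthetic_ck2_complex()
        atoms = parse_structure(text)
        contacts = scan_contacts(atoms, ligand_selector="TBT")
        arg = [c for c in contacts if c.acceptor.residue_name == "ARG"]
        assert len(arg) == 1
        assert arg[0].acceptor.name == "NE"
        assert arg[0].d == pytest.approx(manifest["achieved"]["br_ne_distance"], abs=1e-9)
        assert arg[0].d == pytest.approx(2.99, abs=2e-3)
        named = {a.name: a for a in atoms if a.residue_name == "TBT"}
        nn = sorted(
            [
                np.linalg.norm(named["N1"].xyz - named["N2"].xyz),
                np.linalg.norm(named["N2"].xyz - named["N3"].xyz),
            ]
        )
        assert nn[0] == pytest.approx(1.242, abs=2e-3)
        assert nn[1] == pytest.approx(1.419, abs=2e-3)


class TestQsarTableGenerator:
    def test_descriptor_ranges_bracket_measured_series(self):
        df, _ = gen_qsar_table(400, seed=8)
        assert df.Vmol.between(127.1, 213.0).all()
        assert df.pKa.between(4.78, 8.56).all()

    def test_coefficient_estimates_unbiased_over_replicates(self):
        from halokit.qsar import fit_linear_qsar

        true = {"intercept": 30.0, "Vmol": -0.12, "pKa": -2.1}
        est = []
        for seed in range(120):
            df, _ = gen_qsar_table(12, coefficients=true, noise_sd=0.25, seed=seed)
            fit = fit_linear_qsar(df, ["Vmol", "pKa"])
            est.append([fit.coef_["Vmol"], fit.coef_["pKa"]])
        est = np.asarray(est)
        for j, name in enumerate(["Vmol", "pKa"]):
            se = est[:, j].std(ddof=1) / np.sqrt(len(est))
            assert abs(est[:, j].mean() - true[name]) < 3 * se
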