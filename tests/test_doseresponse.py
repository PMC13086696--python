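"""Dose-response fitting: likelihood identities, recovery, selection, BMCs."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binomtest

from nanopotency.datasets import (
    CompoundSpec,
    ExperimentDesign,
    PotencyArchetype,
    generate_apical_dataset,
    true_bmc,
)
from nanopotency.doseresponse import (
    BmrSpec,
    bmc_from_model,
    fit_all_models,
    fit_bmc_records,
    fit_model,
    load_molar_masses,
    normalize_to_metal_uM,
    select_best_model,
)


class TestMetalNormalization:
    def test_zero_maps_to_zero(self, zinc):
        assert normalize_to_metal_uM(0.0, zinc) == 0.0

    def test_zno_single_metal_atom(self, zinc):
        # 100 µg/mL / 81.38 g/mol * 1000 = 1228.8 µM Zn
        assert normalize_to_metal_uM(100.0, zinc) == pytest.approx(1228.8, abs=0.1)

    def test_alumina_two_metal_atoms(self):
        al = CompoundSpec("Al2O3 NP", "Al2O3", "Al", 2, form_code=2)
        assert normalize_to_metal_uM(100.0, al) == pytest.approx(1961.6, abs=0.1)

    def test_unknown_formula_is_lookup_error(self):
        mystery = CompoundSpec("X", "XyZ9", "Xy")
        with pytest.raises(KeyError):
            normalize_to_metal_uM(10.0, mystery)

    def test_shipped_table_covers_all_study_formulas(self):
        from nanopotency.datasets import default_study_compounds

        formulas = {c.chemical_formula for c in default_study_compounds()}
        table = set(load_molar_masses()["chemical_formula"])
        assert formulas <= table


class TestFitModel:
    def test_zero_noise_exp3_parameter_recovery(self, noisefree_exp3_slice):
        fm = fit_model(noisefree_exp3_slice, "exp3", covariate=None)
        a, b, c, d = fm.params[None]
        assert a == pytest.approx(100.0, rel=1e-4)
        assert b == pytest.approx(-0.002, rel=1e-4)
        assert d == pytest.approx(1.0, rel=1e-4)
        assert fm.sigma < 1e-6

    def test_aic_identity(self, noisefree_exp3_slice):
        for fm in fit_all_models(noisefree_exp3_slice, covariate=None):
            assert fm.aic == pytest.approx(2 * fm.n_params - 2 * fm.log_likelihood)

    def test_flat_data_prefers_null_within_parameter_penalty(self, zinc):
        arch = PotencyArchetype("exp3", a=100, b=0.0, d=1, sigma=0.05)
        design = ExperimentDesign((0.0, 50.0, 100.0, 200.0), replicates=4,
                                  timepoints_h=(24.0,), seed=2)
        ds = generate_apical_dataset([zinc], {zinc.id: {"viability_24h": arch}}, design,
                                     endpoints=["viability_24h"])
        sl = pd.DataFrame({"concentration": ds.table["concentration_ug_per_ml"],
                           "response": ds.table["response"]})
        fits = {f.model_id: f for f in fit_all_models(sl, covariate=None)}
        null = fits.pop("null")
        for f in fits.values():
            dk = f.n_params - null.n_params
            assert null.aic <= f.aic + 2 * dk + 1e-6

    def test_covariate_never_lowers_log_likelihood(self, zinc):
        arch = PotencyArchetype("exp3", a=100, b=-0.004, d=1, sigma=0.1)
        design = ExperimentDesign((0.0, 50.0, 100.0, 200.0, 400.0), replicates=3,
                                  timepoints_h=(24.0, 48.0), seed=8)
        ds = generate_apical_dataset(
            [zinc], {zinc.id: {"viability_24h": arch, "viability_48h": arch}}, design,
            endpoints=["viability_24h", "viability_48h"])
        sl = pd.DataFrame({"concentration": ds.table["concentration_ug_per_ml"],
                           "response": ds.table["response"],
                           "timepoint_h": ds.table["timepoint_h"]})
        with_cov = fit_model(sl, "exp3", covariate="timepoint_h")
        without = fit_model(sl, "exp3", covariate=None)
        assert with_cov.log_likelihood >= without.log_likelihood - 1e-6
        assert len(with_cov.covariate_levels) == 2

    def test_nonpositive_responses_rejected(self):
        sl = pd.DataFrame({"concentration": [0, 0, 10, 10, 20, 20],
                           "response": [1.0, 1.0, 0.5, -0.1, 0.2, 0.2]})
        with pytest.raises(ValueError, match="positive"):
            fit_model(sl, "exp3", covariate=None)


class TestModelSelection:
    def _fm(self, aic, b=-0.002):
        from nanopotency.doseresponse import FittedModel

        return FittedModel("exp3", {None: (100.0, b, 1.0, 1.0)}, 0.1, -aic / 2,
                           0, aic, (None,))

    def test_lowest_aic_wins(self):
        cands = [self._fm(210.1), self._fm(205.3), self._fm(230.0)]
        assert select_best_model(cands, BmrSpec("relative", 0.5)) is cands[1]

    def test_exact_aic_tie_broken_by_lower_bmc(self):
        slow = self._fm(205.3, b=-0.002)   # BMC50 ~ 346
        fast = self._fm(205.3, b=-0.003)   # BMC50 ~ 231
        assert select_best_model([slow, fast], BmrSpec("relative", 0.5)) is fast

    def test_single_candidate_returned(self):
        only = self._fm(123.4)
        assert select_best_model([only], BmrSpec("relative", 0.25)) is only


class TestBmcFromModel:
    @pytest.mark.parametrize("arch", [
        PotencyArchetype("exp3", a=100, b=-0.002, d=1.2, sigma=0.0, direction="decrease"),
        PotencyArchetype("exp5", a=100, b=0.003, c=0.3, d=0.9, sigma=0.0, direction="decrease"),
        PotencyArchetype("hill", a=4, b=150, c=5, d=2, sigma=0.0, direction="increase"),
    ], ids=["exp3", "exp5", "hill"])
    def test_noise_free_fit_matches_closed_form_oracle(self, zinc, arch):
        design = ExperimentDesign((0.0, 25.0, 50.0, 100.0, 200.0, 400.0), replicates=2,
                                  timepoints_h=(24.0,), seed=0)
        ds = generate_apical_dataset([zinc], {zinc.id: {"ep_24h": arch}}, design,
                                     endpoints=["ep_24h"])
        sl = pd.DataFrame({"concentration": ds.table["concentration_ug_per_ml"],
                           "response": ds.table["response"]})
        model_id = {"exp3": "exp3", "exp5": "exp5", "hill": "hill5"}[arch.model_id]
        fm = fit_model(sl, model_id, covariate=None)
        for v in (0.05, 0.10, 0.25):
            rec = bmc_from_model(fm, BmrSpec("relative", v, arch.direction))
            assert rec.status == "ok"
            assert rec.bmc == pytest.approx(true_bmc(arch, BmrSpec("relative", v)), rel=1e-6)

    def test_bmc_monotone_in_bmr(self, noisefree_exp3_slice):
        fm = fit_model(noisefree_exp3_slice, "exp3", covariate=None)
        bmcs = [bmc_from_model(fm, BmrSpec("relative", v)).bmc
                for v in (0.05, 0.10, 0.25, 0.50)]
        assert all(x < y for x, y in zip(bmcs, bmcs[1:]))

    def test_asymptote_precludes_bmr(self):
        from nanopotency.doseresponse import FittedModel

        fm = FittedModel("exp5", {None: (100.0, 0.01, 0.95, 1.0)}, 0.1, 0.0, 5, 10.0, (None,))
        rec = bmc_from_model(fm, BmrSpec("relative", 0.25, "decrease"))
        assert rec.status == "unreachable" and rec.bmc is None

    def test_null_model_means_no_response(self):
        from nanopotency.doseresponse import FittedModel

        fm = FittedModel("null", {None: (100.0, 0.0, 1.0, 1.0)}, 0.1, 0.0, 2, 4.0, (None,))
        assert bmc_from_model(fm, BmrSpec("relative", 0.05)).status == "no_response"


class TestRecoveryUnderNoise:
    def test_bmc50_recovery_median_error_and_no_sign_bias(self, zinc):
        """100 noisy datasets (sigma=0.1, 3 reps): median |rel err| of BMC50
        below 10% and no systematic over/under-estimation."""
        arch = PotencyArchetype("exp3", a=100, b=-0.004, d=1.0, sigma=0.1,
                                direction="decrease")
        truth = true_bmc(arch, BmrSpec("relative", 0.5))
        design_base = (0.0, 25.0, 50.0, 100.0, 200.0, 400.0)
        errors = []
        for rep in range(100):
            design = ExperimentDesign(design_base, replicates=3, timepoints_h=(24.0,),
                                      seed=1000 + rep)
            ds = generate_apical_dataset([zinc], {zinc.id: {"viability_24h": arch}},
                                         design, endpoints=["viability_24h"])
            sl = pd.DataFrame({"concentration": ds.table["concentration_ug_per_ml"],
                               "response": ds.table["response"]})
            fits = fit_all_models(sl, covariate=None, seed=rep)
            best = select_best_model(fits, BmrSpec("relative", 0.5, "decrease"))
            rec = bmc_from_model(best, BmrSpec("relative", 0.5, "decrease"))
            if rec.status == "ok":
                errors.append((rec.bmc - truth) / truth)
        assert len(errors) >= 95
        errors = np.asarray(errors)
        assert np.median(np.abs(errors)) <= 0.10
        n_over = int(np.sum(errors > 0))
        assert binomtest(n_over, len(errors), 0.5).pvalue >= 0.01


class TestHighLevelDriver:
    def test_records_cover_all_bmr_endpoint_combinations(self, zinc):
        arch_v = PotencyArchetype("exp3", a=100, b=-0.004, d=1, sigma=0.05)
        arch_c = PotencyArchetype("exp5", a=4, b=0.01, c=4, d=1, sigma=0.05,
                                  direction="increase")
        design = ExperimentDesign((0.0, 25.0, 50.0, 100.0, 200.0), replicates=3,
                                  timepoints_h=(2.0, 4.0), seed=21)
        ds = generate_apical_dataset(
            [zinc], {zinc.id: {"comet_2h": arch_c, "comet_4h": arch_c}}, design,
            endpoints=["comet_2h", "comet_4h"])
        recs = fit_bmc_records(ds, compounds={zinc.id: zinc}, seed=0)
        # 4 BMRs x 2 timepoint endpoints
        assert len(recs) == 8
        ok = [r for r in recs if r.status == "ok"]
        assert ok and all(r.bmc_uM_metal == pytest.approx(
            r.bmc / 81.38 * 1000, rel=1e-9) for r in ok)
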