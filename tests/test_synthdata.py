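import dataclasses

import numpy as np
import pandas as pd
import pytest

from mirepos.containers import Signature, ValidationError
from mirepos.diffexpr import fold_change
from mirepos.connectivity import connectivity_score
from mirepos.repurpose import top_alterations
from mirepos.survival import cox_univariate
from mirepos.synthdata import (
    SynthConfig,
    gen_cellline_panel,
    gen_mirna_study,
    gen_perturbation_library,
    gen_survival_cohort,
    gen_target_db,
)


class TestConfigValidation:
    def test_planted_exceeding_features_rejected(self):
        with pytest.raises(ValidationError):
            SynthConfig(n_features=10, n_planted_de=11)

    def test_censor_rate_one_rejected(self):
        with pytest.raises(ValidationError):
            SynthConfig(censor_rate=1.0)

    def test_too_few_lines_rejected(self):
        with pytest.raises(ValidationError):
            gen_cellline_panel(SynthConfig(n_lines=8))


class TestMirnaStudy:
    def test_same_config_gives_identical_matrices(self, small_cfg):
        a, _ = gen_mirna_study(small_cfg)
        b, _ = gen_mirna_study(dataclasses.replace(small_cfg))
        pd.testing.assert_frame_equal(a.matrix.values, b.matrix.values)

    def test_zero_noise_fold_change_is_exact(self, small_cfg):
        cfg = dataclasses.replace(small_cfg, planted_log2fc=2.0, noise_sd=0.0,
                                  pair_effect_sd=0.0)
        study, truth = gen_mirna_study(cfg)
        tissue = study.samples_where(specimen="tissue")
        ann = study.annotation[study.annotation["sample_id"].isin(tissue)]
        fc = fold_change(study.matrix.subset_samples(tissue), ann)
        for feature, direction in truth.planted_de.items():
            expected = 4.0 if direction == "up" else 0.25
            assert fc[feature] == pytest.approx(expected, abs=1e-9)

    def test_mean_fold_change_calibrated_over_seeds(self, small_cfg):
        """Planted log2 shift of 1 with noise recovers a ~2-fold mean change."""
        cfg0 = dataclasses.replace(
            small_cfg, n_tumor=20, n_normal=20, n_matched_pairs=0,
            planted_log2fc=1.0, noise_sd=0.3, n_features=40, n_planted_de=6,
        )
        fcs = []
        for seed in range(50):
            cfg = dataclasses.replace(cfg0, seed=seed)
            study, truth = gen_mirna_study(cfg)
            tissue = study.samples_where(specimen="tissue")
            ann = study.annotation[study.annotation["sample_id"].isin(tissue)]
            fc = fold_change(study.matrix.subset_samples(tissue), ann)
            up = [f for f, d in truth.planted_de.items() if d == "up"]
            fcs.append(fc[up].mean())
        assert 1.7 <= np.mean(fcs) <= 2.3

    def test_blood_concordant_subset_shares_direction(self, small_cfg):
        cfg = dataclasses.replace(small_cfg, noise_sd=0.1)
        study, truth = gen_mirna_study(cfg)
        blood = study.samples_where(specimen="blood")
        ann = study.annotation[study.annotation["sample_id"].isin(blood)]
        fc = fold_change(study.matrix.subset_samples(blood), ann)
        for feature in truth.blood_concordant:
            direction = truth.planted_de[feature]
            assert (fc[feature] > 1) == (direction == "up")

    def test_control_probes_present(self, small_cfg):
        study, _ = gen_mirna_study(small_cfg)
        classes = set(study.matrix.probe_class.unique())
        assert {"measurement", "negative_control", "background"} <= classes

    def test_ground_truth_ids_resolve(self, small_cfg):
        study, truth = gen_mirna_study(small_cfg)
        features = set(study.matrix.feature_ids)
        assert set(truth.planted_de) <= features
        assert truth.blood_concordant <= features


class TestSurvivalCohort:
    def test_null_betas_cover_hr_one(self, small_cfg):
        """With no planted effect the Cox CI covers HR = 1 at nominal rate."""
        covered = total = 0
        for seed in range(100):
            cfg = dataclasses.replace(small_cfg, seed=seed, n_subjects=150)
            cohort, _ = gen_survival_cohort(cfg, ["f0", "f1"], betas={})
            for f in ["f0", "f1"]:
                x = cohort.expression.loc[f].to_numpy()
                res = cox_univariate(x, cohort.clinical["time"],
                                     cohort.clinical["event"])
                covered += res.ci_low <= 1.0 <= res.ci_high
                total += 2 - 1
        assert covered / total >= 0.90

    def test_high_censor_rate_mostly_censored(self, small_cfg):
        fracs = []
        for seed in range(5):
            cfg = dataclasses.replace(small_cfg, seed=seed, censor_rate=0.9,
                                      n_subjects=300)
            cohort, _ = gen_survival_cohort(cfg, ["f0"], betas={})
            fracs.append(1.0 - cohort.clinical["event"].mean())
        assert np.mean(fracs) >= 0.80

    def test_planted_beta_recovered(self, small_cfg):
        cfg = dataclasses.replace(small_cfg, seed=3, n_subjects=500)
        cohort, truth = gen_survival_cohort(cfg, ["f0"],
                                            betas={"f0": np.log(2)})
        assert truth.planted_prognostic == {"f0": pytest.approx(np.log(2))}
        x = cohort.expression.loc["f0"]
        z = (x - x.mean()) / x.std(ddof=1)
        res = cox_univariate(z.to_numpy(), cohort.clinical["time"],
                             cohort.clinical["event"])
        assert 1.6 <= res.hr <= 2.5

    def test_unknown_beta_feature_rejected(self, small_cfg):
        with pytest.raises(ValidationError):
            gen_survival_cohort(small_cfg, ["f0"], betas={"nope": 1.0})


class TestCellLinePanel:
    def test_zero_noise_planted_gene_sensitive_everywhere(self, small_cfg):
        from mirepos.drugsens import feature_calls, pan_table

        cfg = dataclasses.replace(small_cfg, panel_noise_sd=1e-12,
                                  protein_noise_sd=1e-12,
                                  response_noise_sd=1e-12)
        panel, truth = gen_cellline_panel(cfg)
        drugs = sorted(panel.responses["drug"].unique())
        gene = sorted(truth.planted_sensitive_genes)[0]
        for level, expr in (("mRNA", panel.mrna), ("protein", panel.protein)):
            calls = feature_calls(expr.loc[[gene]], panel.responses, drugs,
                                  level=level)
            assert (calls["call"] == "sensitive").all()
            assert set(calls["drug"]) == set(drugs)

    def test_planted_essential_gene_flagged(self, small_cfg):
        from mirepos.drugsens import essentiality

        panel, truth = gen_cellline_panel(small_cfg)
        for gene in truth.essential_genes:
            _, _, essential = essentiality(panel.crispr, panel.rnai, gene)
            assert essential

    def test_mutation_count_override_yields_top_gene(self, small_cfg):
        panel, _ = gen_cellline_panel(
            small_cfg,
            mutation_counts={"BRCA001": {"MUC3A": 6, "TTN": 2}},
        )
        alt = top_alterations(panel.mutations, panel.fusions, lines=["BRCA001"])
        assert alt.loc["BRCA001", "top_mutated"] == [("MUC3A", 6)]

    def test_protein_mean_centered(self, small_cfg):
        panel, _ = gen_cellline_panel(small_cfg)
        assert np.allclose(panel.protein.mean(axis=1), 0.0, atol=1e-9)

    def test_determinism(self, small_cfg):
        a, _ = gen_cellline_panel(small_cfg)
        b, _ = gen_cellline_panel(dataclasses.replace(small_cfg))
        pd.testing.assert_frame_equal(a.responses, b.responses)
        pd.testing.assert_frame_equal(a.mrna, b.mrna)


class TestTargetDb:
    def test_two_mirnas_three_targets_each(self, small_cfg):
        cfg = dataclasses.replace(small_cfg, targets_per_mirna=3)
        genes = [f"G{i}" for i in range(6)]
        table = gen_target_db(cfg, ["m1", "m2"], genes)
        assert len(table) == 6
        assert table.groupby("mirna_id").size().tolist() == [3, 3]

    def test_same_seed_identical_table(self, small_cfg):
        genes = [f"G{i}" for i in range(30)]
        a = gen_target_db(small_cfg, ["m1", "m2", "m3"], genes)
        b = gen_target_db(dataclasses.replace(small_cfg), ["m1", "m2", "m3"], genes)
        pd.testing.assert_frame_equal(a, b)

    def test_targets_within_universe_and_coverage(self, small_cfg):
        genes = [f"G{i}" for i in range(17)]
        table = gen_target_db(small_cfg, ["m1", "m2", "m3"], genes)
        assert set(table["target_gene"]) == set(genes)
        assert set(table["mirna_id"]) == {"m1", "m2", "m3"}

    def test_empty_universe_rejected(self, small_cfg):
        with pytest.raises(ValidationError):
            gen_target_db(small_cfg, [], ["G1"])


class TestPerturbationLibrary:
    def _signature(self):
        return Signature(up=[f"G{i}" for i in range(4)],
                         down=[f"G{i}" for i in range(4, 8)])

    def test_planted_hit_scores_one_at_zero_noise(self, small_cfg):
        genes = [f"G{i}" for i in range(40)]
        sig = self._signature()
        library, truth = gen_perturbation_library(small_cfg, sig, genes)
        for pid in truth.planted_hits:
            res = connectivity_score(sig, library.profile(pid))
            assert res.score == pytest.approx(1.0)

    def test_shuffled_profiles_rarely_score_high(self, small_cfg):
        # universe and signature sizes match the default study conditions
        genes = [f"G{i}" for i in range(200)]
        sig = Signature(up=[f"G{i}" for i in range(10)],
                        down=[f"G{i}" for i in range(10, 20)])
        low = 0
        n = 0
        for seed in range(10):
            cfg = dataclasses.replace(small_cfg, seed=seed, n_perturbagens=12,
                                      n_planted_hits=1, n_planted_decoys=1)
            library, truth = gen_perturbation_library(cfg, sig, genes)
            for pid in library.perturbagen_ids:
                if pid in truth.planted_hits | truth.planted_decoys:
                    continue
                res = connectivity_score(sig, library.profile(pid))
                low += abs(res.score) < 0.5
                n += 1
        assert low / n >= 0.95

    def test_hit_responses_potent_and_decoy_not(self, small_cfg):
        genes = [f"G{i}" for i in range(40)]
        library, truth = gen_perturbation_library(small_cfg, self._signature(),
                                                  genes)
        resp = library.responses
        hit = next(iter(truth.planted_hits))
        decoy = next(iter(truth.planted_decoys))
        hit_ic50 = resp[(resp["perturbagen_id"] == hit)
                        & (resp["measure"] == "IC50")]["value"]
        decoy_ic50 = resp[(resp["perturbagen_id"] == decoy)
                          & (resp["measure"] == "IC50")]["value"]
        assert hit_ic50.median() < 7 < decoy_ic50.median()

    def test_empty_signature_rejected(self, small_cfg):
        with pytest.raises(ValidationError):
            gen_perturbation_library(small_cfg, Signature(up=[], down=[]),
                                     ["G1", "G2"])
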