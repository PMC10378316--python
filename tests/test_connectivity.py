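"""Weighted-KS connectivity engine against brute-force running-sum oracles."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from mirepos.connectivity import (
    connectivity_score,
    es_weighted,
    permutation_p,
    screen_library,
)
from mirepos.containers import PerturbationLibrary, Signature, ValidationError


def _profile(scores_by_gene):
    return pd.Series(scores_by_gene, dtype=float)


def oracle_es(tags, profile, weight_exponent):
    """Step-by-step running-sum enumeration (independent of the engine)."""
    ranked = sorted(profile.items(), key=lambda kv: (-kv[1], kv[0]))
    genes = [g for g, _ in ranked]
    scores = np.array([s for _, s in ranked])
    tag_mask = np.array([g in set(tags) for g in genes])
    w = np.abs(scores) ** weight_exponent
    w_tags = w[tag_mask]
    if w_tags.sum() == 0:
        w_tags = np.ones(tag_mask.sum())
        w = np.ones(len(genes))
    running = 0.0
    best = 0.0
    n_miss = len(genes) - tag_mask.sum()
    for i, is_tag in enumerate(tag_mask):
        if is_tag:
            running += w[i] / w_tags.sum() if tag_mask[i] else 0
        else:
            running -= 1.0 / n_miss
        if abs(running) > abs(best):
            best = running
    return best


class TestEsWeighted:
    def test_top_two_tags_unweighted_is_one(self):
        profile = _profile({"A": 4.0, "B": 3.0, "C": 2.0, "D": 1.0})
        assert es_weighted(["A", "B"], profile, weight_exponent=0) == 1.0

    def test_bottom_two_tags_unweighted_is_minus_one(self):
        profile = _profile({"A": 4.0, "B": 3.0, "C": 2.0, "D": 1.0})
        assert es_weighted(["C", "D"], profile, weight_exponent=0) == -1.0

    def test_ten_gene_weighted_case_matches_running_sum(self):
        profile = _profile({f"g{i}": 10.0 - i for i in range(10)})
        tags = ["g1", "g4"]  # ranks 2 and 5
        assert es_weighted(tags, profile, 1) == pytest.approx(
            oracle_es(tags, profile, 1))

    @pytest.mark.parametrize("seed", range(8))
    def test_random_profiles_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 25))
        profile = _profile({f"g{i}": float(rng.normal()) for i in range(n)})
        k = int(rng.integers(1, n // 2 + 1))
        tags = list(rng.choice([f"g{i}" for i in range(n)], size=k,
                               replace=False))
        for w in (0, 1, 2):
            assert es_weighted(tags, profile, w) == pytest.approx(
                oracle_es(tags, profile, w), abs=1e-12)

    def test_no_overlap_rejected(self):
        with pytest.raises(ValidationError):
            es_weighted(["missing"], _profile({"A": 1.0, "B": 0.5}), 1)


class TestConnectivityScore:
    def _concordant_profile(self, n=12, n_up=3, n_down=3):
        genes = [f"g{i}" for i in range(n)]
        scores = np.linspace(2.0, -2.0, n)
        return (_profile(dict(zip(genes, scores))),
                Signature(up=genes[:n_up], down=genes[-n_down:]))

    def test_maximal_concordance_scores_one(self):
        profile, sig = self._concordant_profile()
        assert connectivity_score(sig, profile).score == pytest.approx(1.0)

    def test_inverted_profile_scores_minus_one(self):
        profile, sig = self._concordant_profile()
        assert connectivity_score(sig, -profile).score == pytest.approx(-1.0)

    def test_same_sign_enrichments_score_zero(self):
        # both up and down tags at the top: es_up and es_down share a sign
        genes = [f"g{i}" for i in range(10)]
        profile = _profile(dict(zip(genes, np.linspace(2, -2, 10))))
        sig = Signature(up=["g0", "g1"], down=["g2", "g3"])
        res = connectivity_score(sig, profile)
        assert res.es_up > 0 and res.es_down > 0
        assert res.score == 0.0

    def test_swapping_lists_negates_score(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(30)]
        profile = _profile(dict(zip(genes, rng.normal(size=30))))
        sig = Signature(up=genes[:4], down=genes[4:8])
        a = connectivity_score(sig, profile).score
        b = connectivity_score(sig.swapped(), profile).score
        assert a == pytest.approx(-b)

    def test_monotone_transform_invariance_unweighted(self):
        rng = np.random.default_rng(6)
        genes = [f"g{i}" for i in range(20)]
        scores = rng.normal(size=20)
        profile = _profile(dict(zip(genes, scores)))
        transformed = _profile(dict(zip(genes, np.exp(scores))))
        sig = Signature(up=genes[:3], down=genes[3:6])
        a = connectivity_score(sig, profile, weight_exponent=0).score
        b = connectivity_score(sig, transformed, weight_exponent=0).score
        assert a == pytest.approx(b)

    def test_empty_signature_rejected(self):
        with pytest.raises(ValidationError):
            connectivity_score(Signature(up=[], down=["g"]),
                               _profile({"g": 1.0, "h": 0.0}))


def oracle_permutation_p(signature, profile, weight_exponent=1.0):
    """Exhaustive enumeration over all ordered disjoint tag-set pairs."""
    genes = list(profile.index)
    obs = connectivity_score(signature, profile,
                             weight_exponent=weight_exponent).score
    n_up, n_down = len(signature.up), len(signature.down)
    count = total = 0
    for up in combinations(genes, n_up):
        for down in combinations([g for g in genes if g not in up], n_down):
            s = connectivity_score(Signature(up=list(up), down=list(down)),
                                   profile, weight_exponent=weight_exponent)
            count += abs(s.score) >= abs(obs) - 1e-12
            total += 1
    return count / total, total


class TestPermutationP:
    def test_tiny_universe_matches_exhaustive_enumeration(self):
        genes = [f"g{i}" for i in range(6)]
        profile = _profile(dict(zip(genes, [3.0, 2.0, 1.0, -1.0, -2.0, -3.0])))
        sig = Signature(up=["g0"], down=["g5"])
        p, res = permutation_p(sig, profile, n_perm=1000, seed=0)
        p_oracle, total = oracle_permutation_p(sig, profile)
        assert total == 30
        assert res.n_perm == 30
        assert p == pytest.approx(p_oracle)

    @pytest.mark.parametrize("seed", range(4))
    def test_exhaustive_on_random_small_universes(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 9))
        genes = [f"g{i}" for i in range(n)]
        profile = _profile(dict(zip(genes, rng.normal(size=n))))
        sig = Signature(up=genes[:2], down=genes[2:3])
        p, _ = permutation_p(sig, profile, n_perm=2000, seed=seed)
        p_oracle, _ = oracle_permutation_p(sig, profile)
        assert p == pytest.approx(p_oracle)

    def test_planted_concordant_profile_significant(self):
        genes = [f"g{i}" for i in range(200)]
        profile = _profile(dict(zip(genes, np.linspace(3, -3, 200))))
        sig = Signature(up=genes[:8], down=genes[-8:])
        p, res = permutation_p(sig, profile, n_perm=1000, seed=1)
        assert res.score == pytest.approx(1.0)
        assert p <= 0.01

    def test_zero_score_has_p_one(self):
        genes = [f"g{i}" for i in range(20)]
        profile = _profile(dict(zip(genes, np.linspace(2, -2, 20))))
        sig = Signature(up=["g0", "g1"], down=["g2", "g3"])  # same-sign ES
        p, res = permutation_p(sig, profile, n_perm=500, seed=0)
        assert res.score == 0.0
        assert p == pytest.approx(1.0)


class TestScreenLibrary:
    def _library(self, profiles: dict[str, pd.Series]):
        scores = pd.DataFrame(profiles)
        meta = pd.DataFrame(
            {"perturbagen_class": "compound", "compound_set": "setA"},
            index=pd.Index(list(profiles), name="perturbagen_id"))
        return PerturbationLibrary(scores=scores, meta=meta)

    def test_single_planted_hit_found_among_shuffles(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(100)]
        base = np.linspace(3, -3, 100)
        sig = Signature(up=genes[:6], down=genes[-6:])
        profiles = {"hit": pd.Series(base, index=genes)}
        for i in range(30):
            profiles[f"null{i:02d}"] = pd.Series(rng.permutation(base),
                                                 index=genes)
        screen = screen_library(sig, self._library(profiles), n_perm=300,
                                seed=2)
        hits = screen[screen["hit"]]
        assert list(hits["perturbagen_id"]) == ["hit"]

    def test_unattainable_threshold_empty(self):
        genes = [f"g{i}" for i in range(20)]
        sig = Signature(up=genes[:2], down=genes[-2:])
        profiles = {"a": pd.Series(np.linspace(1, -1, 20), index=genes)}
        screen = screen_library(sig, self._library(profiles), score_min=1.01,
                                n_perm=200, seed=0)
        assert not screen["hit"].any()

    def test_duplicate_hit_profiles_reported_in_id_order(self):
        genes = [f"g{i}" for i in range(30)]
        base = pd.Series(np.linspace(2, -2, 30), index=genes)
        sig = Signature(up=genes[:3], down=genes[-3:])
        screen = screen_library(sig, self._library({"b_hit": base,
                                                    "a_hit": base.copy()}),
                                n_perm=200, seed=0)
        assert list(screen["perturbagen_id"]) == ["a_hit", "b_hit"]
        assert screen["hit"].all()
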