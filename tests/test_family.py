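"""Family engine: rank tests, Akaike weights, refinement, classification."""

import itertools
import math

import numpy as np
import pytest

from g4families.family import (FamilySet, MergeConfig, RefinementConfig,
                               akaike_weights, classify, divergence_test,
                               merge_family_sets, refine, score_matrix,
                               wilcoxon_rank_sum)
from g4families.phmm import NullModel, build_from_alignment
from g4families.msa import Alignment, adjust_gaps, progressive_align
from g4families.simulate import SimConfig, simulate_family, Template


def exact_rank_sum_p(x, y) -> float:
    """Exhaustive one-sided p: P(rank sum of x >= observed) over all
    assignments of the pooled ranks (no ties)."""
    pooled = sorted(x + y)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    w_obs = sum(ranks[v] for v in x)
    nx = len(x)
    all_ranks = list(range(1, len(pooled) + 1))
    count = total = 0
    for combo in itertools.combinations(all_ranks, nx):
        total += 1
        if sum(combo) >= w_obs:
            count += 1
    return count / total


class TestWilcoxon:
    def test_depressed_direction_oracle_value(self):
        # enumeration: every one of the 20 rank assignments has W >= 6
        x, y = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        assert exact_rank_sum_p(x, y) == pytest.approx(1.0)
        assert wilcoxon_rank_sum(x, y) == pytest.approx(1.0)

    def test_elevated_direction_oracle_value(self):
        x, y = [4.0, 5.0, 6.0], [1.0, 2.0, 3.0]
        assert exact_rank_sum_p(x, y) == pytest.approx(1 / 20)
        assert wilcoxon_rank_sum(x, y) == pytest.approx(1 / 20)

    def test_matches_enumeration_on_random_small_samples(self):
        rng = np.random.default_rng(71)
        for _ in range(25):
            nx, ny = rng.integers(2, 6), rng.integers(2, 6)
            vals = rng.permutation(20)[: nx + ny].astype(float)
            x, y = list(vals[:nx]), list(vals[nx:])
            assert wilcoxon_rank_sum(x, y) == pytest.approx(
                exact_rank_sum_p(x, y)
            )

    def test_identical_samples_not_significant(self):
        x = [1.0, 5.0, 9.0, 13.0]
        y = [2.0, 6.0, 10.0, 14.0]
        assert wilcoxon_rank_sum(x, y) >= 0.4

    def test_empty_sample_error(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestAkaikeWeights:
    def test_equal_logliks_give_uniform_weights(self):
        for n in (2, 3, 7):
            w = akaike_weights([5.0] * n)
            assert np.allclose(w, 1 / n)

    def test_two_model_closed_form(self):
        # delta AIC of 2 -> weights 1/(1+e^-1) and e^-1/(1+e^-1)
        w = akaike_weights([0.0, -1.0])
        assert w[0] == pytest.approx(1 / (1 + math.exp(-1)))
        assert w[1] == pytest.approx(math.exp(-1) / (1 + math.exp(-1)))

    def test_parameter_count_penalty(self):
        # equal likelihoods, extra parameters halve e-support per unit AIC
        w = akaike_weights([0.0, 0.0], ks=[0, 1])
        assert w[0] > w[1]

    def test_sum_to_one_and_stability(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            ll = rng.normal(-500, 200, size=rng.integers(2, 9))
            w = akaike_weights(ll)
            assert w.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all(w >= 0)
        # extreme magnitudes do not overflow
        w = akaike_weights([-1e6, -1e6 + 1])
        assert w.sum() == pytest.approx(1.0)

    def test_empty_error(self):
        with pytest.raises(ValueError):
            akaike_weights([])


def _family_clusters(seed=0):
    """Three well-separated synthetic families as (clusters, seqs)."""
    cfg = SimConfig(sub_rate=0.03, indel_rate=0.0, seed=seed)
    templates = [
        Template((3, 3, 3, 3), ("TTA", "TTA", "TTA")),
        Template((3, 3, 3, 3), ("C", "C", "C")),
        Template((4, 4, 4, 4), ("ACAT", "AG", "TCCT")),
    ]
    seqs = {}
    clusters = []
    for fi, tpl in enumerate(templates):
        fam, _ = simulate_family(tpl, 10, cfg, seed=seed + fi)
        ids = []
        for sid, s in fam.items():
            qid = f"f{fi}_{sid}"
            seqs[qid] = s
            ids.append(qid)
        clusters.append(ids)
    return clusters, seqs


class TestScoreMatrixAndDivergence:
    def test_shapes_and_own_profile_dominance(self):
        clusters, seqs = _family_clusters()
        fams = []
        for c in clusters:
            aln = adjust_gaps(progressive_align({m: seqs[m] for m in c}))
            fams.append(build_from_alignment(aln))
        sets = [[seqs[m] for m in c] for c in clusters]
        scores = score_matrix(fams, sets)
        assert len(scores) == 3 and len(scores[0]) == 3
        for i in range(3):
            for j in range(3):
                assert scores[i][j].shape == (10,)
                if i != j:
                    assert scores[i][i].mean() > scores[i][j].mean()
        distinct, pvals = divergence_test(scores)
        assert distinct == [True, True, True]
        assert np.all(pvals[~np.isnan(pvals)] < 0.05)

    def test_duplicated_profile_is_not_distinct(self):
        clusters, seqs = _family_clusters()
        c = clusters[0]
        aln = adjust_gaps(progressive_align({m: seqs[m] for m in c}))
        hmm = build_from_alignment(aln)
        scores = score_matrix([hmm, hmm], [[seqs[m] for m in c]] * 2)
        distinct, _ = divergence_test(scores)
        assert distinct == [False, False]

    def test_mismatched_inputs_error(self):
        with pytest.raises(ValueError):
            score_matrix([], [["GGG"]])


class TestRefine:
    def test_recovers_well_separated_families(self):
        clusters, seqs = _family_clusters()
        fs = refine(clusters, seqs)
        assert len(fs) == 3
        truth = {m: int(m[1]) for m in seqs}
        from sklearn.metrics import adjusted_rand_score

        pred, true = [], []
        for fi, fam in enumerate(fs.families):
            for m in fam.members:
                pred.append(fi)
                true.append(truth[m])
        assert adjusted_rand_score(true, pred) >= 0.9

    def test_identical_clusters_merge_into_one_family(self):
        cfg = SimConfig(sub_rate=0.03, indel_rate=0.0, seed=3)
        tpl = Template((3, 3, 3, 3), ("TTA", "ACA", "TC"))
        fam, _ = simulate_family(tpl, 12, cfg, seed=9)
        seqs = dict(fam)
        ids = sorted(seqs)
        fs = refine([ids[:6], ids[6:]], seqs)
        assert len(fs) == 1
        assert sorted(fs.families[0].members) == ids

    def test_single_iteration_flags_convergence_state(self):
        cfg = RefinementConfig(max_iter=1)
        clusters, seqs = _family_clusters()
        fs = refine(clusters, seqs, cfg)
        for fam in fs.families:
            assert "converged" in fam.provenance

    def test_idempotent_on_own_output(self):
        clusters, seqs = _family_clusters()
        fs = refine(clusters, seqs)
        again = refine([f.members for f in fs.families], seqs)
        assert [sorted(f.members) for f in again.families] == [
            sorted(f.members) for f in fs.families
        ]

    def test_accepted_families_satisfy_thresholds_post_hoc(self):
        clusters, seqs = _family_clusters()
        cfg = RefinementConfig()
        fs = refine(clusters, seqs, cfg)
        assert len(fs) >= 2
        fams = fs.families
        profiles = [f.hmm for f in fams]
        sets = [[seqs[m] for m in f.members] for f in fams]
        scores = score_matrix(profiles, sets, fs.null)
        distinct, _ = divergence_test(scores, cfg.alpha)
        for fam, d in zip(fams, distinct):
            assert d
            assert fam.gap_score < cfg.gap_max
            assert len(fam.members) >= 4

    def test_empty_input_empty_family_set(self):
        assert len(refine([], {})) == 0


class TestClassify:
    def test_verbatim_member_wins_with_high_weight(self):
        clusters, seqs = _family_clusters()
        fs = refine(clusters, seqs)
        member = clusters[1][0]
        truth_family = [
            f.id for f in fs.families if member in f.members
        ][0]
        res = classify(seqs[member], fs, member)
        assert res.best_family == truth_family
        assert res.akaike_weight >= 0.7

    def test_single_family_weight_is_one(self):
        cfg = SimConfig(sub_rate=0.03, indel_rate=0.0, seed=5)
        fam, _ = simulate_family(
            Template((3, 3, 3, 3), ("TTA", "ACA", "TC")), 8, cfg, seed=2
        )
        fs = refine([sorted(fam)], dict(fam))
        assert len(fs) == 1
        res = classify("GGGTTAGGGACAGGGTCGGG", fs)
        assert res.akaike_weight == pytest.approx(1.0)

    def test_weights_sum_to_one_and_argmax_is_best(self):
        clusters, seqs = _family_clusters()
        fs = refine(clusters, seqs)
        res = classify("GGGCGGGCGGGCGGG", fs)
        assert sum(res.weights.values()) == pytest.approx(1.0, abs=1e-9)
        assert res.best_family == max(res.weights, key=res.weights.get)

    def test_pu27_minimal_subsequence_report(self):
        """A Pu27-style report: every 4-tract placement of the c-MYC NHE
        G4 is scored with sequence, length, log odds, weight and family."""
        from g4families.detect import (DetectionParams, detect_regions,
                                       enumerate_matches)

        clusters, seqs = _family_clusters()
        fs = refine(clusters, seqs)
        pu27 = "TGGGGAGGGTGGGGAGGGTGGGGAAGG"
        region = detect_regions(pu27, DetectionParams(strands="plus"))[0]
        rows = []
        for match in enumerate_matches(region, extended=True):
            sub = region.sequence[match.start:match.end]
            res = classify(sub, fs)
            rows.append({
                "sequence": sub, "length": len(sub),
                "log_odds": res.log_odds, "akaike_weight": res.akaike_weight,
                "family": res.best_family,
            })
        assert rows
        for row in rows:
            assert set(row) == {
                "sequence", "length", "log_odds", "akaike_weight", "family"
            }
            assert row["length"] == len(row["sequence"])
            assert 0 < row["akaike_weight"] <= 1

    def test_empty_family_set_error(self):
        with pytest.raises(ValueError):
            classify("GGGAGGG", FamilySet(families=[]))


class TestMergeFamilySets:
    def test_same_family_via_two_routes_is_merged(self):
        cfg = SimConfig(sub_rate=0.03, indel_rate=0.0, seed=11)
        tpl = Template((3, 3, 3, 3), ("TTA", "ACA", "TC"))
        fam, _ = simulate_family(tpl, 16, cfg, seed=21)
        seqs = dict(fam)
        ids = sorted(seqs)
        fs1 = refine([ids[:8]], seqs)
        fs2 = refine([ids[8:]], seqs)
        merged = merge_family_sets([fs1, fs2], seqs)
        assert len(merged) == 1
        assert sorted(merged.families[0].members) == ids

    def test_disjoint_families_unchanged(self):
        clusters, seqs = _family_clusters()
        fs1 = refine([clusters[0]], seqs)
        fs2 = refine([clusters[2]], seqs)
        merged = merge_family_sets([fs1, fs2], seqs)
        assert len(merged) == 2

    def test_count_never_increases(self):
        clusters, seqs = _family_clusters()
        fs = refine(clusters, seqs)
        merged = merge_family_sets([fs], seqs)
        assert len(merged) <= len(fs)


def test_family_set_json_round_trip():
    clusters, seqs = _family_clusters()
    fs = refine(clusters, seqs)
    restored = FamilySet.from_json(fs.to_json())
    assert [f.id for f in restored.families] == [f.id for f in fs.families]
    member = fs.families[0].members[0]
    a = classify(seqs[member], fs)
    b = classify(seqs[member], restored)
    assert a.best_family == b.best_family
    assert a.log_odds == pytest.approx(b.log_odds)
    with pytest.raises(ValueError):
        FamilySet.from_json('{"bundle_version": 99, "families": []}')


def test_bh_correction_is_no_less_conservative():
    clusters, seqs = _family_clusters()
    fams = []
    for c in clusters:
        aln = adjust_gaps(progressive_align({m: seqs[m] for m in c}))
        fams.append(build_from_alignment(aln))
    scores = score_matrix(fams, [[seqs[m] for m in c] for c in clusters])
    raw, _ = divergence_test(scores)
    bh, _ = divergence_test(scores, correction="bh")
    for r, b in zip(raw, bh):
        if b:
            assert r  # BH-adjusted p-values are never smaller than raw
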