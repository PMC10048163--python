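"""Profile HMM: training counts, forward/Viterbi, sampling, serialization."""

import json
import math

import numpy as np
import pytest

from g4families.msa import Alignment
from g4families.phmm import (NullModel, ProfileHMM, build_from_alignment,
                             deserialize, forward_log_odds, forward_loglik,
                             sample, serialize, viterbi)

IDX = {c: i for i, c in enumerate("ACGT")}


def brute_force_paths(h: ProfileHMM, seq: str) -> float:
    """log P(seq|hmm) by exhaustive enumeration of all state paths."""
    m = h.m
    total = 0.0

    def rec(kind, node, i, p):
        nonlocal total
        if p == 0.0:
            return
        if kind == "M" and node == m + 1:
            if i == len(seq):
                total += p
            return
        if kind == "M" and node > 0:
            if i >= len(seq):
                return
            p *= h.match_emissions[node - 1, IDX[seq[i]]]
            i += 1
        elif kind == "I":
            if i >= len(seq):
                return
            p *= h.insert_emissions[node, IDX[seq[i]]]
            i += 1
        if kind == "M":
            rec("M", node + 1, i, p * h.t_mm[node])
            rec("I", node, i, p * h.t_mi[node])
            if node < m:
                rec("D", node + 1, i, p * h.t_md[node])
        elif kind == "I":
            rec("M", node + 1, i, p * h.t_im[node])
            rec("I", node, i, p * h.t_ii[node])
        else:
            rec("M", node + 1, i, p * h.t_dm[node])
            if node < m:
                rec("D", node + 1, i, p * h.t_dd[node])

    rec("M", 0, 0, 1.0)
    return math.log(total)


def brute_force_best_path(h: ProfileHMM, seq: str) -> float:
    """max over state paths of log P(path, seq | hmm)."""
    m = h.m
    best = [0.0]

    def rec(kind, node, i, p):
        if p == 0.0:
            return
        if kind == "M" and node == m + 1:
            if i == len(seq):
                best[0] = max(best[0], p)
            return
        if kind == "M" and node > 0:
            if i >= len(seq):
                return
            p *= h.match_emissions[node - 1, IDX[seq[i]]]
            i += 1
        elif kind == "I":
            if i >= len(seq):
                return
            p *= h.insert_emissions[node, IDX[seq[i]]]
            i += 1
        if kind == "M":
            rec("M", node + 1, i, p * h.t_mm[node])
            rec("I", node, i, p * h.t_mi[node])
            if node < m:
                rec("D", node + 1, i, p * h.t_md[node])
        elif kind == "I":
            rec("M", node + 1, i, p * h.t_im[node])
            rec("I", node, i, p * h.t_ii[node])
        else:
            rec("M", node + 1, i, p * h.t_dm[node])
            if node < m:
                rec("D", node + 1, i, p * h.t_dd[node])

    rec("M", 0, 0, 1.0)
    return math.log(best[0])


def _random_small_models(n_models: int, seed: int):
    """Tiny trained profiles (m <= 3) from random gapped alignments."""
    rng = np.random.default_rng(seed)
    models = []
    while len(models) < n_models:
        nrows = int(rng.integers(2, 4))
        ncols = int(rng.integers(1, 4))
        rows = [
            (f"r{r}", "".join(rng.choice(list("ACGT-"), size=ncols)))
            for r in range(nrows)
        ]
        try:
            h = build_from_alignment(Alignment(rows))
        except ValueError:
            continue
        if h.m <= 3:
            models.append(h)
    return models


def _one_state_g_model() -> ProfileHMM:
    """Single match state emitting G with certainty, no inserts or deletes."""
    eye_g = np.array([[0.0, 0.0, 1.0, 0.0]])
    ins = np.full((2, 4), 0.25)
    one = np.ones(2)
    zero = np.zeros(2)
    return ProfileHMM(
        m=1,
        match_emissions=eye_g,
        insert_emissions=ins,
        t_mm=one, t_mi=zero, t_md=zero,
        t_im=one, t_ii=zero,
        t_dm=one, t_dd=zero,
    )


class TestBuild:
    def test_identical_ungapped_rows(self):
        aln = Alignment([("a", "GGG"), ("b", "GGG")])
        h = build_from_alignment(aln)
        assert h.m == 3
        # G dominates every match emission (2 counts + 1 pseudo vs 1 pseudo)
        assert np.all(h.match_emissions.argmax(axis=1) == IDX["G"])

    def test_gap_majority_column_becomes_insert(self):
        rows = [("a", "GAG"), ("b", "G-G"), ("c", "G-G"), ("d", "G-G"),
                ("e", "G-G")]
        h = build_from_alignment(Alignment(rows), match_rule=0.5)
        assert h.m == 2  # the 80%-gap middle column is modelled by inserts

    def test_normalisation_on_random_alignments(self):
        for h in _random_small_models(10, seed=3):
            assert np.allclose(h.match_emissions.sum(axis=1), 1.0)
            assert np.allclose(h.insert_emissions.sum(axis=1), 1.0)
            assert np.allclose(h.t_mm + h.t_mi + h.t_md, 1.0)
            assert np.allclose(h.t_im + h.t_ii, 1.0)
            assert np.allclose((h.t_dm + h.t_dd)[1:], 1.0)

    def test_too_few_rows_error(self):
        with pytest.raises(ValueError):
            build_from_alignment(Alignment([("a", "GGG")]))


class TestForward:
    def test_closed_form_single_state(self):
        h = _one_state_g_model()
        res = forward_log_odds(h, "G")
        assert res.log_odds == pytest.approx(math.log(4))
        assert res.forward_loglik == pytest.approx(0.0)

    def test_matches_path_enumeration(self):
        rng = np.random.default_rng(17)
        for h in _random_small_models(12, seed=11):
            for L in range(1, 5):
                seq = "".join(rng.choice(list("ACGT"), size=L))
                assert forward_loglik(h, seq) == pytest.approx(
                    brute_force_paths(h, seq), abs=1e-9
                )

    def test_empty_sequence_error(self):
        with pytest.raises(ValueError):
            forward_loglik(_one_state_g_model(), "")

    def test_loglik_nonpositive(self):
        rng = np.random.default_rng(23)
        for h in _random_small_models(8, seed=29):
            seq = "".join(rng.choice(list("ACGT"), size=3))
            assert forward_loglik(h, seq) <= 1e-12


class TestViterbi:
    def test_closed_form_single_state(self):
        path, score = viterbi(_one_state_g_model(), "G")
        assert path == ["M1"]
        assert score == pytest.approx(math.log(4))

    def test_matches_best_path_enumeration(self):
        rng = np.random.default_rng(41)
        null = NullModel()
        for h in _random_small_models(12, seed=43):
            for L in range(1, 5):
                seq = "".join(rng.choice(list("ACGT"), size=L))
                _, score = viterbi(h, seq, null)
                expected = brute_force_best_path(h, seq) - null.loglik(seq)
                assert score == pytest.approx(expected, abs=1e-9)

    def test_viterbi_never_exceeds_forward(self):
        rng = np.random.default_rng(47)
        null = NullModel()
        for h in _random_small_models(20, seed=53):
            for _ in range(5):
                seq = "".join(rng.choice(list("ACGT"), size=rng.integers(1, 6)))
                _, v = viterbi(h, seq, null)
                f = forward_log_odds(h, seq, null).log_odds
                assert v <= f + 1e-9

    def test_path_accounts_for_every_base(self):
        rng = np.random.default_rng(59)
        for h in _random_small_models(10, seed=61):
            seq = "".join(rng.choice(list("ACGT"), size=4))
            path, _ = viterbi(h, seq)
            emitting = sum(1 for s in path if s[0] in "MI")
            assert emitting == len(seq)


class TestSample:
    def test_deterministic_model_gives_identical_sequences(self):
        h = _one_state_g_model()
        assert sample(h, 5, seed=1) == ["G"] * 5

    def test_same_seed_reproduces(self):
        aln = Alignment([("a", "GGGAGGG"), ("b", "GGGTGGG"), ("c", "GGGAGGG")])
        h = build_from_alignment(aln)
        assert sample(h, 20, seed=7) == sample(h, 20, seed=7)
        assert sample(h, 20, seed=7) != sample(h, 20, seed=8)

    def test_sampled_base_frequencies_match_emissions(self):
        # hand-built 2-state model without inserts/deletes: every walk emits
        # exactly one base from each match row, so the expected base mix is
        # the average of the two emission rows
        em = np.array([[0.1, 0.2, 0.6, 0.1], [0.25, 0.25, 0.25, 0.25]])
        ins = np.full((3, 4), 0.25)
        one, zero = np.ones(3), np.zeros(3)
        h = ProfileHMM(
            m=2, match_emissions=em, insert_emissions=ins,
            t_mm=one, t_mi=zero, t_md=zero,
            t_im=one, t_ii=zero, t_dm=one, t_dd=zero,
        )
        seqs = sample(h, 2000, seed=13)
        assert all(len(s) == 2 for s in seqs)
        bases = "".join(seqs)
        n = len(bases)
        for b, expect in zip("ACGT", em.mean(axis=0)):
            sigma = math.sqrt(expect * (1 - expect) / n)
            assert abs(bases.count(b) / n - expect) < 3 * sigma + 1e-6

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            sample(_one_state_g_model(), 0, seed=1)


class TestSerialization:
    def test_round_trip_random_models(self):
        for h in _random_small_models(6, seed=67):
            h2 = deserialize(serialize(h))
            assert h2.m == h.m
            assert np.allclose(h2.match_emissions, h.match_emissions)
            assert np.allclose(h2.t_mm, h.t_mm)
            assert np.allclose(h2.t_dd, h.t_dd)

    def test_scores_identical_after_reload(self):
        aln = Alignment([("a", "GGGAGGG"), ("b", "GGGTGGG")])
        h = build_from_alignment(aln)
        h2 = deserialize(serialize(h))
        for seq in ("GGGAGGG", "GGGTGGG", "ACGTACG"):
            assert forward_loglik(h2, seq) == pytest.approx(
                forward_loglik(h, seq)
            )

    def test_corrupt_payload_raises_schema_error(self):
        h = _one_state_g_model()
        data = json.loads(serialize(h))
        del data["transitions"]
        with pytest.raises(ValueError):
            deserialize(json.dumps(data))
        data2 = json.loads(serialize(h))
        data2["schema_version"] = 99
        with pytest.raises(ValueError):
            deserialize(json.dumps(data2))


def test_parameter_recovery_from_samples():
    """Training on samples from a known model recovers its match emissions."""
    from g4families.msa import progressive_align, adjust_gaps

    template = Alignment(
        [(f"r{i}", "GGGAGGGTTGGGCGGG") for i in range(30)]
        + [(f"v{i}", "GGGTGGGTTGGGCGGG") for i in range(10)]
    )
    h = build_from_alignment(template)
    seqs = {f"s{i}": s for i, s in enumerate(sample(h, 400, seed=5)) if s}
    # align a manageable subset and retrain
    subset = {k: seqs[k] for k in list(seqs)[:60]}
    aln = adjust_gaps(progressive_align(subset))
    h2 = build_from_alignment(aln)
    # compare the dominant emission per match column over the G-tract region
    tv = 0.5 * np.abs(
        h.match_emissions[: min(h.m, h2.m)] - h2.match_emissions[: min(h.m, h2.m)]
    ).sum(axis=1)
    assert tv.mean() < 0.15


class TestLocalMode:
    def test_single_state_local_equals_global(self):
        h = _one_state_g_model()
        from g4families.phmm import forward_loglik

        assert forward_loglik(h, "G", local=True) == pytest.approx(
            forward_loglik(h, "G")
        )

    def test_partial_query_scores_better_locally(self):
        aln = Alignment([(f"r{i}", "GGGAGGGTTGGG") for i in range(10)])
        h = build_from_alignment(aln)
        from g4families.phmm import forward_loglik

        prefix = "GGGA"
        assert forward_loglik(h, prefix, local=True) > forward_loglik(
            h, prefix
        )

    def test_local_likelihood_nonpositive(self):
        from g4families.phmm import forward_loglik

        for h in _random_small_models(6, seed=71):
            assert forward_loglik(h, "GA", local=True) <= 1e-12
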