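"""Per-replicate network construction: motif scanning, panel regression,
TF activity, and the trans-regulation score."""

import numpy as np
import pandas as pd
import pytest

from crmnet.io import ExpressionMatrix, GenomicInterval, PWM, ValidationError
from crmnet.netbuild import (
    RegulatoryElement,
    build_replicate_network,
    dinucleotide_shuffle,
    expression_correlation,
    fit_interaction_model,
    motif_binding_matrix,
    scan_scores,
    tf_activity,
    trans_regulation_scores,
)
from crmnet.synthetic import TruthConfig, generate_truth, simulate_replicates

_COMP = str.maketrans("ACGT", "TGCA")


def consensus_pwm(consensus: str, threshold_frac: float = 0.8) -> PWM:
    counts = np.zeros((4, len(consensus)))
    for pos, base in enumerate(consensus):
        counts["ACGT".index(base), pos] = 12.0
    return PWM.from_counts(consensus, counts, threshold_frac=threshold_frac)


def brute_force_binding(seq: str, pwm: PWM) -> float:
    """Independent oracle: score every offset on both strands by explicit
    per-base lookup and sum the passing scores."""
    total = 0.0
    w = pwm.width
    for strand_seq in (seq, seq.translate(_COMP)[::-1]):
        for off in range(len(strand_seq) - w + 1):
            window = strand_seq[off : off + w]
            if any(b not in "ACGT" for b in window):
                continue
            score = sum(
                pwm.matrix["ACGT".index(b), pos] for pos, b in enumerate(window)
            )
            if score >= pwm.threshold:
                total += score
    return total


def make_re(seq: str, accessibility: float = 1.0, start: int = 0) -> RegulatoryElement:
    return RegulatoryElement(
        GenomicInterval("chr1", start, start + len(seq)), accessibility, seq
    )


class TestMotifBinding:
    def test_no_hit_scores_zero(self):
        pwm = consensus_pwm("ACGTACGTAC")
        B = motif_binding_matrix([make_re("T" * 50)], [pwm])
        assert B[0, 0] == 0.0

    def test_single_perfect_match_equals_max_score(self):
        pwm = consensus_pwm("ACGTACGTAC")
        B = motif_binding_matrix([make_re("TTTT" + "ACGTACGTAC" + "TTTT")], [pwm])
        assert B[0, 0] == pytest.approx(pwm.max_score)

    def test_reverse_strand_hit_found(self):
        consensus = "AACCGGTTAA"
        rc = consensus.translate(_COMP)[::-1]
        pwm = consensus_pwm(consensus)
        B = motif_binding_matrix([make_re("TT" + rc + "GG")], [pwm])
        assert B[0, 0] == pytest.approx(pwm.max_score)

    def test_two_hits_sum_matches_brute_force(self, rng):
        pwm = consensus_pwm("ACGTACGTAC")
        for _ in range(5):
            bases = "".join(rng.choice(list("ACGT"), size=120))
            seq = bases[:20] + "ACGTACGTAC" + bases[30:80] + "ACGTACGTAC" + bases[90:]
            B = motif_binding_matrix([make_re(seq)], [pwm])
            assert B[0, 0] == pytest.approx(brute_force_binding(seq, pwm))
            assert B[0, 0] >= 2 * pwm.max_score - 1e-9

    def test_pwm_wider_than_re_scores_zero(self):
        pwm = consensus_pwm("ACGTACGTAC")
        B = motif_binding_matrix([make_re("ACG")], [pwm])
        assert B[0, 0] == 0.0

    def test_missing_sequence_rejected(self):
        re_ = RegulatoryElement(GenomicInterval("chr1", 0, 10), 1.0, None)
        with pytest.raises(ValidationError):
            motif_binding_matrix([re_], [consensus_pwm("ACGT")])

    def test_ambiguous_bases_never_score(self):
        pwm = consensus_pwm("ACGT")
        scores = scan_scores("ACNTACGT", pwm)
        assert np.isneginf(scores[:, :2]).all()  # windows covering the N


class TestInteractionModel:
    def test_exact_linear_recovery(self, rng):
        n = 30
        access = rng.random((3, n))
        y = 2.0 * access[1] + 1.0
        expr = ExpressionMatrix(
            pd.DataFrame([y], index=["g1"], columns=[f"s{i}" for i in range(n)])
        )
        model = fit_interaction_model(expr, access, {"g1": [1]})
        assert model.intercepts["g1"] == pytest.approx(1.0, abs=1e-8)
        assert model.weights["g1"][0] == pytest.approx(2.0, abs=1e-8)

    def test_pure_noise_weights_within_standard_errors(self):
        # for a gene unrelated to its candidate REs the fitted weight should
        # be within 3 standard errors of zero almost always
        hits = 0
        trials = 100
        for seed in range(trials):
            rng = np.random.default_rng(seed)
            n = 200
            access = rng.random((1, n))
            y = rng.normal(size=n)
            expr = ExpressionMatrix(
                pd.DataFrame([y], index=["g"], columns=[f"s{i}" for i in range(n)])
            )
            model = fit_interaction_model(expr, access, {"g": [0]})
            beta = model.weights["g"][0]
            X = np.column_stack([np.ones(n), access[0]])
            resid = y - X @ np.array([model.intercepts["g"], beta])
            sigma2 = resid @ resid / (n - 2)
            se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
            if abs(beta) < 3 * se:
                hits += 1
        assert hits >= 95

    def test_parameter_recovery_under_noise(self):
        rng = np.random.default_rng(7)
        n, p = 148, 5
        access = rng.random((p, n))
        truth = rng.uniform(0.5, 1.5, size=p)
        y = 0.3 + truth @ access + rng.normal(0, 0.1, size=n)
        expr = ExpressionMatrix(
            pd.DataFrame([y], index=["g"], columns=[f"s{i}" for i in range(n)])
        )
        model = fit_interaction_model(expr, access, {"g": list(range(p))})
        rmse = np.sqrt(np.mean((model.weights["g"] - truth) ** 2))
        assert rmse < 0.1

    def test_empty_candidates_gives_intercept_only(self):
        expr = ExpressionMatrix(
            pd.DataFrame([[1.0, 3.0]], index=["g"], columns=["s1", "s2"])
        )
        model = fit_interaction_model(expr, np.zeros((2, 2)), {"g": []})
        assert model.intercepts["g"] == 2.0
        assert model.weights["g"].size == 0

    def test_underdetermined_without_ridge_instructs_ridge(self):
        expr = ExpressionMatrix(
            pd.DataFrame([[1.0, 2.0]], index=["g"], columns=["s1", "s2"])
        )
        access = np.ones((4, 2))
        with pytest.raises(ValidationError, match="ridge"):
            fit_interaction_model(expr, access, {"g": [0, 1, 2, 3]})
        # and succeeds once a ridge penalty is supplied
        model = fit_interaction_model(expr, access, {"g": [0, 1, 2, 3]}, ridge_lambda=1.0)
        assert model.weights["g"].shape == (4,)


class TestExpressionCorrelation:
    def _panel(self, rows, genes):
        return ExpressionMatrix(
            pd.DataFrame(rows, index=genes,
                         columns=[f"s{i}" for i in range(len(rows[0]))])
        )

    def test_identical_series_correlate_one(self, rng):
        x = rng.random(20)
        panel = self._panel([x, x], ["tf", "tg"])
        R = expression_correlation(panel, ["tf"], ["tg"])
        assert R[0, 0] == pytest.approx(1.0)

    def test_affine_decreasing_series_correlate_minus_one(self, rng):
        x = rng.random(20)
        panel = self._panel([x, x.max() - x], ["tf", "tg"])
        R = expression_correlation(panel, ["tf"], ["tg"])
        assert R[0, 0] == pytest.approx(-1.0)

    def test_constant_series_correlate_zero(self, rng):
        panel = self._panel([np.full(10, 3.0), rng.random(10)], ["tf", "tg"])
        assert expression_correlation(panel, ["tf"], ["tg"])[0, 0] == 0.0

    def test_matches_textbook_formula(self, rng):
        x, y = rng.random(50), rng.random(50)
        panel = self._panel([x, y], ["tf", "tg"])
        R = expression_correlation(panel, ["tf"], ["tg"])
        expected = (
            np.mean((x - x.mean()) * (y - y.mean())) / (x.std() * y.std())
        )
        assert R[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_missing_gene_listed(self, rng):
        panel = self._panel([rng.random(5)], ["tf"])
        with pytest.raises(ValidationError, match="nope"):
            expression_correlation(panel, ["tf"], ["nope"])


class TestDinucleotideShuffle:
    def test_preserves_dinucleotide_counts(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=200))
        shuffled = dinucleotide_shuffle(seq, rng)
        def dinucs(s):
            counts = {}
            for a, b in zip(s, s[1:]):
                counts[a + b] = counts.get(a + b, 0) + 1
            return counts
        assert dinucs(shuffled) == dinucs(seq)
        assert shuffled[0] == seq[0] and shuffled[-1] == seq[-1]


class TestTfActivity:
    def test_unexpressed_tf_has_zero_activity(self):
        pwm = consensus_pwm("ACGTACGTAC")
        tfa = tf_activity({"tf": 0.0}, [pwm], ["tf"], [make_re("ACGT" * 30)], 2, 0)
        assert tfa[0] == 0.0

    def test_planted_motif_inflates_activity(self, rng):
        pwm = consensus_pwm("ACGTTGCAAC")
        res = []
        for i in range(8):
            bases = "".join(rng.choice(list("ACGT"), size=100))
            res.append(make_re(bases[:30] + "ACGTTGCAAC" + bases[40:], start=i * 200))
        tfa = tf_activity({"tf": 4.0}, [pwm], ["tf"], res, 5, 1)
        # enrichment far above 1 pushes TFA above sqrt(expression * 1)
        assert tfa[0] > np.sqrt(4.0)

    def test_deterministic_under_fixed_seed(self, rng):
        pwm = consensus_pwm("ACGTTGCAAC")
        res = [make_re("".join(rng.choice(list("ACGT"), size=80)))]
        a = tf_activity({"tf": 2.0}, [pwm], ["tf"], res, 4, 9)
        b = tf_activity({"tf": 2.0}, [pwm], ["tf"], res, 4, 9)
        assert np.array_equal(a, b)

    def test_shuffles_must_be_positive(self):
        with pytest.raises(ValidationError):
            tf_activity({"tf": 1.0}, [consensus_pwm("ACGT")], ["tf"],
                        [make_re("ACGT" * 5)], 0, 0)


class TestTransRegulationScores:
    def _model(self, weights):
        from crmnet.netbuild import InteractionModel

        return InteractionModel(
            {"g": list(range(len(weights)))}, {"g": np.asarray(weights, float)},
            {"g": 0.0},
        )

    def test_hand_worked_example(self):
        # inner = 1*0.5*1 + 2*1*0.5 = 1.5 ; times 2^|1| = 3 ; times sqrt(4*1)=2
        B = np.array([[1.0, 2.0]])
        S = trans_regulation_scores(
            B, np.array([0.5, 1.0]), self._model([1.0, 0.5]),
            np.array([[1.0]]), np.array([4.0]), np.array([1.0]), ["g"],
        )
        assert S[0, 0] == pytest.approx(6.0)

    def test_silent_target_scores_zero(self):
        B = np.array([[1.0, 2.0]])
        S = trans_regulation_scores(
            B, np.array([0.5, 1.0]), self._model([1.0, 0.5]),
            np.array([[1.0]]), np.array([4.0]), np.array([0.0]), ["g"],
        )
        assert S[0, 0] == 0.0

    def test_correlation_sign_is_irrelevant(self):
        B = np.array([[1.0, 2.0]])
        args = (np.array([0.5, 1.0]), self._model([1.0, 0.5]))
        s_pos = trans_regulation_scores(
            B, *args, np.array([[0.5]]), np.array([4.0]), np.array([1.0]), ["g"]
        )
        s_neg = trans_regulation_scores(
            B, *args, np.array([[-0.5]]), np.array([4.0]), np.array([1.0]), ["g"]
        )
        assert s_pos[0, 0] == pytest.approx(s_neg[0, 0])

    def test_negative_inner_sum_clamped(self):
        B = np.array([[1.0]])
        S = trans_regulation_scores(
            B, np.array([1.0]), self._model([-2.0]),
            np.array([[0.0]]), np.array([1.0]), np.array([1.0]), ["g"],
        )
        assert S[0, 0] == 0.0

    def test_linear_in_accessibility(self):
        B = np.array([[1.0, 2.0]])
        access = np.array([0.5, 1.0])
        common = (self._model([1.0, 0.5]), np.array([[0.3]]),
                  np.array([2.0]), np.array([1.5]), ["g"])
        s1 = trans_regulation_scores(B, access, *common)
        s2 = trans_regulation_scores(B, 2 * access, *common)
        assert s2[0, 0] == pytest.approx(2 * s1[0, 0])

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            trans_regulation_scores(
                np.ones((1, 2)), np.ones(3), self._model([1.0]),
                np.ones((1, 1)), np.ones(1), np.ones(1), ["g"],
            )


class TestBuildReplicateNetwork:
    def test_zero_noise_recovers_truth_support(self, small_truth):
        truth = small_truth
        _, samples = simulate_replicates(
            truth, sigma_s=0.0, crm_jitter=0, sigma_e=0.0, seed=4
        )
        model = fit_interaction_model(
            truth.panel_expr, truth.panel_access, truth.candidates
        )
        R = expression_correlation(truth.panel_expr, truth.tf_ids, truth.tg_ids)
        net = build_replicate_network(
            "r1", samples[0], truth.pwms, truth.tf_ids, truth.tg_ids,
            model, R, s_quantile=0.0, enrichment_shuffles=3, seed=5,
        )
        assert net.edges() == truth.network.edges()

    def test_crm_intervals_lie_in_candidate_set(self, small_truth):
        truth = small_truth
        _, samples = simulate_replicates(
            truth, sigma_s=0.0, crm_jitter=0, sigma_e=0.0, seed=4
        )
        model = fit_interaction_model(
            truth.panel_expr, truth.panel_access, truth.candidates
        )
        R = expression_correlation(truth.panel_expr, truth.tf_ids, truth.tg_ids)
        net = build_replicate_network(
            "r1", samples[0], truth.pwms, truth.tf_ids, truth.tg_ids,
            model, R, s_quantile=0.0, enrichment_shuffles=3, seed=5,
        )
        for t in net:
            candidate_ivs = [
                truth.res[k].interval for k in truth.candidates[t.tg]
            ]
            for iv in t.crm:
                assert any(iv.overlaps(c) for c in candidate_ivs)
            starts = [iv.start for iv in t.crm]
            assert starts == sorted(starts)

    def test_quantile_filter_shrinks_network(self, small_truth):
        truth = small_truth
        _, samples = simulate_replicates(truth, seed=4)
        model = fit_interaction_model(
            truth.panel_expr, truth.panel_access, truth.candidates
        )
        R = expression_correlation(truth.panel_expr, truth.tf_ids, truth.tg_ids)
        loose = build_replicate_network(
            "r1", samples[0], truth.pwms, truth.tf_ids, truth.tg_ids,
            model, R, s_quantile=0.0, enrichment_shuffles=2, seed=5,
        )
        strict = build_replicate_network(
            "r1", samples[0], truth.pwms, truth.tf_ids, truth.tg_ids,
            model, R, s_quantile=0.8, enrichment_shuffles=2, seed=5,
        )
        assert strict.edges() <= loose.edges()
        assert len(strict) < len(loose)
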