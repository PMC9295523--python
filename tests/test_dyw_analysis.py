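"""PWM construction, exact p-value scanning, and DYW completeness grading."""

import itertools

import numpy as np
import pytest

from pprscout.dyw_analysis import (
    AA_ALPHABET,
    build_pwm,
    grade_dyw,
    scan_pwm,
    score_distribution,
)
from pprscout.synthetic_data import (
    REGION_CONSENSUS,
    gen_region_blocks,
)


class TestBuildPwm:
    def test_degenerate_column(self):
        pwm = build_pwm(["AC"] * 4, pseudocount=0.0)
        assert pwm.matrix[0, AA_ALPHABET.index("A")] == pytest.approx(1.0, abs=1e-9)

    def test_even_split_column(self):
        pwm = build_pwm(["AA", "AC"], pseudocount=0.0)
        a, c = AA_ALPHABET.index("A"), AA_ALPHABET.index("C")
        assert pwm.matrix[1, a] == pytest.approx(0.5, abs=1e-9)
        assert pwm.matrix[1, c] == pytest.approx(0.5, abs=1e-9)

    def test_matches_counting_oracle_on_generated_domains(self):
        """PWM columns equal direct count-and-normalize on 231 generated
        region sequences."""
        block = gen_region_blocks(n=231, seed=11)["PG_box"]
        pc = 0.5
        pwm = build_pwm(block, pseudocount=pc)
        n = len(block)
        for j in range(len(block[0])):
            for ai, aa in enumerate(AA_ALPHABET):
                count = sum(s[j] == aa for s in block)
                assert pwm.matrix[j, ai] == pytest.approx(
                    (count + pc) / (n + 20 * pc)
                )

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            build_pwm(["AAA", "AA"])

    def test_gapped_columns_dropped(self, caplog):
        with caplog.at_level("WARNING"):
            pwm = build_pwm(["A-C", "A-C", "AAC"])
        assert pwm.width == 2


def brute_force_pvalues(pwm, scale=1000):
    """Tail probabilities by enumerating every window of width w over the
    integer-scaled scores."""
    ints = np.round(scale * np.log2(pwm.matrix / pwm.background[None, :])).astype(int)
    bg = pwm.background
    outcomes = {}
    for combo in itertools.product(range(20), repeat=pwm.width):
        s = int(sum(ints[j, a] for j, a in enumerate(combo)))
        p = float(np.prod([bg[a] for a in combo]))
        outcomes[s] = outcomes.get(s, 0.0) + p
    scores = sorted(outcomes, reverse=True)
    tail, acc = {}, 0.0
    for s in scores:
        acc += outcomes[s]
        tail[s] = acc
    return ints, tail


class TestExactPvalues:
    def test_width2_dp_equals_enumeration(self):
        rng = np.random.default_rng(3)
        block = ["".join(rng.choice(list(AA_ALPHABET), size=2)) for _ in range(8)]
        pwm = build_pwm(block, pseudocount=0.4)
        ints, tail = brute_force_pvalues(pwm)
        min_sum, dp_tail = score_distribution(pwm)
        for a1, a2 in itertools.product(range(20), repeat=2):
            s = int(ints[0, a1] + ints[1, a2])
            assert dp_tail[s - min_sum] == pytest.approx(tail[s], rel=1e-9)

    def test_width3_dp_equals_enumeration(self):
        rng = np.random.default_rng(4)
        block = ["".join(rng.choice(list(AA_ALPHABET), size=3)) for _ in range(5)]
        pwm = build_pwm(block, pseudocount=0.7)
        ints, tail = brute_force_pvalues(pwm)
        min_sum, dp_tail = score_distribution(pwm)
        for combo in itertools.islice(itertools.product(range(20), repeat=3), 0, None, 7):
            s = int(sum(ints[j, a] for j, a in enumerate(combo)))
            assert dp_tail[s - min_sum] == pytest.approx(tail[s], rel=1e-9)

    def test_best_window_one_hot_pvalue(self):
        """The argmax window of a near-one-hot width-3 PWM has p = (1/20)^3
        under the uniform background."""
        pwm = build_pwm(["MKW", "MKW"], pseudocount=0.01)
        hits = scan_pwm(pwm, "MKW", p_cutoff=1.0)
        assert len(hits) == 1
        assert hits[0].p_value == pytest.approx((1 / 20) ** 3, rel=1e-9)

    def test_sequence_shorter_than_width(self):
        pwm = build_pwm(["MKWL", "MKWL"], pseudocount=0.1)
        assert scan_pwm(pwm, "MK", p_cutoff=1.0) == []

    def test_pvalue_monotone_in_score(self):
        rng = np.random.default_rng(9)
        block = ["".join(rng.choice(list(AA_ALPHABET), size=6)) for _ in range(10)]
        pwm = build_pwm(block, pseudocount=0.5)
        seq = "".join(rng.choice(list(AA_ALPHABET), size=400))
        hits = scan_pwm(pwm, seq, p_cutoff=1.0)
        hits.sort(key=lambda h: h.log_odds_score)
        for a, b in zip(hits, hits[1:]):
            assert a.p_value >= b.p_value

    def test_monte_carlo_tail_width32(self, region_pwms):
        """DP tail matches Monte-Carlo estimates within 3 SE at width 32."""
        pwm = region_pwms["active_site"]
        assert pwm.width == 32
        rng = np.random.default_rng(12)
        n = 20000
        ints = np.round(
            1000 * np.log2(pwm.matrix / pwm.background[None, :])
        ).astype(int)
        draws = rng.integers(0, 20, size=(n, 32))
        sums = ints[np.arange(32)[None, :], draws].sum(axis=1)
        min_sum, tail = score_distribution(pwm)
        for q in (0.5, 0.9, 0.99):
            thr = int(np.quantile(sums, q))
            p_mc = float(np.mean(sums >= thr))
            p_dp = float(tail[thr - min_sum])
            se = np.sqrt(p_dp * (1 - p_dp) / n)
            assert abs(p_mc - p_dp) <= 3 * se + 1e-12


def _full_domain(rng=None):
    rng = rng or np.random.default_rng(0)
    lk = lambda n: "".join(rng.choice(list(AA_ALPHABET), size=n))
    return (
        REGION_CONSENSUS["PG_box"] + lk(43)
        + REGION_CONSENSUS["active_site"] + lk(12)
        + REGION_CONSENSUS["C_terminal"]
    )


class TestGrade:
    def test_full_domain(self, region_pwms):
        assert grade_dyw(_full_domain(), region_pwms) == "full"

    def test_pg_box_alone_is_truncated(self, region_pwms):
        assert grade_dyw(REGION_CONSENSUS["PG_box"], region_pwms) == "truncated_with_PG"

    def test_random_sequence_absent(self, region_pwms):
        rng = np.random.default_rng(21)
        seq = "".join(rng.choice(list(AA_ALPHABET), size=300))
        assert grade_dyw(seq, region_pwms) == "absent"

    def test_monotone_upgrade(self, region_pwms):
        """Appending the missing regions never downgrades the grade."""
        rng = np.random.default_rng(2)
        lk = lambda n: "".join(rng.choice(list(AA_ALPHABET), size=n))
        truncated = REGION_CONSENSUS["PG_box"]
        assert grade_dyw(truncated, region_pwms) == "truncated_with_PG"
        completed = (
            truncated + lk(43) + REGION_CONSENSUS["active_site"]
            + lk(12) + REGION_CONSENSUS["C_terminal"]
        )
        assert grade_dyw(completed, region_pwms) == "full"

    def test_out_of_order_regions_not_full(self, region_pwms):
        rng = np.random.default_rng(8)
        lk = lambda n: "".join(rng.choice(list(AA_ALPHABET), size=n))
        scrambled = (
            REGION_CONSENSUS["C_terminal"] + lk(12)
            + REGION_CONSENSUS["active_site"] + lk(43)
            + REGION_CONSENSUS["PG_box"]
        )
        assert grade_dyw(scrambled, region_pwms) != "full"

    def test_false_positive_rate_bounded(self, region_pwms):
        """Across 10,000 random windows the empirical hit rate at p <= 1e-5
        stays within the binomial bound."""
        pwm = region_pwms["PG_box"]
        rng = np.random.default_rng(33)
        n_windows = 10_000
        seq = "".join(rng.choice(list(AA_ALPHABET), size=n_windows + pwm.width - 1))
        hits = scan_pwm(pwm, seq, p_cutoff=1e-5)
        expected = n_windows * 1e-5
        assert len(hits) <= expected + 3 * np.sqrt(expected) + 1
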