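import math
from fractions import Fraction

import numpy as np
import pytest

from mirddr.annotate import KnownMiRNA
from mirddr.diffexpr import (
    ac_pmf,
    ac_pvalue,
    apply_floor,
    bh_fdr,
    call_de,
    differential_expression,
    exclusion_rule,
    ExpressionRecord,
    family_table,
    log2fc,
    log_tpm_matrix,
    tpm,
)
from mirddr.preprocess import round_half_up
from mirddr.simdata import simulate_null_tag_counts


def ac_pmf_exact(y: int, x: int, n1: int, n2: int) -> Fraction:
    """Exact rational evaluation of the conditional count distribution."""
    rho = Fraction(n2, n1)
    return (
        rho**y
        * Fraction(math.factorial(x + y), math.factorial(x) * math.factorial(y))
        / (1 + rho) ** (x + y + 1)
    )


def ac_pvalue_exact(x: int, y: int, n1: int, n2: int) -> Fraction:
    c = sum(ac_pmf_exact(t, x, n1, n2) for t in range(0, y + 1))
    below = sum(ac_pmf_exact(t, x, n1, n2) for t in range(0, y))
    d = 1 - below
    return min(Fraction(1), 2 * min(c, d))


class TestNormalization:
    def test_published_tpm_values(self):
        assert round_half_up(tpm(12_312, 12_819_498), 2) == 960.41
        assert round_half_up(tpm(1_066, 12_819_498), 2) == 83.15

    def test_zero_count(self):
        assert tpm(0, 12_819_498) == 0.0

    def test_nonpositive_total_rejected(self):
        with pytest.raises(ValueError):
            tpm(5, 0)

    def test_floor_replaces_exact_zeros_only(self):
        assert apply_floor((0.0, 3.04)) == (0.01, 3.04)
        assert apply_floor((2.5, 2.5)) == (2.5, 2.5)
        assert apply_floor((0.0, 0.0)) == (0.01, 0.01)

    def test_exclusion_needs_both_below_one(self):
        assert exclusion_rule((0.5, 0.8)) is True
        assert exclusion_rule((0.5, 12.0)) is False
        assert exclusion_rule((1.0, 0.2)) is False  # 1.0 is not < 1


class TestLog2FC:
    @pytest.mark.parametrize(
        "tr,ck,expected",
        [
            (1490.18, 12462.71, -3.06),
            (0.01, 0.78, -6.29),
            (41.59, 83.15, -1.00),
            (0.01, 3.04, -8.25),
        ],
    )
    def test_published_fold_changes(self, tr, ck, expected):
        assert round_half_up(log2fc(tr, ck), 2) == expected

    def test_identity(self):
        assert log2fc(7.7, 7.7) == 0.0

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            log2fc(0.0, 1.0)


class TestExactTest:
    def test_pmf_simple_rational_value(self):
        # y=0, x=2, N1=N2: (1/2)^3 = 1/8
        assert ac_pmf(0, 2, 1000, 1000) == pytest.approx(0.125, abs=1e-12)

    @pytest.mark.parametrize("x", [0, 5, 50, 200])
    @pytest.mark.parametrize("ratio", [(1, 5), (1, 1), (5, 1)])
    def test_pmf_normalizes(self, x, ratio):
        from mirddr.diffexpr import ac_log_pmf

        n1, n2 = ratio[0] * 10_000, ratio[1] * 10_000
        rho = n2 / n1
        mean = (x + 1) * rho
        # geometric tail decays at rate log((1+rho)/rho) per term
        cut = int(mean + 12 * math.sqrt(mean * (1 + rho)) + 60 / math.log((1 + rho) / rho))
        ys = np.arange(0, cut + 1)
        total = float(np.exp(ac_log_pmf(ys, x, n1, n2)).sum())
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_pmf_symmetry_at_equal_totals(self):
        for x, y in [(3, 9), (0, 4), (17, 2)]:
            assert ac_pmf(y, x, 5000, 5000) == pytest.approx(
                ac_pmf(x, y, 5000, 5000), rel=1e-12
            )

    def test_pmf_is_negative_binomial(self):
        # independent route: p(y|x) = NB(x+1, N1/(N1+N2)) evaluated at y
        from scipy.stats import nbinom

        for x, y, n1, n2 in [(5, 2, 1000, 4000), (0, 7, 3000, 1000), (40, 40, 500, 500)]:
            assert ac_pmf(y, x, n1, n2) == pytest.approx(
                float(nbinom.pmf(y, x + 1, n1 / (n1 + n2))), rel=1e-10
            )

    def test_pvalue_capped_at_mode(self):
        assert ac_pvalue(5, 5, 10**6, 10**6) == 1.0

    def test_extreme_discordance(self):
        assert ac_pvalue(50, 0, 10**6, 10**6) < 1e-12

    def test_pvalue_matches_exact_rational_tails(self):
        grid = [
            (5, 10, 10**6, 10**6), (0, 3, 10**6, 10**6), (20, 5, 10**6, 10**6),
            (7, 7, 10**5, 10**6), (2, 30, 10**6, 10**5), (0, 0, 10**6, 10**6),
            (1, 0, 500, 700), (12, 40, 3000, 9000), (100, 60, 10**4, 10**4),
            (3, 3, 123, 456), (8, 0, 10**4, 10**4), (0, 8, 10**4, 10**4),
            (25, 75, 10**5, 3 * 10**5), (60, 20, 2 * 10**5, 10**5),
            (4, 4, 10**6, 10**6), (9, 2, 10**3, 10**3), (33, 33, 777, 777),
            (15, 1, 10**5, 10**5), (1, 15, 10**5, 10**5), (50, 55, 10**6, 10**6),
        ]
        for x, y, n1, n2 in grid:
            exact = float(ac_pvalue_exact(x, y, n1, n2))
            assert ac_pvalue(x, y, n1, n2) == pytest.approx(exact, abs=1e-10)

    def test_pvalue_unimodal_in_y(self):
        # p rises with y up to the conditional mode region, then falls:
        # min(lower tail, upper tail) is unimodal because one tail is
        # increasing and the other decreasing in y
        n1, n2 = 10**5, 2 * 10**5
        for x in (5, 20, 80):
            ys = np.arange(0, int(x * n2 / n1 * 3) + 5)
            ps = [ac_pvalue(x, int(y), n1, n2) for y in ys]
            peak = int(np.argmax(ps))
            assert all(ps[i] <= ps[i + 1] + 1e-12 for i in range(peak))
            assert all(ps[i] >= ps[i + 1] - 1e-12 for i in range(peak, len(ps) - 1))

    def test_null_type_one_error_controlled(self):
        x, y, n1, n2 = simulate_null_tag_counts(500, 50_000, seed=11)
        ps = [ac_pvalue(int(a), int(b), n1, n2) for a, b in zip(x, y)]
        assert np.mean(np.array(ps) < 0.05) <= 0.075


class TestBhFdr:
    def test_step_up_hand_example(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_p(self):
        assert bh_fdr([0.37]) == [0.37]

    def test_all_ones(self):
        assert bh_fdr([1.0, 1.0, 1.0]) == [1.0, 1.0, 1.0]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    def test_matches_reference_implementation(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 40))
            ours = bh_fdr(p)
            ref = multipletests(p, method="fdr_bh")[1]
            assert ours == pytest.approx(list(ref), abs=1e-12)


class TestCalling:
    def _rec(self, lfc, q):
        rec = ExpressionRecord("m", 1, 1, 100, 100)
        rec.log2fc, rec.q_value = lfc, q
        return rec

    @pytest.mark.parametrize(
        "lfc,q,status",
        [
            (-3.06, 1e-6, "DOWN"),
            (0.9, 1e-6, "NS"),
            (2.0, 0.05, "NS"),  # q must be strictly below the cutoff
            (1.5, 0.01, "UP"),
            (1.0, 0.01, "NS"),  # log2fc must be strictly above 1
        ],
    )
    def test_threshold_boundaries(self, lfc, q, status):
        assert call_de(self._rec(lfc, q)) == status

    def test_full_analysis_marks_exclusions(self):
        records = differential_expression(
            [("kept", 50, 5), ("excluded", 1, 1)], 10**7, 10**7
        )
        by_id = {r.mirna_id: r for r in records}
        assert by_id["excluded"].status == "EXCLUDED"
        assert by_id["excluded"].p_value is None
        assert by_id["kept"].p_value is not None


class TestFamilyTable:
    TOTALS = (12_819_498, 4_736_578)

    def _family(self, ck, tr, name="osa-miR482a"):
        fam = name.split("-")[1][:6]
        return [KnownMiRNA(name, "miR482", "ACGT" * 5, ck, tr)]

    def test_nd_when_both_below_five(self):
        rows = family_table(self._family(1, 2), *self.TOTALS)
        assert rows[0].log2fc is None

    def test_zero_floor_fold_change(self):
        rows = family_table(self._family(39, 0), *self.TOTALS)
        assert round_half_up(rows[0].log2fc, 2) == -8.25

    def test_five_reads_is_computed(self):
        rows = family_table(self._family(5, 0), *self.TOTALS)
        assert rows[0].log2fc is not None

    def test_members_aggregated(self):
        known = [
            KnownMiRNA("osa-miR166a", "miR166", "A" * 21, 10, 1),
            KnownMiRNA("ath-miR166b", "miR166", "C" * 21, 5, 2),
            KnownMiRNA("osa-miR171a", "miR171", "G" * 21, 7, 7),
        ]
        rows = family_table(known, *self.TOTALS)
        fam = {r.family: r for r in rows}
        assert fam["miR166"].n_members == 2
        assert fam["miR166"].reads_ck == 15 and fam["miR166"].reads_tr == 3


class TestLogTpmMatrix:
    def test_values_and_shape(self):
        rec = ExpressionRecord("m", 1, 1, 1000, 1000)
        rec.tpm_ck, rec.tpm_tr, rec.status = 1000.0, 0.01, "DOWN"
        frame = log_tpm_matrix([rec])
        assert len(frame) == 1
        assert frame.log10_tpm_ck[0] == pytest.approx(3.0)
        assert frame.log10_tpm_tr[0] == pytest.approx(-2.0)

    def test_only_de_records_exported(self):
        recs = []
        for status in ("UP", "NS", "DOWN", "EXCLUDED"):
            r = ExpressionRecord(status, 1, 1, 1000, 1000)
            r.tpm_ck = r.tpm_tr = 1.0
            r.status = status
            recs.append(r)
        assert list(log_tpm_matrix(recs).mirna_id) == ["UP", "DOWN"]
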