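import math

import numpy as np
import pytest
from scipy.stats import chi2_contingency

from faerspv import signal_stats as ss
from faerspv.signal_stats import (
    ConfigurationError,
    ConsistencyError,
    ContingencyTable,
    chi_square,
    contingency,
    evaluate_signal,
    ic,
    ic025,
    prr,
    reconstruct_table,
    ror,
)


def random_tables(n, seed=0, low=1, high=2000):
    rng = np.random.default_rng(seed)
    tables = []
    while len(tables) < n:
        a, b, c, d = rng.integers(low, high, size=4)
        tables.append(ContingencyTable(int(a), int(b), int(c), int(d)))
    return tables


class TestContingency:
    def test_set_arithmetic(self):
        drug = {str(i) for i in range(100)}
        query = {str(i) for i in range(90, 110)}
        table = contingency(drug, query, 1000)
        assert (table.a, table.b, table.c, table.d) == (10, 90, 10, 890)

    def test_zero_overlap(self):
        table = contingency({"1", "2"}, {"3"}, 10)
        assert table.a == 0 and table.b == 2 and table.c == 1

    def test_inconsistent_corpus_size(self):
        with pytest.raises(ConsistencyError):
            contingency({"1", "2"}, {"3"}, 2)

    def test_conservation_on_synthetic_corpus(self, sim_corpus):
        expected = sim_corpus.ledger.expected
        n = expected["after_age"]
        for (drug, query), a in expected["a_counts"].items():
            drug_total = expected["per_drug"][drug]
            flagged = expected["flagged"][query]
            table = ContingencyTable(a, drug_total - a, flagged - a, n - drug_total - flagged + a)
            assert table.n == n


class TestPrr:
    def test_hand_computed(self):
        assert prr(ContingencyTable(10, 90, 10, 890)) == pytest.approx(9.0)

    def test_independence(self):
        assert prr(ContingencyTable(10, 90, 100, 900)) == pytest.approx(1.0)

    def test_undefined_when_no_comparator_events(self):
        assert prr(ContingencyTable(0, 57636, 0, 6000000)) is None
        assert prr(ContingencyTable(5, 5, 0, 100)) is None

    def test_zero_a_with_comparator_events_defined(self):
        assert prr(ContingencyTable(0, 100, 10, 890)) == 0.0


class TestRor:
    def test_hand_computed(self):
        assert ror(ContingencyTable(10, 90, 10, 890)) == pytest.approx(8900 / 900)

    def test_independence(self):
        assert ror(ContingencyTable(10, 90, 100, 900)) == pytest.approx(1.0)

    def test_undefined_cells(self):
        assert ror(ContingencyTable(10, 0, 10, 890)) is None
        assert ror(ContingencyTable(10, 90, 0, 890)) is None

    def test_reconstructed_ribociclib_qt_row(self):
        # printed marginals: a=190 of 6,819 drug reports, corpus 6,599,471,
        # comparator count solved from the printed PRR 8.43
        table = reconstruct_table(190, 6819, 6_599_471, 8.43)
        assert ror(table) == pytest.approx(8.65, abs=0.02)


class TestChiSquare:
    def test_independence_is_zero(self):
        assert chi_square(ContingencyTable(10, 90, 100, 900)) == pytest.approx(0.0)

    @pytest.mark.parametrize("table", random_tables(50, seed=42))
    def test_matches_reference_pearson(self, table):
        ours = chi_square(table)
        reference = chi2_contingency(
            [[table.a, table.b], [table.c, table.d]], correction=False
        ).statistic
        assert ours == pytest.approx(reference, rel=1e-10)

    def test_zero_margin_undefined(self):
        assert chi_square(ContingencyTable(0, 0, 10, 90)) is None
        assert chi_square(ContingencyTable(0, 10, 0, 90)) is None

    def test_computable_at_zero_a(self):
        assert chi_square(ContingencyTable(0, 100, 50, 850)) is not None

    def test_reconstructed_ribociclib_arrhythmia_row(self):
        table = reconstruct_table(11, 6819, 6_599_471, 8.19)
        assert chi_square(table) == pytest.approx(68.83, abs=0.1)


class TestIc:
    def test_log2_oe_independence_zero(self):
        assert ic(ContingencyTable(10, 90, 100, 900), "log2_oe") == pytest.approx(0.0)

    def test_log2_oe_hand_computed(self):
        value = ic(ContingencyTable(10, 90, 10, 890), "log2_oe")
        assert value == pytest.approx(math.log2(5), abs=1e-9)

    def test_log2_oe_undefined_at_zero_a(self):
        assert ic(ContingencyTable(0, 100, 10, 890), "log2_oe") is None

    def test_shrunk_finite_and_negative_at_zero_a(self):
        table = ContingencyTable(0, 100, 50, 850)
        expected = 100 * 50 / 1000
        value = ic(table, "log2_oe_shrunk")
        assert value == pytest.approx(math.log2(0.5 / (expected + 0.5)))
        assert value < 0

    def test_unknown_method_rejected(self):
        with pytest.raises(ConfigurationError):
            ic(ContingencyTable(1, 1, 1, 1), "mgps")
        with pytest.raises(ConfigurationError):
            ic025(ContingencyTable(1, 1, 1, 1), "mgps")


class TestIc025:
    @pytest.mark.parametrize("method", ss.IC_METHODS)
    @pytest.mark.parametrize("table", random_tables(10, seed=1))
    def test_below_point_estimate(self, method, table):
        assert ic025(table, method) < ic(table, method)

    @pytest.mark.parametrize("method", ss.IC_METHODS)
    def test_interval_width_shrinks_with_count(self, method):
        widths = []
        for scale in (1, 10, 100, 1000):
            table = ContingencyTable(5 * scale, 95 * scale, 50 * scale, 850 * scale)
            widths.append(ic(table, method) - ic025(table, method))
        assert widths == sorted(widths, reverse=True)

    @pytest.mark.parametrize(
        "cells",
        [(1, 9, 10, 980), (3, 7, 5, 985), (2, 3, 4, 91), (10, 90, 10, 890), (1, 1, 1, 7)],
    )
    def test_bcpnn_close_to_posterior_draws(self, cells):
        table = ContingencyTable(*cells)
        rng = np.random.default_rng(2024)
        draws = 1_000_000
        p11, px, py = ss._bcpnn_posteriors(table)
        samples = (
            np.log(rng.beta(*p11, draws))
            - np.log(rng.beta(*px, draws))
            - np.log(rng.beta(*py, draws))
        ) / np.log(2.0)
        mc = np.quantile(samples, 0.025)
        assert ic025(table, "bcpnn_bate1998") == pytest.approx(mc, abs=0.05)


class TestEvaluateSignal:
    def test_paper_positive_row(self):
        assert evaluate_signal(190, 8.43, 8.65, 1237.99, 2.86) is True

    def test_fewer_than_three_events(self):
        assert evaluate_signal(2, 10, 10, 50, 1) is False

    def test_paper_negative_row(self):
        # high chi-square alone does not make a signal
        assert evaluate_signal(166, 1.8, 1.82, 60.04, 0.64) is False

    def test_undefined_metric_vetoes(self):
        assert evaluate_signal(10, None, 5, 5, 1) is False
        assert evaluate_signal(10, 5, 5, 5, None) is False


class TestAlgebraicProperties:
    @pytest.mark.parametrize("table", random_tables(200, seed=7))
    def test_prr_ror_ordering(self, table):
        p, r = prr(table), ror(table)
        if p > 1:
            assert r > p
        elif p < 1:
            assert r < p

    def test_equalities_at_independence(self):
        for k in (1, 3, 9):
            table = ContingencyTable(2 * k, 8 * k, 20 * k, 80 * k)
            assert prr(table) == pytest.approx(1.0)
            assert ror(table) == pytest.approx(1.0)
            assert chi_square(table) == pytest.approx(0.0, abs=1e-9)
            assert ic(table, "log2_oe") == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("table", random_tables(50, seed=9))
    def test_row_swap_inverts_ratios(self, table):
        swapped = ContingencyTable(table.c, table.d, table.a, table.b)
        assert prr(swapped) == pytest.approx(1 / prr(table))
        assert ror(swapped) == pytest.approx(1 / ror(table))
        assert chi_square(swapped) == pytest.approx(chi_square(table), rel=1e-10)


class TestParameterRecovery:
    def test_planted_rate_ratio_recovered(self):
        # large planted corpus: estimated PRR within 3 sampling standard
        # errors (log scale) of the planted rho, expected cell count >= 50
        from faerspv import cleaning, cohort, meddra_map
        from faerspv import synthetic_data as sd
        from conftest import assemble

        rho = 8.0
        config = sd.SimConfig(
            n_reports=8000,
            seed=5,
            drugs={"palbociclib": 0.25, "ribociclib": 0.2, "abemaciclib": 0.1},
            planted_rr={("ribociclib", "Toy cardiac failure"): rho},
        )
        corpus = sd.generate_corpus(config)
        cases = assemble(corpus)
        cleaned, _ = cleaning.clean_cases(cases, set(corpus.deleted_caseids))
        subsets = cohort.select_primary_suspect(cleaned, cohort.load_drug_dictionary())
        query = meddra_map.load_bundled_queries()["Toy cardiac failure"]
        flagged = {c.caseid for c in meddra_map.flag_reports(cleaned, query)}
        table = contingency({c.caseid for c in subsets["ribociclib"]}, flagged, len(cleaned))
        assert table.a >= 50
        estimate = prr(table)
        se_log = math.sqrt(
            1 / table.a - 1 / (table.a + table.b) + 1 / table.c - 1 / (table.c + table.d)
        )
        assert abs(math.log(estimate) - math.log(rho)) <= 3 * se_log
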