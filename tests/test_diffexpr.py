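"""TPM, Audic–Claverie exact test, BH FDR, DEG calling and set logic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cottondge import diffexpr as de
from cottondge import simulate as sim
from conftest import library_from_counts, multinomial_library
from oracles import ac_test_oracle, bh_oracle


class TestComputeTpm:
    def test_arithmetic(self):
        assert de.compute_tpm({"g": 30}, 3_000_000)["g"] == pytest.approx(10.0)

    def test_zero_count(self):
        assert de.compute_tpm({"g": 0}, 100)["g"] == 0.0

    def test_zero_total_raises(self):
        with pytest.raises(ValueError):
            de.compute_tpm({"g": 1}, 0)

    def test_library_sums_to_one_million(self):
        rng = np.random.default_rng(0)
        counts = {f"g{i}": int(c) for i, c in enumerate(rng.integers(0, 500, 200))}
        total = sum(counts.values())
        tpm = de.compute_tpm(counts, total)
        assert sum(tpm.values()) == pytest.approx(1e6, abs=1e-6)


class TestAcTest:
    def test_zero_counts_p_one(self):
        assert de.ac_test(0, 0, 1000, 1000) == 1.0

    def test_equal_counts_not_significant(self):
        p = de.ac_test(5, 5, 1000, 1000)
        assert p > 0.5
        assert p == pytest.approx(ac_test_oracle(5, 5, 1000, 1000), abs=1e-10)

    def test_matches_direct_summation_on_spot_checks(self):
        for x, y, n1, n2 in [
            (0, 10, 1000, 1000),
            (10, 0, 1000, 2000),
            (3, 40, 500, 1000),
            (25, 25, 2000, 1000),
            (50, 50, 1000, 500),
        ]:
            assert de.ac_test(x, y, n1, n2) == pytest.approx(
                ac_test_oracle(x, y, n1, n2), abs=1e-10
            )

    def test_self_symmetric_case(self):
        # x=y with N1=N2 maps to itself under the swap
        for x in (0, 3, 17):
            assert de.ac_test(x, x, 5000, 5000) == de.ac_test(x, x, 5000, 5000)

    def test_swap_orientations_agree_in_magnitude(self):
        """The doubled smaller-tail p is orientation-dependent, but the two
        orientations always agree to well within an order of magnitude."""
        rng = np.random.default_rng(1)
        for _ in range(100):
            x, y = int(rng.integers(0, 60)), int(rng.integers(0, 60))
            n1, n2 = rng.integers(1000, 100000, 2)
            a = de.ac_test(x, y, int(n1), int(n2))
            b = de.ac_test(y, x, int(n2), int(n1))
            # asymmetry grows with tail depth; bounded on the log scale
            log_ratio = abs(np.log10(a) - np.log10(b))
            assert log_ratio <= 1.0 + 0.1 * abs(np.log10(min(a, b)))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            de.ac_test(-1, 0, 100, 100)


class TestBhFdr:
    def test_hand_computed_step_up(self):
        q = de.bh_fdr([0.001, 0.01, 0.02, 0.03])
        assert q == pytest.approx([0.004, 0.02, 0.02666667, 0.03], abs=1e-6)

    def test_all_equal_unchanged(self):
        assert de.bh_fdr([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_matches_independent_implementation(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(1e-8, 1.0, size=int(rng.integers(1, 60)))
        q = de.bh_fdr(p)
        assert q == pytest.approx(bh_oracle(list(p)), abs=1e-12)
        # monotone w.r.t. p
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_cross_checked_against_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(7)
        for _ in range(20):
            p = rng.uniform(1e-6, 1, size=50)
            q = de.bh_fdr(p)
            q_ref = multipletests(p, method="fdr_bh")[1]
            assert q == pytest.approx(q_ref, abs=1e-12)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            de.bh_fdr([0.0, 0.5])
        with pytest.raises(ValueError):
            de.bh_fdr([0.5, 1.5])


class TestCallDegs:
    def test_double_threshold(self):
        # strong signal: TPM 10 vs 40 at large depth -> q small, lfc = 2
        parent = library_from_counts("P", {"g": 1000, "bg": 99000})
        line = library_from_counts("L", {"g": 4000, "bg": 96000})
        table = de.call_degs(parent, line)
        assert table.loc["g", "call"] == "up"
        assert table.loc["g", "log2_ratio"] == pytest.approx(2.0, abs=0.01)

    def test_significant_but_small_fold_change_is_ns(self):
        parent = library_from_counts("P", {"g": 10000, "bg": 990000})
        line = library_from_counts("L", {"g": 13000, "bg": 987000})
        table = de.call_degs(parent, line)
        assert table.loc["g", "q"] < 1e-3  # highly significant count shift
        assert abs(table.loc["g", "log2_ratio"]) < 1
        assert table.loc["g", "call"] == "ns"

    def test_zero_zero_genes_excluded(self):
        parent = library_from_counts("P", {"a": 5, "b": 0, "c": 10})
        line = library_from_counts("L", {"a": 5, "b": 0, "c": 12})
        table = de.call_degs(parent, line, genes=["a", "b", "c"])
        assert "b" not in table.index
        assert len(table) == 2

    def test_null_simulation_low_false_call_rate(self):
        """Identical-abundance libraries: DE-call fraction stays at or below
        the nominal level (single replicate; the acceptance suite runs 20)."""
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(2000)]
        abund = rng.lognormal(0, 1.5, size=2000)
        p_lib = multinomial_library("P", abund, genes, 1_000_000, rng)
        l_lib = multinomial_library("L", abund, genes, 1_000_000, rng)
        table = de.call_degs(p_lib, l_lib)
        frac = (table["call"] != "ns").mean()
        assert frac <= 0.002


class TestRunAllComparisons:
    def test_twenty_comparisons(self, design):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(300)]
        abund = rng.lognormal(0, 1, 300)
        libraries = {
            lib_id: multinomial_library(lib_id, abund, genes, 50_000, rng)
            for lib_id in design.library_ids
        }
        results = de.run_all_comparisons(design, libraries)
        assert len(results) == 20
        assert set(results) == set(design.comparisons)

    def test_single_line_single_stage(self, two_line_design):
        rng = np.random.default_rng(5)
        genes = ["a", "b"]
        libraries = {
            lib_id: multinomial_library(lib_id, np.array([1.0, 2.0]), genes, 1000, rng)
            for lib_id in two_line_design.library_ids
        }
        assert len(de.run_all_comparisons(two_line_design, libraries)) == 1

    def test_missing_parent_library_raises(self, two_line_design):
        rng = np.random.default_rng(5)
        lib = multinomial_library("x", np.array([1.0]), ["a"], 100, rng)
        with pytest.raises(ValueError, match="parent library missing"):
            de.run_all_comparisons(two_line_design, {"CSIL-A_05DPA": lib})


def _call_table(up=(), down=(), ns=()):
    rows = (
        [(g, "up") for g in up] + [(g, "down") for g in down] + [(g, "ns") for g in ns]
    )
    return pd.DataFrame(
        {"gene_id": [g for g, _ in rows], "call": [c for _, c in rows]}
    ).set_index("gene_id")


class TestCommonDegs:
    def test_intersection(self):
        tables = {
            "A": _call_table(up=["a", "b", "c"]),
            "B": _call_table(up=["b", "c", "d"]),
        }
        assert de.common_degs(tables, "intersection") == {"b", "c"}

    def test_down_only_in_line(self):
        tables = {
            "A": _call_table(up=["g"]),
            "B": _call_table(up=["g"]),
            "C": _call_table(up=["g"]),
            "D": _call_table(down=["g"]),
        }
        assert de.common_degs(tables, "down_only_in", line="D") == {"g"}
        assert de.common_degs(tables, "down_only_in", line="D", strict=True) == {"g"}

    def test_down_in_two_lines_not_selected(self):
        tables = {
            "A": _call_table(down=["g"]),
            "D": _call_table(down=["g"]),
        }
        assert de.common_degs(tables, "down_only_in", line="D") == set()

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(9)
        genes = [f"g{i}" for i in range(100)]
        lines = ["A", "B", "C", "D"]
        calls = {
            ln: {g: rng.choice(["up", "down", "ns"], p=[0.3, 0.3, 0.4]) for g in genes}
            for ln in lines
        }
        tables = {
            ln: pd.DataFrame(
                {"gene_id": genes, "call": [calls[ln][g] for g in genes]}
            ).set_index("gene_id")
            for ln in lines
        }
        expected_common = {
            g for g in genes if all(calls[ln][g] != "ns" for ln in lines)
        }
        assert de.common_degs(tables, "intersection") == expected_common
        expected_up = {g for g in genes if all(calls[ln][g] == "up" for ln in lines)}
        assert de.common_degs(tables, "up_in_all") == expected_up
        expected_down_only = {
            g
            for g in genes
            if calls["D"][g] == "down"
            and all(calls[ln][g] != "down" for ln in lines if ln != "D")
        }
        assert de.common_degs(tables, "down_only_in", line="D") == expected_down_only

    def test_unknown_mode_or_line(self):
        tables = {"A": _call_table(up=["g"]), "B": _call_table()}
        with pytest.raises(ValueError):
            de.common_degs(tables, "bogus")
        with pytest.raises(ValueError):
            de.common_degs(tables, "down_only_in", line="Z")


class TestValidationCorrelation:
    def test_proportional_vectors(self):
        v = [1.0, 4.0, 9.0, 16.0]
        # exactly 1 on the raw scale (Pearson is scale-invariant) ...
        r2_raw = de.validation_correlation(v, [2 * x for x in v], log_transform=False)
        assert r2_raw == pytest.approx(1.0, abs=1e-12)
        # ... and essentially 1 after the log2(v+1) transform
        assert de.validation_correlation(v, [2 * x for x in v]) > 0.99

    def test_negated_vector_raw_scale(self):
        v = [1.0, 2.0, 3.0, 4.0]
        r2 = de.validation_correlation(v, [-x for x in v], log_transform=False)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_noisy_proportional_r2_matches_expectation(self):
        """For y = x + noise on the log scale, E[r^2] ~ var(x)/(var(x)+sigma^2)."""
        rng = np.random.default_rng(4)
        sigma = 0.5
        x = rng.normal(0, 2.0, size=5000)
        y = x + rng.normal(0, sigma, size=5000)
        r2 = de.validation_correlation(2.0**x, 2.0**y)
        # log2(2^x + 1) != x for small x, so allow a loose Monte-Carlo band
        expected = 4.0 / (4.0 + sigma**2)
        assert r2 == pytest.approx(expected, abs=0.08)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="zero variance"):
            de.validation_correlation([1, 1, 1], [1, 2, 3])
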