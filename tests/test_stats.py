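"""Kernel-level tests: every statistical primitive against an independent
brute-force oracle plus its documented edge cases."""

import math
import subprocess
import sys
import textwrap
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from methlink.stats import (
    bh_fdr,
    correlate,
    fisher_exact_2x2,
    moderated_two_group_test,
    wilcoxon_rank_sum,
)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def wilcoxon_enumeration_p(x, y):
    """Two-sided exact rank-sum p by full enumeration of rank assignments."""
    combined = np.concatenate([x, y])
    order = np.argsort(combined)
    ranks = np.empty_like(order, dtype=float)
    ranks[order] = np.arange(1, len(combined) + 1)
    n1 = len(x)
    w_obs = ranks[:n1].sum()
    n = len(combined)
    all_w = [sum(c) for c in combinations(range(1, n + 1), n1)]
    total = len(all_w)
    p_le = sum(w <= w_obs for w in all_w) / total
    p_ge = sum(w >= w_obs for w in all_w) / total
    return min(1.0, 2.0 * min(p_le, p_ge))


def bh_direct(p):
    """Direct step-up definition: q_i = min over ranks k >= rank(i) of p_(k)*m/k."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    prev = np.inf
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * m / rank_from_top)
        q[i] = min(val, 1.0)
        prev = val
    return q


def fisher_oracle_p(a, b, c, d):
    """Hypergeometric minimum-likelihood two-sided p by enumeration."""
    n = a + b + c + d
    r1 = a + b
    c1 = a + c
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    probs = {k: hypergeom.pmf(k, n, c1, r1) for k in range(lo, hi + 1)}
    p_obs = probs[a]
    return min(1.0, sum(p for p in probs.values() if p <= p_obs * (1 + 1e-7)))


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------


class TestWilcoxon:
    def test_two_vs_two_exact(self):
        res = wilcoxon_rank_sum([1, 2], [3, 4])
        assert res.method == "exact"
        assert res.p_value == pytest.approx(1 / 3)

    def test_all_identical_gives_p_one(self):
        res = wilcoxon_rank_sum([5, 5, 5], [5, 5, 5])
        assert res.p_value == 1.0

    def test_complete_separation_ten_vs_four(self):
        res = wilcoxon_rank_sum(list(range(10, 20)), [1, 2, 3, 4])
        assert res.method == "exact"
        assert res.p_value == pytest.approx(2 / 1001)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1, 2])

    def test_ties_fall_back_to_approximation(self):
        res = wilcoxon_rank_sum([1, 1, 2], [2, 3, 4])
        assert res.method == "approx"

    def test_exact_matches_enumeration_oracle(self, rng):
        """Exact p equals full rank-assignment enumeration on >= 100 random
        tie-free datasets with combined n <= 12."""
        checked = 0
        while checked < 120:
            n1 = int(rng.integers(1, 9))
            n2 = int(rng.integers(1, 13 - n1)) if n1 < 12 else 1
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)
            res = wilcoxon_rank_sum(x, y)
            assert res.method == "exact"
            assert res.p_value == pytest.approx(wilcoxon_enumeration_p(x, y), abs=1e-12)
            checked += 1


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------


class TestBH:
    def test_small_example(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_p_identity(self):
        assert bh_fdr([0.5]) == pytest.approx([0.5])

    def test_matches_direct_definition_on_uniforms(self, rng):
        p = rng.uniform(size=1000)
        assert bh_fdr(p) == pytest.approx(bh_direct(p), abs=1e-12)

    def test_q_at_least_p_and_order_invariant(self, rng):
        p = rng.uniform(size=200)
        q = bh_fdr(p)
        assert np.all(q >= p)
        perm = rng.permutation(200)
        assert bh_fdr(p[perm]) == pytest.approx(q[perm])

    def test_missing_p_propagates(self):
        q = bh_fdr([0.01, np.nan, 0.04])
        assert np.isnan(q[1]) and not np.isnan(q[0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, 1.5])


# ---------------------------------------------------------------------------
# Fisher exact
# ---------------------------------------------------------------------------


class TestFisher:
    def test_diagonal_table(self):
        res, odds = fisher_exact_2x2(2, 0, 0, 2)
        assert res.p_value == pytest.approx(1 / 3)
        assert odds == math.inf

    def test_zero_margin_p_one(self):
        res, _ = fisher_exact_2x2(0, 0, 3, 5)
        assert res.p_value == 1.0

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(-1, 2, 3, 4)

    def test_symmetry_under_row_and_column_swap(self):
        p1 = fisher_exact_2x2(5, 2, 1, 9)[0].p_value
        p2 = fisher_exact_2x2(9, 1, 2, 5)[0].p_value
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_matches_hypergeometric_oracle_random_tables(self, rng):
        for _ in range(400):
            a, b, c, d = (int(v) for v in rng.integers(0, 11, size=4))
            if a + b + c + d == 0:
                continue
            p = fisher_exact_2x2(a, b, c, d)[0].p_value
            assert p == pytest.approx(fisher_oracle_p(a, b, c, d), rel=1e-7, abs=1e-12)


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------


class TestCorrelate:
    def test_perfect_antitone_spearman(self):
        _, rho = correlate([1, 2, 3], [3, 2, 1], "spearman")
        assert rho == pytest.approx(-1.0)

    def test_tied_monotone_spearman(self):
        _, rho = correlate([1, 2, 2, 4], [10, 20, 20, 40], "spearman")
        assert rho == pytest.approx(1.0)

    def test_identity_pearson(self):
        x = [1.0, 2.5, 3.1, 0.4]
        res, r = correlate(x, x, "pearson")
        assert r == pytest.approx(1.0)
        assert res.p_value < 1e-12

    def test_constant_input_undefined(self):
        res, r = correlate([1, 1, 1, 1], [1, 2, 3, 4], "spearman")
        assert math.isnan(r) and math.isnan(res.p_value)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            correlate([1, 2], [3, 4])

    def test_spearman_invariant_to_monotone_transform(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        _, rho1 = correlate(x, y, "spearman")
        _, rho2 = correlate(np.exp(3 * x), y, "spearman")
        assert rho1 == pytest.approx(rho2)


# ---------------------------------------------------------------------------
# moderated two-group test
# ---------------------------------------------------------------------------


def _ordinary_t(expr, n1, n2):
    xc = expr.iloc[:, :n1].to_numpy()
    xk = expr.iloc[:, n1:].to_numpy()
    m1, m2 = xc.mean(axis=1), xk.mean(axis=1)
    df = n1 + n2 - 2
    ss = ((xc - m1[:, None]) ** 2).sum(axis=1) + ((xk - m2[:, None]) ** 2).sum(axis=1)
    s2 = ss / df
    return (m1 - m2) / np.sqrt(s2 * (1 / n1 + 1 / n2))


def _simulated_expr(rng, n_genes=200, n1=5, n2=5, d0=4.0, s0=0.05):
    variances = s0 * d0 / rng.chisquare(d0, size=n_genes)
    data = rng.normal(0, np.sqrt(variances)[:, None], size=(n_genes, n1 + n2))
    return pd.DataFrame(
        data,
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"a{i}" for i in range(n1)] + [f"b{i}" for i in range(n2)],
    )


class TestModeratedTest:
    def test_zero_prior_df_recovers_ordinary_t(self, rng):
        expr = _simulated_expr(rng)
        groups = ["case"] * 5 + ["ctrl"] * 5
        table, fit = moderated_two_group_test(expr, groups, prior_df=0.0)
        assert fit.d0 == 0.0
        assert np.max(np.abs(table["t"].to_numpy() - _ordinary_t(expr, 5, 5))) < 1e-12

    def test_infinite_prior_df_uses_common_variance(self, rng):
        expr = _simulated_expr(rng)
        groups = ["case"] * 5 + ["ctrl"] * 5
        table, fit = moderated_two_group_test(expr, groups, prior_df=math.inf)
        assert np.allclose(fit.posterior_var, fit.s0_sq)

    def test_posterior_var_between_prior_and_sample(self, rng):
        expr = _simulated_expr(rng)
        groups = ["case"] * 5 + ["ctrl"] * 5
        table, fit = moderated_two_group_test(expr, groups)
        xc = expr.iloc[:, :5].to_numpy()
        xk = expr.iloc[:, 5:].to_numpy()
        s2 = (
            ((xc - xc.mean(1)[:, None]) ** 2).sum(1)
            + ((xk - xk.mean(1)[:, None]) ** 2).sum(1)
        ) / 8
        lo = np.minimum(s2, fit.s0_sq) - 1e-12
        hi = np.maximum(s2, fit.s0_sq) + 1e-12
        assert np.all((fit.posterior_var >= lo) & (fit.posterior_var <= hi))

    def test_prior_recovery_from_simulation(self):
        """Estimated (d0, s0^2) recover the generating values from 5,000
        genes with scaled-inverse-chi-square variances (d0=4, s0^2=0.05)."""
        rng = np.random.default_rng(11)
        expr = _simulated_expr(rng, n_genes=5000, n1=7, n2=7, d0=4.0, s0=0.05)
        groups = ["case"] * 7 + ["ctrl"] * 7
        _, fit = moderated_two_group_test(expr, groups)
        assert fit.d0 == pytest.approx(4.0, rel=0.20)
        assert fit.s0_sq == pytest.approx(0.05, rel=0.10)

    def test_small_group_rejected(self, rng):
        expr = _simulated_expr(rng, n1=1, n2=5)
        with pytest.raises(ValueError):
            moderated_two_group_test(expr, ["a"] + ["b"] * 5)

    def test_matches_limma_reference(self, rng, tmp_path):
        """Moderated t and p agree with the Bioconductor limma reference on
        a small two-group fixture."""
        expr = _simulated_expr(rng, n_genes=60, n1=4, n2=4)
        groups = ["case"] * 4 + ["ctrl"] * 4
        table, fit = moderated_two_group_test(expr, groups)
        expr_path = tmp_path / "expr.tsv"
        expr.to_csv(expr_path, sep="\t")
        rscript = textwrap.dedent(
            """
            suppressMessages(library(limma))
            x <- as.matrix(read.delim("%s", row.names = 1))
            design <- cbind(Intercept = 1, case = c(rep(1, 4), rep(0, 4)))
            fit <- eBayes(lmFit(x, design))
            out <- data.frame(t = fit$t[, "case"], p = fit$p.value[, "case"],
                              d0 = fit$df.prior, s0 = fit$s2.prior)
            write.table(out, "%s", sep = "\\t", quote = FALSE)
            """
            % (expr_path, tmp_path / "limma.tsv")
        )
        (tmp_path / "run.R").write_text(rscript)
        subprocess.run(
            ["Rscript", str(tmp_path / "run.R")], check=True, capture_output=True
        )
        ref = pd.read_csv(tmp_path / "limma.tsv", sep="\t", index_col=0)
        assert fit.d0 == pytest.approx(float(ref["d0"].iloc[0]), rel=1e-4)
        assert fit.s0_sq == pytest.approx(float(ref["s0"].iloc[0]), rel=1e-4)
        assert table["t"].to_numpy() == pytest.approx(ref["t"].to_numpy(), rel=1e-6)
        assert table["p"].to_numpy() == pytest.approx(ref["p"].to_numpy(), rel=1e-6)
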