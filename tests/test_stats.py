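"""Selection statistics: regression, slope-homogeneity ANCOVA, the 2x2
dropout chi-square, and screen-report assembly."""

import math

import numpy as np
import pytest

from limbscreen import (
    AlleleKey,
    GeneSimSpec,
    NormalizedAllele,
    PairedAllele,
    SimulationConfig,
    allele_loss_chisq,
    build_screen_report,
    compare_slopes_ancova,
    fit_regression,
)
from limbscreen.pipeline import simulate_count_screen
from limbscreen.stats import (
    DegeneratePredictorError,
    InsufficientAllelesError,
    NoValidControlsError,
)


def make_pairs(xs, ys, gene="g", animal="a"):
    """Paired alleles with prescribed primary/secondary log scores."""
    pairs = []
    for i, (x, y) in enumerate(zip(xs, ys)):
        key = AlleleKey(gene, f"D:{i}:1")
        prim = NormalizedAllele("p", gene, key, unique_reads=1,
                                rp10k=2.0 ** x - 1.0, log_score=float(x),
                                frequency=0.001)
        sec = NormalizedAllele("s", gene, key,
                               unique_reads=0 if y == 0 else 1,
                               rp10k=2.0 ** y - 1.0, log_score=float(y),
                               frequency=0.001)
        pairs.append(PairedAllele(animal=animal, gene=gene, allele=key,
                                  primary=prim, secondary=sec))
    return pairs


def ols_oracle(x, y):
    """Normal-equations fit, independent of the implementation route."""
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    return beta[1], beta[0], float(resid @ resid)


def ancova_oracle(xa, ya, xb, yb):
    """Nested-RSS homogeneity-of-slopes F computed from group-wise fits."""
    _, _, rss_a = ols_oracle(xa, ya)
    _, _, rss_b = ols_oracle(xb, yb)
    rss_full = rss_a + rss_b  # separate slopes = separate fits
    x = np.concatenate([xa, xb])
    y = np.concatenate([ya, yb])
    g = np.concatenate([np.zeros(len(xa)), np.ones(len(xb))])
    X = np.column_stack([np.ones_like(x), x, g])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    rss_reduced = float(resid @ resid)
    n = len(x)
    f = (rss_reduced - rss_full) / (rss_full / (n - 4))
    return f, n - 4


class TestFitRegression:
    def test_perfect_fidelity_line(self):
        pairs = make_pairs([0, 1, 2, 3], [0, 1, 2, 3])
        fit = fit_regression(pairs)
        assert fit.slope == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_exact_line_through_origin(self):
        fit = fit_regression(make_pairs([0, 1, 2], [0, 2, 4]))
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(0.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self, rng):
        x = rng.uniform(0, 10, size=20)
        y = 0.7 * x + rng.normal(0, 1, size=20)
        fit = fit_regression(make_pairs(x, y))
        slope, intercept, _ = ols_oracle(x, y)
        assert fit.slope == pytest.approx(slope, abs=1e-10)
        assert fit.intercept == pytest.approx(intercept, abs=1e-10)

    def test_residuals_orthogonal_to_predictor(self, rng):
        x = rng.uniform(0, 8, size=40)
        y = 0.5 * x + rng.normal(0, 0.5, size=40)
        fit = fit_regression(make_pairs(x, y))
        resid = y - fit.intercept - fit.slope * x
        assert abs(resid @ x) < 1e-8

    def test_preconditions(self):
        with pytest.raises(InsufficientAllelesError):
            fit_regression(make_pairs([1, 2], [1, 2]))
        with pytest.raises(DegeneratePredictorError):
            fit_regression(make_pairs([2, 2, 2], [1, 2, 3]))


class TestAncova:
    def test_identical_groups_give_f_zero_p_one(self):
        pairs = make_pairs([0, 1, 2, 3, 4], [0.1, 1.2, 1.9, 3.3, 3.8])
        res = compare_slopes_ancova(pairs, pairs)
        assert res.f_interaction == 0.0
        assert res.p_value == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_nested_rss_oracle(self, seed):
        rng = np.random.default_rng(seed)
        xa = rng.uniform(0, 10, 50)
        ya = 1.0 * xa + rng.normal(0, 0.3, 50)
        xb = rng.uniform(0, 10, 50)
        yb = 0.2 * xb + rng.normal(0, 0.3, 50)
        res = compare_slopes_ancova(make_pairs(xa, ya), make_pairs(xb, yb))
        f, df2 = ancova_oracle(xa, ya, xb, yb)
        assert res.f_interaction == pytest.approx(f, abs=1e-8)
        assert res.df == (1, df2)

    def test_equals_squared_t_of_slope_difference(self, rng):
        """The interaction F equals the squared t of the pooled-variance
        slope-difference test."""
        xa = rng.uniform(0, 10, 30)
        ya = 0.9 * xa + rng.normal(0, 0.4, 30)
        xb = rng.uniform(0, 10, 40)
        yb = 0.5 * xb + rng.normal(0, 0.4, 40)
        res = compare_slopes_ancova(make_pairs(xa, ya), make_pairs(xb, yb))
        sa, _, rss_a = ols_oracle(xa, ya)
        sb, _, rss_b = ols_oracle(xb, yb)
        s2 = (rss_a + rss_b) / (len(xa) + len(xb) - 4)
        sxx_a = ((xa - xa.mean()) ** 2).sum()
        sxx_b = ((xb - xb.mean()) ** 2).sum()
        t = (sa - sb) / math.sqrt(s2 * (1 / sxx_a + 1 / sxx_b))
        assert res.f_interaction == pytest.approx(t ** 2, abs=1e-8)

    def test_swapping_groups_preserves_f_and_p(self, rng):
        xa = rng.uniform(0, 10, 25)
        ya = 0.8 * xa + rng.normal(0, 0.5, 25)
        xb = rng.uniform(0, 10, 35)
        yb = 0.3 * xb + rng.normal(0, 0.5, 35)
        a, b = make_pairs(xa, ya), make_pairs(xb, yb)
        r1 = compare_slopes_ancova(a, b)
        r2 = compare_slopes_ancova(b, a)
        assert r1.f_interaction == pytest.approx(r2.f_interaction, abs=1e-10)
        assert r1.p_value == pytest.approx(r2.p_value, abs=1e-12)


def chisq_closed_form(a, b, c, d):
    """N(ad - bc)^2 / [(a+b)(c+d)(a+c)(b+d)] for the 2x2 table."""
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))


class TestAlleleLossChisq:
    @pytest.mark.parametrize("table,expected", [
        ((22, 48, 22, 92), 7.03),   # fetub vs controls
        ((6, 8, 22, 92), 9.53),     # catalase vs controls
        ((6, 8, 56, 168), 5.81),    # catalase vs all other targets
        ((22, 48, 40, 128), 3.25),  # fetub vs all other targets
    ])
    def test_published_statistics_reproduced(self, table, expected):
        res = allele_loss_chisq(*table)
        assert round(res.statistic, 2) == expected

    def test_equal_proportions_give_zero(self):
        assert allele_loss_chisq(5, 10, 10, 20).statistic == pytest.approx(0.0)

    def test_zero_margin_degenerate(self):
        res = allele_loss_chisq(0, 10, 0, 20)
        assert res.degenerate and res.statistic == 0.0 and res.p_value == 1.0

    def test_matches_closed_form_on_random_tables(self, rng):
        for _ in range(200):
            a, b, c, d = rng.integers(0, 25, size=4)
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            res = allele_loss_chisq(a, a + b, c, c + d)
            assert res.statistic == pytest.approx(
                chisq_closed_form(a, b, c, d), abs=1e-10)

    def test_matches_scipy_contingency_without_correction(self, rng):
        from scipy.stats import chi2_contingency

        for _ in range(50):
            a, b, c, d = rng.integers(1, 40, size=4)
            res = allele_loss_chisq(a, a + b, c, c + d)
            ref = chi2_contingency([[a, b], [c, d]], correction=False)
            assert res.statistic == pytest.approx(float(ref.statistic), abs=1e-10)
            assert res.p_value == pytest.approx(float(ref.pvalue), abs=1e-12)

    def test_swapping_rows_or_columns_preserves_statistic(self):
        base = allele_loss_chisq(22, 48, 22, 92).statistic
        assert allele_loss_chisq(22, 92, 22, 48).statistic == pytest.approx(base)
        assert allele_loss_chisq(26, 48, 70, 92).statistic == pytest.approx(base)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            allele_loss_chisq(5, 0, 1, 10)
        with pytest.raises(ValueError):
            allele_loss_chisq(11, 10, 1, 10)


def screen_config(s_map, **kw):
    genes = tuple(GeneSimSpec(name, s) for name, s in s_map.items())
    defaults = dict(genes=genes, control_genes=("ctrlA", "ctrlB"), n_animals=10)
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestBuildScreenReport:
    def test_insufficient_alleles_verdict(self):
        xs = [1.0, 2.0, 3.0, 4.0]
        pairs_by_gene = {
            "ctrlA": make_pairs(xs, xs, "ctrlA"),
            "ctrlB": make_pairs(xs, [1.1, 1.9, 3.2, 3.9], "ctrlB"),
            "tiny": make_pairs([1.0, 2.0], [1.0, 2.0], "tiny"),
        }
        report = build_screen_report(pairs_by_gene, ("ctrlA", "ctrlB"))
        assert report.genes["tiny"].verdict == "insufficient alleles"
        assert report.genes["tiny"].regression is None

    def test_missing_controls_abort(self):
        with pytest.raises(NoValidControlsError):
            build_screen_report({"ctrlA": make_pairs([1, 2, 3], [1, 2, 3], "ctrlA")},
                                ("ctrlA", "ctrlB"))

    def test_strong_selection_flagged_neutrals_not(self, rng):
        config = screen_config({"ctrlA": 0.0, "ctrlB": 0.0,
                                "hit": 0.8, "neutral": 0.0})
        pairs = simulate_count_screen(config, rng)
        report = build_screen_report(pairs, ("ctrlA", "ctrlB"))
        assert report.genes["hit"].verdict == "flagged"
        assert report.genes["hit"].regression.slope < report.control_regression.slope

    def test_control_like_genes_not_distinguishable(self, rng):
        """Two neutral control genes compared to each other show no slope
        difference (the screen's internal-consistency check)."""
        config = screen_config({"ctrlA": 0.0, "ctrlB": 0.0})
        pairs = simulate_count_screen(config, rng)
        res = compare_slopes_ancova(pairs["ctrlA"], pairs["ctrlB"])
        assert res.p_value > 0.05

    def test_slope_and_loss_monotone_in_selection_strength(self):
        """Across s in {0, 0.25, 0.5, 0.75, 1}, the mean fitted slope is
        non-increasing and the mean lost fraction non-decreasing.

        Averaged over replicates because the slope's response to weak
        selection is much smaller than single-screen sampling noise (weak
        selection mostly shifts the intercept; the slope reacts through
        allele dropout); the tolerance covers residual Monte-Carlo error.
        """
        rng = np.random.default_rng(7)
        s_values = [0.0, 0.25, 0.5, 0.75, 1.0]
        slopes = {s: [] for s in s_values}
        losses = {s: [] for s in s_values}
        for _rep in range(12):
            config = screen_config(
                {"ctrlA": 0.0, "ctrlB": 0.0,
                 **{f"g{s}": s for s in s_values}}, n_animals=25)
            pairs = simulate_count_screen(config, rng)
            for s in s_values:
                gene_pairs = pairs[f"g{s}"]
                losses[s].append(np.mean([p.lost for p in gene_pairs]))
                slopes[s].append(fit_regression(gene_pairs).slope)
        mean_slopes = [np.mean(slopes[s]) for s in s_values]
        mean_losses = [np.mean(losses[s]) for s in s_values]
        tol = 0.02  # Monte-Carlo allowance, ~2 SE of an adjacent difference
        assert all(a >= b - tol for a, b in zip(mean_slopes, mean_slopes[1:]))
        assert all(a <= b + tol for a, b in zip(mean_losses, mean_losses[1:]))
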