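"""Per-gene negative-selection statistics and the screen report.

Negative selection leaves two signatures in a paired-limb dataset: the
regression of regenerate log scores on primary log scores flattens (mutant
lineages contribute less than their primary-limb share predicts), and the
fraction of primary-limb alleles absent from the regenerate rises. The
screen tests both, per gene, against the pooled inessential controls and
against the pooled other targets:

* ordinary least squares of y = secondary log2(RP10K+1) on x = primary
  log2(RP10K+1), lost alleles included at y = 0;
* homogeneity-of-slopes ANCOVA — the F test of the group x slope
  interaction in the pooled two-group linear model;
* Pearson chi-square (no continuity correction) on the 2x2 lost/preserved
  table.

A gene is flagged when its slope is significantly different from — and
lower than — the pooled control slope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .quantify import PairedAllele

MIN_ALLELES = 3


class InsufficientAllelesError(ValueError):
    pass


class DegeneratePredictorError(ValueError):
    pass


class NoValidControlsError(ValueError):
    pass


@dataclass(frozen=True)
class RegressionResult:
    label: str
    n_alleles: int
    slope: float
    intercept: float
    r_squared: float
    slope_se: float
    p_slope: float


@dataclass(frozen=True)
class AncovaResult:
    """Two-group homogeneity-of-slopes test."""

    labels: tuple[str, str]
    slopes: tuple[float, float]
    f_interaction: float
    df: tuple[int, int]
    p_value: float


@dataclass(frozen=True)
class ChiSquareResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    statistic: float
    df: int
    p_value: float
    degenerate: bool = False


def _xy(pairs: list[PairedAllele]) -> tuple[np.ndarray, np.ndarray]:
    x = np.array([p.primary.log_score for p in pairs])
    y = np.array([p.secondary.log_score for p in pairs])
    return x, y


def fit_regression(pairs: list[PairedAllele], label: str = "") -> RegressionResult:
    """OLS of regenerate on primary log scores for one gene set."""
    if len(pairs) < MIN_ALLELES:
        raise InsufficientAllelesError(
            f"{label or 'gene set'}: {len(pairs)} alleles < {MIN_ALLELES}")
    x, y = _xy(pairs)
    if np.ptp(x) == 0:
        raise DegeneratePredictorError(f"{label}: constant predictor")
    fit = sps.linregress(x, y)
    return RegressionResult(label=label, n_alleles=len(pairs),
                            slope=float(fit.slope), intercept=float(fit.intercept),
                            r_squared=float(fit.rvalue ** 2),
                            slope_se=float(fit.stderr), p_slope=float(fit.pvalue))


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def compare_slopes_ancova(pairs_a: list[PairedAllele], pairs_b: list[PairedAllele],
                          labels: tuple[str, str] = ("A", "B")) -> AncovaResult:
    """Test whether two gene sets share a regression slope.

    Fits the pooled model y = b0 + b1 x + b2 g + b3 (x g) and compares it
    to the common-slope reduction by the extra-sum-of-squares F test:
    F = (RSS_reduced - RSS_full) / (RSS_full / (n - 4)) on (1, n - 4) df.
    """
    fit_a = fit_regression(pairs_a, labels[0])
    fit_b = fit_regression(pairs_b, labels[1])
    xa, ya = _xy(pairs_a)
    xb, yb = _xy(pairs_b)
    x = np.concatenate([xa, xb])
    y = np.concatenate([ya, yb])
    g = np.concatenate([np.zeros(len(xa)), np.ones(len(xb))])
    n = len(x)
    full = np.column_stack([np.ones(n), x, g, x * g])
    reduced = full[:, :3]
    rss_full = _rss(full, y)
    rss_reduced = _rss(reduced, y)
    df2 = n - 4
    f = (rss_reduced - rss_full) / (rss_full / df2) if rss_full > 0 else 0.0
    if f < 1e-10:  # identical groups up to floating-point noise
        f = 0.0
    p = float(sps.f.sf(f, 1, df2)) if f > 0 else 1.0
    return AncovaResult(labels=labels, slopes=(fit_a.slope, fit_b.slope),
                        f_interaction=f, df=(1, df2), p_value=p)


def allele_loss_chisq(lost_a: int, total_a: int, lost_b: int,
                      total_b: int) -> ChiSquareResult:
    """Pearson chi-square (df=1, no continuity correction) comparing the
    lost/preserved split of two gene sets."""
    if total_a <= 0 or total_b <= 0:
        raise ValueError("totals must be positive")
    if lost_a > total_a or lost_b > total_b or min(lost_a, lost_b) < 0:
        raise ValueError("lost counts must lie in [0, total]")
    table = ((lost_a, total_a - lost_a), (lost_b, total_b - lost_b))
    row = (float(total_a), float(total_b))
    col = (float(lost_a + lost_b), float(total_a + total_b - lost_a - lost_b))
    if min(row) == 0 or min(col) == 0:
        return ChiSquareResult(table=table, statistic=0.0, df=1, p_value=1.0,
                               degenerate=True)
    n = row[0] + row[1]
    stat = 0.0
    for i in (0, 1):
        for j in (0, 1):
            expected = row[i] * col[j] / n
            stat += (table[i][j] - expected) ** 2 / expected
    return ChiSquareResult(table=table, statistic=stat, df=1,
                           p_value=float(sps.chi2.sf(stat, 1)))


def _lost_total(pairs: list[PairedAllele]) -> tuple[int, int]:
    return sum(p.lost for p in pairs), len(pairs)


@dataclass
class GeneScreenResult:
    gene: str
    n_alleles: int
    verdict: str  # flagged | not flagged | insufficient alleles
    regression: RegressionResult | None = None
    ancova_vs_controls: AncovaResult | None = None
    ancova_vs_others: AncovaResult | None = None
    ancova_vs_others_trimmed: AncovaResult | None = None
    chisq_vs_controls: ChiSquareResult | None = None
    chisq_vs_others: ChiSquareResult | None = None
    chisq_vs_others_trimmed: ChiSquareResult | None = None


@dataclass
class ScreenReport:
    control_genes: tuple[str, ...]
    control_regression: RegressionResult
    alpha: float
    genes: dict[str, GeneScreenResult] = field(default_factory=dict)

    @property
    def flagged(self) -> list[str]:
        return [g for g, r in self.genes.items() if r.verdict == "flagged"]

    def to_records(self) -> list[dict]:
        rows = []
        for g, r in self.genes.items():
            row: dict = {"gene": g, "n_alleles": r.n_alleles, "verdict": r.verdict}
            if r.regression:
                row.update(slope=r.regression.slope,
                           r_squared=r.regression.r_squared)
            for name in ("ancova_vs_controls", "ancova_vs_others",
                         "ancova_vs_others_trimmed"):
                a: AncovaResult | None = getattr(r, name)
                if a:
                    row[f"{name}_F"] = a.f_interaction
                    row[f"{name}_p"] = a.p_value
            for name in ("chisq_vs_controls", "chisq_vs_others",
                         "chisq_vs_others_trimmed"):
                c: ChiSquareResult | None = getattr(r, name)
                if c:
                    row[f"{name}_stat"] = c.statistic
                    row[f"{name}_p"] = c.p_value
            rows.append(row)
        return rows


def build_screen_report(pairs_by_gene: dict[str, list[PairedAllele]],
                        control_genes, alpha: float = 0.05) -> ScreenReport:
    """Assemble per-gene selection verdicts for a whole screen.

    Every experimental gene with >= 3 paired alleles is ANCOVA-compared
    against the pooled controls; genes significant there are candidate
    outliers, and each gene is then re-compared against the pooled other
    targets with those outliers excluded (the published procedure for
    keeping one strongly selected gene from masking another). Loss
    chi-squares are computed against the same three pools. The verdict is
    ``flagged`` when the ANCOVA against controls is significant and the
    gene's slope is below the control slope.
    """
    control_genes = tuple(control_genes)
    present_controls = [g for g in control_genes if pairs_by_gene.get(g)]
    if len(present_controls) < 2:
        raise NoValidControlsError(
            f"need >= 2 control genes with alleles, have {present_controls}")
    control_pairs = [p for g in present_controls for p in pairs_by_gene[g]]
    if len(control_pairs) < MIN_ALLELES:
        raise NoValidControlsError("pooled controls have too few alleles")
    control_fit = fit_regression(control_pairs, "controls")
    lost_c, total_c = _lost_total(control_pairs)

    experimental = {g: pairs for g, pairs in pairs_by_gene.items()
                    if g not in control_genes}
    report = ScreenReport(control_genes=control_genes,
                          control_regression=control_fit, alpha=alpha)

    # First pass: each gene against the pooled controls.
    candidates: set[str] = set()
    for gene, pairs in experimental.items():
        if len(pairs) < MIN_ALLELES:
            report.genes[gene] = GeneScreenResult(gene=gene, n_alleles=len(pairs),
                                                  verdict="insufficient alleles")
            continue
        res = GeneScreenResult(gene=gene, n_alleles=len(pairs), verdict="not flagged")
        res.regression = fit_regression(pairs, gene)
        try:
            res.ancova_vs_controls = compare_slopes_ancova(
                pairs, control_pairs, (gene, "controls"))
        except DegeneratePredictorError:
            pass
        lost_g, total_g = _lost_total(pairs)
        res.chisq_vs_controls = allele_loss_chisq(lost_g, total_g, lost_c, total_c)
        if (res.ancova_vs_controls is not None
                and res.ancova_vs_controls.p_value < alpha):
            candidates.add(gene)
            if res.regression.slope < control_fit.slope:
                res.verdict = "flagged"
        report.genes[gene] = res

    # Second pass: against all other targets, with and without candidate
    # outliers in the comparison pool.
    for gene, res in report.genes.items():
        if res.verdict == "insufficient alleles":
            continue
        pairs = experimental[gene]
        others = [p for g, ps in experimental.items() if g != gene for p in ps]
        trimmed = [p for g, ps in experimental.items()
                   if g != gene and g not in candidates for p in ps]
        lost_g, total_g = _lost_total(pairs)
        for pool, a_name, c_name in ((others, "ancova_vs_others", "chisq_vs_others"),
                                     (trimmed, "ancova_vs_others_trimmed",
                                      "chisq_vs_others_trimmed")):
            if len(pool) >= MIN_ALLELES:
                try:
                    setattr(res, a_name,
                            compare_slopes_ancova(pairs, pool, (gene, "others")))
                except DegeneratePredictorError:
                    pass
                lost_o, total_o = _lost_total(pool)
                setattr(res, c_name,
                        allele_loss_chisq(lost_g, total_g, lost_o, total_o))
    return report
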