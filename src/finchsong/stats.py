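"""Statistical analyses for song-learning experiments.

Covers the study-level analyses: paired within-nest median comparison for
cross-fostering (Wilcoxon signed-rank), tempo-bias bin contrasts (Welch t
tests, one-tailed where the hypothesis is directional, significant at
0.025), the 3x3 genetic-background x tutor-tempo grid with omega-squared
variance partitioning, spectral/temporal trade-off correlations, gamma fits
to SD distributions, and Holm-Bonferroni family-wise correction applied
within each experiment family.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sst
from statsmodels.stats.multitest import multipletests

__all__ = [
    "NestRecord",
    "TestResult",
    "GammaFitResult",
    "GridResult",
    "nest_medians",
    "wilcoxon_signed_rank",
    "holm_bonferroni",
    "adjust_family",
    "anova_omega2",
    "t_test",
    "gamma_fit",
    "classify_match",
    "grid_analysis",
    "tradeoff_tests",
]

#: One-tailed tests use a 0.025 threshold (false-positive rate of a two-tailed test).
ONE_TAILED_ALPHA = 0.025


@dataclass(frozen=True)
class NestRecord:
    """One bird's metadata and learning outcome."""

    bird_id: str
    nest_id: str
    father_tempo: float
    condition: str  # 'home' | 'fostered' | 'computer'
    sd_bits: float
    tutor_tempo: float | None = None
    tutee_tempo: float | None = None

    def __post_init__(self):
        if self.father_tempo <= 0:
            raise ValueError("father_tempo must be positive")
        if self.sd_bits < 0:
            raise ValueError("sd_bits must be non-negative")


@dataclass(frozen=True)
class TestResult:
    """A hypothesis-test outcome; ``p_adjusted`` is filled by Holm correction."""

    statistic: float
    p_raw: float
    tails: int
    method: str
    p_adjusted: float | None = None
    effect_size: float | None = None
    alpha: float | None = None


@dataclass(frozen=True)
class GammaFitResult:
    """Maximum-likelihood gamma fit (location fixed at 0) to SD scores."""

    shape: float
    scale: float
    p50: float
    p80: float

    def pdf(self, x) -> np.ndarray:
        return sst.gamma.pdf(x, self.shape, loc=0.0, scale=self.scale)


def nest_medians(records: Sequence[NestRecord]) -> pd.DataFrame:
    """Per-nest paired medians of SD for home-reared vs cross-fostered birds.

    Returns a DataFrame indexed by nest_id with columns median_home and
    median_fostered; raises if a nest lacks either condition.
    """
    if not records:
        raise ValueError("no records supplied")
    df = pd.DataFrame(
        {
            "nest_id": [r.nest_id for r in records],
            "condition": [r.condition for r in records],
            "sd_bits": [r.sd_bits for r in records],
        }
    )
    rows = {}
    for nest, grp in df.groupby("nest_id"):
        home = grp.loc[grp.condition == "home", "sd_bits"]
        fostered = grp.loc[grp.condition == "fostered", "sd_bits"]
        if home.empty or fostered.empty:
            missing = "home" if home.empty else "fostered"
            raise ValueError(f"nest {nest!r} has no {missing} birds")
        rows[nest] = (home.median(), fostered.median())
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["median_home", "median_fostered"]
    ).rename_axis("nest_id")


def wilcoxon_signed_rank(
    pairs: Sequence[tuple[float, float]], tails: int = 2
) -> TestResult:
    """Paired Wilcoxon signed-rank test on (a, b) pairs.

    Zero differences are dropped; the exact null distribution is used for
    n <= 25 with no tied |differences|, the normal approximation with
    midranks otherwise. The reported statistic is the signed rank sum
    W+ - W-, which flips sign when the pair order is swapped.
    """
    diffs = np.asarray([a - b for a, b in pairs], dtype=float)
    diffs = diffs[diffs != 0]
    n = diffs.size
    if n < 2:
        raise ValueError("need at least 2 non-zero differences")
    ranks = sst.rankdata(np.abs(diffs))
    w_plus = float(ranks[diffs > 0].sum())
    w_minus = float(ranks[diffs < 0].sum())
    has_ties = np.unique(np.abs(diffs)).size < n
    method = "exact" if (n <= 25 and not has_ties) else "approx"
    res = sst.wilcoxon(diffs, alternative="two-sided", method=method)
    p = res.pvalue if tails == 2 else res.pvalue / 2
    return TestResult(
        statistic=w_plus - w_minus,
        p_raw=float(p),
        tails=tails,
        method=f"wilcoxon-signed-rank ({method})",
        alpha=ONE_TAILED_ALPHA if tails == 1 else 0.05,
    )


def holm_bonferroni(pvals: Sequence[float]) -> list[float]:
    """Holm step-down adjusted p-values, order preserved.

    Controls the family-wise error rate at the Bonferroni level while being
    uniformly more powerful; adjusted values are monotone and >= raw values.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="holm")[1])


def adjust_family(results: Sequence[TestResult]) -> list[TestResult]:
    """Holm-correct a family of test results, returning updated copies."""
    adjusted = holm_bonferroni([r.p_raw for r in results])
    return [replace(r, p_adjusted=a) for r, a in zip(results, adjusted)]


def anova_omega2(groups: Sequence[Sequence[float]]) -> TestResult:
    """One-way ANOVA with omega-squared effect size.

    omega² = (SS_between − (k−1)·MS_within) / (SS_total + MS_within),
    clamped at 0; a less biased estimate of variance explained than eta².
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs n >= 2")
    all_x = np.concatenate(arrays)
    grand = all_x.mean()
    n_total = all_x.size
    k = len(arrays)
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    ss_total = ((all_x - grand) ** 2).sum()
    ms_between = ss_between / (k - 1)
    ms_within = ss_within / (n_total - k)
    if ms_within == 0:
        raise ValueError("zero within-group variance")
    f_stat = ms_between / ms_within
    p = float(sst.f.sf(f_stat, k - 1, n_total - k))
    omega2 = (ss_between - (k - 1) * ms_within) / (ss_total + ms_within)
    return TestResult(
        statistic=float(f_stat),
        p_raw=p,
        tails=2,
        method="one-way ANOVA",
        effect_size=float(max(omega2, 0.0)),
    )


def t_test(
    a: Sequence[float],
    b: Sequence[float],
    tails: int = 2,
    direction: str = "greater",
) -> TestResult:
    """Welch two-sample t test.

    For one-tailed tests, ``direction`` is the hypothesized sign of
    mean(a) − mean(b) ('greater' or 'less'); one-tailed significance is
    assessed at the 0.025 level.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    if np.std(a) == 0 and np.std(b) == 0 and a.mean() == b.mean():
        raise ValueError("degenerate samples: no variance and equal means")
    if tails == 2:
        alternative = "two-sided"
    elif direction in ("greater", "less"):
        alternative = direction
    else:
        raise ValueError("direction must be 'greater' or 'less'")
    res = sst.ttest_ind(a, b, equal_var=False, alternative=alternative)
    return TestResult(
        statistic=float(res.statistic),
        p_raw=float(res.pvalue),
        tails=tails,
        method="Welch t-test",
        alpha=ONE_TAILED_ALPHA if tails == 1 else 0.05,
    )


def gamma_fit(sd_scores: Sequence[float]) -> GammaFitResult:
    """ML gamma fit (location 0) with the 50th and 80th percentiles of the fit."""
    x = np.asarray(sd_scores, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 scores")
    if np.any(x <= 0):
        raise ValueError("gamma fit requires strictly positive scores")
    if np.all(x == x[0]):
        raise ValueError("constant data cannot be fit")
    shape, _, scale = sst.gamma.fit(x, floc=0.0)
    p50, p80 = sst.gamma.ppf([0.5, 0.8], shape, loc=0.0, scale=scale)
    return GammaFitResult(float(shape), float(scale), float(p50), float(p80))


def classify_match(
    tutor_tempo: float,
    father_tempo: float,
    tol: float | None = None,
    tutor_grid: Sequence[float] | None = None,
) -> str:
    """Categorize a bird by tutor tempo relative to its father's song.

    With an explicit ``tol``: matched iff |tutor − father| <= tol. With a
    ``tutor_grid`` (the tempos used in the experiment): matched iff the
    bird's tutor is the grid tempo nearest its father's tempo. Otherwise
    the label follows the sign of (tutor − father).
    Returns 'matched', 'tutor_faster', or 'tutor_slower'.
    """
    if tutor_tempo <= 0 or father_tempo <= 0:
        raise ValueError("tempos must be positive")
    if tol is not None:
        matched = abs(tutor_tempo - father_tempo) <= tol
    elif tutor_grid is not None:
        grid = np.asarray(tutor_grid, dtype=float)
        nearest = grid[np.argmin(np.abs(grid - father_tempo))]
        matched = np.isclose(tutor_tempo, nearest)
    else:
        matched = tutor_tempo == father_tempo
    if matched:
        return "matched"
    return "tutor_faster" if tutor_tempo > father_tempo else "tutor_slower"


@dataclass(frozen=True)
class GridResult:
    """3x3 background-by-tutor-tempo analysis.

    ``cell_means``/``normalized`` are DataFrames (rows: father tempo
    backgrounds; columns: tutor tempos); the three tests partition variance
    by match category, genetic background alone, and tutor tempo alone,
    Holm-corrected as one family.
    """

    cell_means: pd.DataFrame
    normalized: pd.DataFrame
    category_test: TestResult
    background_test: TestResult
    tutor_test: TestResult
    category_means: dict[str, float]


def grid_analysis(
    records: Sequence[NestRecord], normalization: str = "minmax"
) -> GridResult:
    """Analyze a full background x tutor-tempo tutoring grid.

    Computes per-cell mean SD (normalized across the 9 cells for display),
    assigns each bird a match category by nearest-tutor rule, and partitions
    SD variance (omega²) by category, background, and tutor tempo.
    """
    recs = [r for r in records if r.tutor_tempo is not None]
    if not recs:
        raise ValueError("no records with tutor_tempo")
    df = pd.DataFrame(
        {
            "father": [r.father_tempo for r in recs],
            "tutor": [r.tutor_tempo for r in recs],
            "sd": [r.sd_bits for r in recs],
        }
    )
    backgrounds = sorted(df.father.unique())
    tutors = sorted(df.tutor.unique())
    cell_means = pd.DataFrame(index=backgrounds, columns=tutors, dtype=float)
    for bg in backgrounds:
        for tu in tutors:
            cell = df[(df.father == bg) & (df.tutor == tu)].sd
            if cell.empty:
                raise ValueError(f"empty cell: background {bg} x tutor {tu}")
            cell_means.loc[bg, tu] = cell.mean()
    vals = cell_means.to_numpy(dtype=float)
    if normalization == "minmax":
        span = vals.max() - vals.min()
        norm = (vals - vals.min()) / span if span > 0 else np.zeros_like(vals)
    elif normalization == "zscore":
        sd = vals.std()
        norm = (vals - vals.mean()) / sd if sd > 0 else np.zeros_like(vals)
    else:
        raise ValueError("normalization must be 'minmax' or 'zscore'")
    normalized = pd.DataFrame(norm, index=backgrounds, columns=tutors)

    df["category"] = [
        classify_match(r.tutor, r.father, tutor_grid=tutors)
        for r in df.itertuples()
    ]
    cat_groups = [g.sd.to_numpy() for _, g in df.groupby("category")]
    bg_groups = [g.sd.to_numpy() for _, g in df.groupby("father")]
    tutor_groups = [g.sd.to_numpy() for _, g in df.groupby("tutor")]
    tests = adjust_family(
        [anova_omega2(cat_groups), anova_omega2(bg_groups), anova_omega2(tutor_groups)]
    )
    category_means = df.groupby("category").sd.mean().to_dict()
    return GridResult(
        cell_means=cell_means,
        normalized=normalized,
        category_test=tests[0],
        background_test=tests[1],
        tutor_test=tests[2],
        category_means=category_means,
    )


def tradeoff_tests(records: Sequence[NestRecord]) -> list[TestResult]:
    """Spectral/temporal trade-off: does better tempo matching accompany
    better spectral copying?

    Returns Holm-corrected Pearson correlations of SD with the tutee's
    measured tempo and of SD with |tutee tempo − tutor tempo|.
    """
    recs = [
        r for r in records if r.tutee_tempo is not None and r.tutor_tempo is not None
    ]
    if len(recs) < 3:
        raise ValueError("need at least 3 records with measured tutee tempo")
    sd = np.asarray([r.sd_bits for r in recs])
    tempo = np.asarray([r.tutee_tempo for r in recs])
    mismatch = np.abs(tempo - np.asarray([r.tutor_tempo for r in recs]))
    if np.std(sd) == 0:
        raise ValueError("degenerate input: SD has no variance")
    results = []
    for x, label in ((tempo, "SD vs tutee tempo"), (mismatch, "SD vs |tempo error|")):
        if np.std(x) == 0:
            raise ValueError(f"degenerate input: {label} predictor is constant")
        r, p = sst.pearsonr(sd, x)
        results.append(
            TestResult(statistic=float(r), p_raw=float(p), tails=2,
                       method=f"pearson ({label})", effect_size=float(r) ** 2)
        )
    return adjust_family(results)
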