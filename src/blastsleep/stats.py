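"""Nonparametric testing battery with multiple-comparison handling.

The designs this package serves rarely pass normality screens (small n,
bounded ratios, heavy tails), so the battery is rank-based throughout:

* :func:`normality_gate` — Jarque–Bera screen, informational by default;
* :func:`two_group_test` — two-sided Mann–Whitney U (exact for small
  tie-free samples, tie-corrected normal approximation otherwise);
* :func:`multi_group_test` — Kruskal–Wallis followed by Dunn's pairwise
  z-tests on mean ranks with Bonferroni correction;
* :func:`repeated_measures_test` — Friedman over conditions followed by
  pairwise Wilcoxon signed-rank with Bonferroni correction.

Ties take mid-ranks everywhere; adjusted p values are capped at 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats

__all__ = [
    "TestResult",
    "normality_gate",
    "two_group_test",
    "multi_group_test",
    "repeated_measures_test",
    "dunn_posthoc",
]


@dataclass
class TestResult:
    statistic_name: str
    statistic: float
    p_raw: float
    p_adjusted: float
    comparison: str
    n_per_group: tuple

    def __post_init__(self) -> None:
        self.p_raw = float(min(max(self.p_raw, 0.0), 1.0))
        self.p_adjusted = float(min(max(self.p_adjusted, self.p_raw), 1.0))


def normality_gate(x, alpha: float = 0.05) -> str:
    """Jarque–Bera screen: ``"parametric"`` or ``"nonparametric"``.

    Constant sequences (undefined kurtosis) count as non-normal.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 8:
        raise ValueError("normality_gate needs at least 8 observations")
    if np.ptp(x) == 0:
        return "nonparametric"
    stat, p = scipy.stats.jarque_bera(x)
    return "nonparametric" if p < alpha else "parametric"


def two_group_test(a, b, comparison: str = "a vs b") -> TestResult:
    """Two-sided Mann–Whitney U.

    Exact distribution when the smaller sample has ≤ 8 observations and
    there are no cross-group ties; tie-corrected normal approximation
    otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("two_group_test needs non-empty groups")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(a), len(b)) <= 8 and not has_ties) else "asymptotic"
    res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult(
        statistic_name="U",
        statistic=float(res.statistic),
        p_raw=float(res.pvalue),
        p_adjusted=float(res.pvalue),
        comparison=comparison,
        n_per_group=(len(a), len(b)),
    )


def _mid_ranks(groups: list[np.ndarray]) -> tuple[list[np.ndarray], np.ndarray]:
    pooled = np.concatenate(groups)
    ranks = scipy.stats.rankdata(pooled)
    out, i = [], 0
    for g in groups:
        out.append(ranks[i : i + len(g)])
        i += len(g)
    return out, pooled


def dunn_posthoc(groups: list[np.ndarray], names: list[str] | None = None) -> list[TestResult]:
    """Dunn's pairwise z-tests on mean ranks, Bonferroni-adjusted.

    The z denominator uses the tie-corrected rank variance
    ``(N(N+1)/12 − ΣT/(12(N−1))) (1/nᵢ + 1/nⱼ)`` with ``T = t³ − t`` per
    tied value; the Bonferroni factor is the number of pairs.
    """
    names = names or [f"g{i}" for i in range(len(groups))]
    ranked, pooled = _mid_ranks(groups)
    n_tot = len(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(counts**3 - counts))
    var_term = n_tot * (n_tot + 1) / 12.0 - tie_sum / (12.0 * (n_tot - 1))
    n_pairs = len(groups) * (len(groups) - 1) // 2

    out = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            ni, nj = len(groups[i]), len(groups[j])
            denom = np.sqrt(var_term * (1.0 / ni + 1.0 / nj))
            z = (ranked[i].mean() - ranked[j].mean()) / denom if denom > 0 else 0.0
            p = 2.0 * scipy.stats.norm.sf(abs(z))
            out.append(
                TestResult(
                    statistic_name="Dunn z",
                    statistic=float(z),
                    p_raw=p,
                    p_adjusted=min(1.0, p * n_pairs),
                    comparison=f"{names[i]} vs {names[j]}",
                    n_per_group=(ni, nj),
                )
            )
    return out


def multi_group_test(groups, names: list[str] | None = None) -> list[TestResult]:
    """Kruskal–Wallis over ≥ 3 groups, then Dunn-Bonferroni post hocs.

    The first returned entry is the omnibus H test; the remaining entries
    are the pairwise comparisons.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise ValueError("multi_group_test needs >= 3 groups; use two_group_test")
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    names = names or [f"g{i}" for i in range(len(groups))]
    if np.ptp(np.concatenate(groups)) == 0:
        h_stat, h_p = 0.0, 1.0  # all observations identical; H degenerates to 0
    else:
        h_stat, h_p = scipy.stats.kruskal(*groups)
    omnibus = TestResult(
        statistic_name="Kruskal-Wallis H",
        statistic=float(h_stat),
        p_raw=float(h_p),
        p_adjusted=float(h_p),
        comparison=" vs ".join(names),
        n_per_group=tuple(len(g) for g in groups),
    )
    return [omnibus, *dunn_posthoc(groups, names)]


def repeated_measures_test(matrix, condition_names: list[str] | None = None) -> list[TestResult]:
    """Friedman over subjects × conditions, then Wilcoxon-Bonferroni pairs.

    ``matrix`` has one row per subject and one column per condition; no
    missing cells are allowed.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2 or m.shape[0] < 3:
        raise ValueError("need a subjects × conditions matrix, >=3 subjects, >=2 conditions")
    if not np.all(np.isfinite(m)):
        raise ValueError("missing cells are not allowed")
    n_subj, n_cond = m.shape
    names = condition_names or [f"c{j}" for j in range(n_cond)]

    if np.all(m == m[:, [0]]):
        # every subject constant across conditions: no rank information
        chi2, p = 0.0, 1.0
    elif n_cond == 2:
        # scipy's Friedman needs >= 3 conditions; the 2-condition statistic
        # reduces to the sign-test chi-square on paired rank differences
        diff = m[:, 1] - m[:, 0]
        n_pos = int(np.sum(diff > 0))
        n_neg = int(np.sum(diff < 0))
        n_eff = n_pos + n_neg
        chi2 = (n_pos - n_neg) ** 2 / n_eff if n_eff else 0.0
        p = float(scipy.stats.chi2.sf(chi2, df=1)) if n_eff else 1.0
    else:
        chi2, p = scipy.stats.friedmanchisquare(*(m[:, j] for j in range(n_cond)))
    out = [
        TestResult(
            statistic_name="Friedman chi2",
            statistic=float(chi2),
            p_raw=float(p),
            p_adjusted=float(p),
            comparison=" vs ".join(names),
            n_per_group=(n_subj,) * n_cond,
        )
    ]
    n_pairs = n_cond * (n_cond - 1) // 2
    for i in range(n_cond):
        for j in range(i + 1, n_cond):
            d = m[:, i] - m[:, j]
            if np.all(d == 0):
                w, p = 0.0, 1.0
            else:
                res = scipy.stats.wilcoxon(m[:, i], m[:, j], alternative="two-sided")
                w, p = float(res.statistic), float(res.pvalue)
            out.append(
                TestResult(
                    statistic_name="Wilcoxon W",
                    statistic=w,
                    p_raw=p,
                    p_adjusted=min(1.0, p * n_pairs),
                    comparison=f"{names[i]} vs {names[j]}",
                    n_per_group=(n_subj, n_subj),
                )
            )
    return out
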