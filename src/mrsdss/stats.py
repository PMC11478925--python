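"""Reader-study evaluation statistics.

Implements the statistics used to assess the added value of MRS and the
decision-support output for radiological diagnosis:

* diagnostic accuracy under the strict ">50% certainty" rule,
* certainty-when-correct / when-incorrect summaries, where "correct"
  means the truth class carries the strict maximum certainty (so a
  40/35/25 split still counts as correct even though 40 <= 50),
* per-case stagewise changes in correct-class certainty, assessed by
  the Wilcoxon signed-rank test (exact sign enumeration for small n,
  tie-corrected normal approximation otherwise) with Hodges-Lehmann
  median estimates and confidence intervals,
* Levene / Brown-Forsythe variance comparison across raters,
* Kruskal-Wallis and one-way ANOVA metabolite comparisons with
  Bonferroni-adjusted pairwise t-tests.

The two correctness predicates are deliberately distinct, named
``strict_over_50`` and ``truth_is_max``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .classify import round_half_up
from .synthesize import REVIEW_STAGES, TUMOUR_TYPES

CERT_COLUMNS = {t: f"cert_{t}" for t in TUMOUR_TYPES}


def _stage_rows(table: pd.DataFrame, rater: str, stage: str) -> pd.DataFrame:
    rows = table[(table["rater"] == rater) & (table["stage"] == stage)]
    if rows.empty:
        raise ValueError(f"no rows for rater {rater!r} at stage {stage!r}")
    sums = rows[list(CERT_COLUMNS.values())].sum(axis=1)
    if not np.allclose(sums, 100.0, atol=1e-6):
        raise ValueError("certainty triples must sum to 100")
    return rows


def _truth_certainty(rows: pd.DataFrame) -> pd.Series:
    idx = rows["truth"].map(CERT_COLUMNS)
    return pd.Series(
        [row[c] for (_, row), c in zip(rows.iterrows(), idx)],
        index=rows.index, dtype=float,
    )


def strict_over_50(rows: pd.DataFrame) -> pd.Series:
    """Correct iff the certainty on the truth class exceeds 50 (strict)."""
    return _truth_certainty(rows) > 50.0


def truth_is_max(rows: pd.DataFrame) -> pd.Series:
    """Correct iff the truth class holds the strict maximum certainty."""
    certs = rows[list(CERT_COLUMNS.values())].to_numpy(dtype=float)
    truth_c = _truth_certainty(rows).to_numpy()
    others = np.array([
        np.delete(certs[i], TUMOUR_TYPES.index(t)).max()
        for i, t in enumerate(rows["truth"])
    ])
    return pd.Series(truth_c > others, index=rows.index)


@dataclass(frozen=True)
class AccuracyResult:
    percent: int
    exact: float
    n_correct: int
    n_total: int


def diagnostic_accuracy(table: pd.DataFrame, rater: str, stage: str
                        ) -> AccuracyResult:
    """Percentage of diagnoses made correctly with certainty > 50%."""
    rows = _stage_rows(table, rater, stage)
    correct = strict_over_50(rows)
    n_total = len(rows)
    n_correct = int(correct.sum())
    exact = 100.0 * n_correct / n_total
    return AccuracyResult(round_half_up(exact), exact, n_correct, n_total)


@dataclass(frozen=True)
class CertaintySummary:
    mean_correct: float | None
    sd_correct: float | None
    n_correct: int
    mean_incorrect: float | None
    sd_incorrect: float | None
    n_incorrect: int


def certainty_summary(table: pd.DataFrame, rater: str, stage: str
                      ) -> CertaintySummary:
    """Mean +/- SD of truth-class certainty, split by whether the truth
    class held the strict maximum certainty (ties count as incorrect)."""
    rows = _stage_rows(table, rater, stage)
    truth_c = _truth_certainty(rows)
    correct = truth_is_max(rows)

    def summarise(vals: pd.Series):
        if len(vals) == 0:
            return None, None, 0
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        return float(vals.mean()), sd, len(vals)

    mc, sc, nc = summarise(truth_c[correct])
    mi, si, ni = summarise(truth_c[~correct])
    return CertaintySummary(mc, sc, nc, mi, si, ni)


def certainty_change(table: pd.DataFrame, rater: str,
                     from_stage: str, to_stage: str) -> pd.Series:
    """Per-case delta of truth-class certainty between two stages."""
    a = _stage_rows(table, rater, from_stage).set_index("case")
    b = _stage_rows(table, rater, to_stage).set_index("case")
    if set(a.index) != set(b.index):
        odd = set(a.index) ^ set(b.index)
        raise ValueError(f"unpaired cases between stages: {sorted(odd)}")
    ca = _truth_certainty(a.reset_index()).to_numpy()
    cb = _truth_certainty(b.loc[a.index].reset_index()).to_numpy()
    return pd.Series(cb - ca, index=a.index, name="delta")


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float
    p_value: float
    median: float
    hl_estimate: float
    ci_low: float
    ci_high: float
    n_used: int
    method: str


def _signed_rank_stat(d: np.ndarray) -> tuple[float, np.ndarray]:
    ranks = sstats.rankdata(np.abs(d))
    return float(ranks[d > 0].sum()), ranks


def _exact_signed_rank_p(d: np.ndarray) -> tuple[float, float]:
    """Two-sided exact p by full 2^n sign enumeration (ties allowed)."""
    n = len(d)
    _, ranks = _signed_rank_stat(d)
    w_obs = float(ranks[d > 0].sum())
    signs = np.array(list(itertools.product([0, 1], repeat=n)), dtype=float)
    dist = signs @ ranks
    p_le = float(np.mean(dist <= w_obs + 1e-12))
    p_ge = float(np.mean(dist >= w_obs - 1e-12))
    return w_obs, min(1.0, 2.0 * min(p_le, p_ge))


def _hodges_lehmann(d: np.ndarray, alpha: float = 0.05
                    ) -> tuple[float, float, float]:
    """HL estimate and CI from ordered Walsh averages."""
    n = len(d)
    walsh = np.sort([
        (d[i] + d[j]) / 2.0 for i in range(n) for j in range(i, n)
    ])
    est = float(np.median(walsh))
    m = len(walsh)
    mean_w = n * (n + 1) / 4.0
    sd_w = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
    z = sstats.norm.ppf(1 - alpha / 2)
    k = int(np.floor(mean_w - z * sd_w))
    k = max(0, min(k, m - 1))
    return est, float(walsh[k]), float(walsh[m - 1 - k])


def wilcoxon_signed_rank(
    deltas,
    zero_policy: str = "wilcoxon",
    mode: str = "auto",
    exact_threshold: int = 15,
) -> WilcoxonResult:
    """Wilcoxon signed-rank test on paired differences.

    Zeros are dropped (``zero_policy="wilcoxon"``) or ranked and then
    discarded from the statistic (``"pratt"``).  ``mode="exact"``
    enumerates all 2^n sign assignments (used automatically for
    n <= ``exact_threshold``); ``"normal"`` applies the tie- and
    continuity-corrected Gaussian approximation.
    """
    d_all = np.asarray(deltas, dtype=float)
    if zero_policy not in ("wilcoxon", "pratt"):
        raise ValueError(f"unknown zero policy {zero_policy!r}")
    d = d_all[d_all != 0]
    if len(d) == 0:
        raise ValueError("all deltas are zero")
    hl, lo, hi = _hodges_lehmann(d_all if zero_policy == "pratt" else d)

    if zero_policy == "wilcoxon":
        ranks = sstats.rankdata(np.abs(d))
        n_eff = len(d)
        w = float(ranks[d > 0].sum())
        mean_w = n_eff * (n_eff + 1) / 4.0
        tie_counts = np.unique(ranks, return_counts=True)[1]
        var_w = n_eff * (n_eff + 1) * (2 * n_eff + 1) / 24.0 \
            - np.sum(tie_counts**3 - tie_counts) / 48.0
    else:  # pratt: rank zeros too, drop their rank contribution
        ranks_all = sstats.rankdata(np.abs(d_all))
        nz = d_all != 0
        n0 = int((~nz).sum())
        n_eff = len(d)
        w = float(ranks_all[d_all > 0].sum())
        n_tot = len(d_all)
        mean_w = (n_tot * (n_tot + 1) - n0 * (n0 + 1)) / 4.0
        tie_counts = np.unique(ranks_all[nz], return_counts=True)[1]
        var_w = (n_tot * (n_tot + 1) * (2 * n_tot + 1)
                 - n0 * (n0 + 1) * (2 * n0 + 1)) / 24.0 \
            - np.sum(tie_counts**3 - tie_counts) / 48.0

    use_exact = (mode == "exact") or (mode == "auto" and n_eff <= exact_threshold)
    if use_exact:
        if zero_policy == "pratt":
            # enumeration over the signs of the nonzero deltas, zeros
            # keeping their ranks
            ranks_nz = sstats.rankdata(np.abs(d_all))[d_all != 0]
            signs = np.array(list(itertools.product([0, 1], repeat=len(d))),
                             dtype=float)
            dist = signs @ ranks_nz
            p_le = float(np.mean(dist <= w + 1e-12))
            p_ge = float(np.mean(dist >= w - 1e-12))
            p = min(1.0, 2.0 * min(p_le, p_ge))
        else:
            w, p = _exact_signed_rank_p(d)
        method = "exact"
    else:
        if var_w <= 0:
            raise ValueError("degenerate variance (all |deltas| tied at zero?)")
        diff = w - mean_w
        cc = 0.5 * np.sign(diff) if diff != 0 else 0.0
        z = (diff - cc) / np.sqrt(var_w)
        p = float(2.0 * sstats.norm.sf(abs(z)))
        p = min(1.0, p)
        method = "normal"
    return WilcoxonResult(
        statistic=w, p_value=float(p),
        median=float(np.median(d_all)), hl_estimate=hl,
        ci_low=lo, ci_high=hi, n_used=n_eff, method=method,
    )


def levene_test(groups, center: str = "median") -> tuple[float, float]:
    """Levene's test for equality of variances.

    ``center="median"`` gives the Brown-Forsythe variant (default, for
    robustness); ``"mean"`` the classical test.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if len(g) < 2:
            raise ValueError("each group needs at least two observations")
    stat, p = sstats.levene(*groups, center=center)
    return float(stat), float(p)


def kruskal_wallis(groups, exact: bool = False) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with chi-square p.

    ``exact=True`` (total n <= 10) enumerates all group-label
    assignments and returns the permutation p instead.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        raise ValueError("all values identical")
    H, p_chi2 = sstats.kruskal(*groups)
    if not exact:
        return float(H), float(p_chi2)
    n = len(pooled)
    if n > 10:
        raise ValueError("exact enumeration limited to total n <= 10")
    sizes = [len(g) for g in groups]
    count = 0
    total = 0
    idx = np.arange(n)
    for assignment in _partitions(idx, sizes):
        perm_groups = [pooled[list(a)] for a in assignment]
        try:
            H_perm = sstats.kruskal(*perm_groups)[0]
        except ValueError:
            H_perm = 0.0
        total += 1
        if H_perm >= H - 1e-12:
            count += 1
    return float(H), count / total


def _partitions(idx: np.ndarray, sizes: list[int]):
    """All distinct assignments of indices into ordered groups of given sizes."""
    if len(sizes) == 1:
        yield (tuple(idx),)
        return
    for combo in itertools.combinations(idx, sizes[0]):
        rest = np.array(sorted(set(idx) - set(combo)))
        for tail in _partitions(rest, sizes[1:]):
            yield (combo,) + tail


def metabolite_group_comparison(
    table: pd.DataFrame,
    group_col: str,
    value_cols: list[str] | None = None,
    adjust: str = "bonferroni",
) -> pd.DataFrame:
    """Per-metabolite one-way ANOVA plus Bonferroni-adjusted pairwise
    two-sample t-tests across groups."""
    if value_cols is None:
        value_cols = [c for c in table.columns if c != group_col
                      and pd.api.types.is_numeric_dtype(table[c])]
    levels = sorted(table[group_col].unique())
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    pairs = list(itertools.combinations(levels, 2))
    m = len(pairs)
    rows = []
    for col in value_cols:
        groups = [table.loc[table[group_col] == lv, col].to_numpy(dtype=float)
                  for lv in levels]
        if any(len(g) < 2 for g in groups):
            raise ValueError(f"group with fewer than 2 observations for {col!r}")
        row: dict = {"metabolite": col}
        if all(np.ptp(g) == 0 for g in groups) and \
                np.ptp(np.concatenate(groups)) == 0:
            row["F"] = np.nan
            row["p"] = np.nan
        else:
            F, p = sstats.f_oneway(*groups)
            row["F"], row["p"] = float(F), float(p)
        for (a, b), ga, gb in (
            ((pair), groups[levels.index(pair[0])], groups[levels.index(pair[1])])
            for pair in pairs
        ):
            if np.ptp(np.concatenate([ga, gb])) == 0:
                padj = np.nan
            else:
                praw = float(sstats.ttest_ind(ga, gb).pvalue)
                padj = min(1.0, praw * m) if adjust == "bonferroni" else praw
            row[f"p_{a}_vs_{b}"] = padj
        rows.append(row)
    return pd.DataFrame(rows).set_index("metabolite")


def table2_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Accuracy and certainty summaries for every rater x stage."""
    rows = []
    for rater in sorted(table["rater"].unique()):
        for stage in REVIEW_STAGES:
            acc = diagnostic_accuracy(table, rater, stage)
            cs = certainty_summary(table, rater, stage)
            rows.append({
                "rater": rater,
                "stage": stage,
                "accuracy_percent": acc.percent,
                "n_correct": acc.n_correct,
                "n_total": acc.n_total,
                "mean_certainty_correct": cs.mean_correct,
                "sd_certainty_correct": cs.sd_correct,
                "mean_certainty_incorrect": cs.mean_incorrect,
                "sd_certainty_incorrect": cs.sd_incorrect,
            })
    return pd.DataFrame(rows)


__all__ = [
    "AccuracyResult",
    "CertaintySummary",
    "WilcoxonResult",
    "strict_over_50",
    "truth_is_max",
    "diagnostic_accuracy",
    "certainty_summary",
    "certainty_change",
    "wilcoxon_signed_rank",
    "levene_test",
    "kruskal_wallis",
    "metabolite_group_comparison",
    "table2_summary",
]
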