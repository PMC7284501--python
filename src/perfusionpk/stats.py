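"""Group summaries, hypothesis tests and fold-change inference for Kin.

Results are summarized as mean +/- SD (n-1 denominator).  Two groups are
compared with an unpaired Student t-test (pooled variance, mirroring the
reference analysis; Welch available behind a flag); three or more groups with
one-way ANOVA followed by Tukey's multiple-comparisons test (Tukey-Kramer for
unbalanced groups).  Significance is declared at p < 0.05 throughout.

Inhibitor and genotype effects are reported as the fold-change of group mean
Kin, with a seeded percentile bootstrap (resampling animals within each
group) providing the confidence interval.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import GroupComparison, RegionPK, ValidationError, regionpk_to_frame

ALPHA = 0.05


def summarize(values: Sequence[float]) -> tuple[float, float | None, int]:
    """Mean, sample SD (n-1 denominator; None for n=1) and n."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValidationError("cannot summarize an empty group")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else None
    return mean, sd, int(arr.size)


def two_group_test(
    a: Sequence[float], b: Sequence[float], welch: bool = False
) -> float:
    """Two-sided unpaired t-test p-value (Student pooled by default)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs n >= 2 for a t-test")
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        # degenerate variance: identical constants cannot be distinguished,
        # distinct constants separate with certainty (p -> 0 limit)
        return 1.0 if a.mean() == b.mean() else 0.0
    res = sps.ttest_ind(a, b, equal_var=not welch)
    return float(res.pvalue)


@dataclass(frozen=True)
class AnovaTukeyResult:
    f_stat: float
    p_value: float
    #: Tukey HSD adjusted p per unordered pair of group labels
    pairwise: Mapping[tuple[str, str], float]
    #: unadjusted pairwise p in the same pooled-variance frame (Fisher LSD)
    pairwise_raw: Mapping[tuple[str, str], float]


def anova_tukey(groups: Mapping[str, Sequence[float]]) -> AnovaTukeyResult:
    """One-way ANOVA omnibus test plus Tukey HSD adjusted pairwise p-values.

    Unbalanced groups are handled by the Tukey-Kramer form (studentized-range
    distribution with the pooled within-group variance).  ``pairwise_raw``
    carries the unadjusted p-values computed in the same frame (pooled
    within-group variance, N-k degrees of freedom), so the adjusted p is
    never below its raw counterpart.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValidationError("ANOVA needs at least two groups")
    arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    if any(a.size < 2 for a in arrays):
        raise ValidationError("each group needs n >= 2")

    within_ss = sum(float(((a - a.mean()) ** 2).sum()) for a in arrays)
    means = [float(a.mean()) for a in arrays]
    if within_ss == 0.0:
        # degenerate within-group variance: identical constants are
        # indistinguishable, distinct constants separate with certainty
        if len(set(means)) == 1:
            ones = {tuple(sorted(p)): 1.0 for p in itertools.combinations(labels, 2)}
            return AnovaTukeyResult(0.0, 1.0, ones, dict(ones))
        pairwise = {
            tuple(sorted((la, lb))): (
                1.0
                if arrays[labels.index(la)].mean() == arrays[labels.index(lb)].mean()
                else 0.0
            )
            for la, lb in itertools.combinations(labels, 2)
        }
        return AnovaTukeyResult(math.inf, 0.0, pairwise, dict(pairwise))

    f_stat, p_value = sps.f_oneway(*arrays)
    hsd = sps.tukey_hsd(*arrays)
    n_total = sum(a.size for a in arrays)
    df_within = n_total - len(arrays)
    msw = within_ss / df_within
    pairwise: dict[tuple[str, str], float] = {}
    pairwise_raw: dict[tuple[str, str], float] = {}
    for i, j in itertools.combinations(range(len(labels)), 2):
        key = tuple(sorted((labels[i], labels[j])))
        pairwise[key] = float(hsd.pvalue[i, j])
        se = math.sqrt(msw * (1.0 / arrays[i].size + 1.0 / arrays[j].size))
        t = (arrays[i].mean() - arrays[j].mean()) / se
        pairwise_raw[key] = float(2.0 * sps.t.sf(abs(t), df_within))
    return AnovaTukeyResult(float(f_stat), float(p_value), pairwise, pairwise_raw)


def _se_log_fold(ref: np.ndarray, tst: np.ndarray) -> float:
    """Delta-method standard error of log(mean(tst)/mean(ref))."""
    return math.sqrt(
        ref.var(ddof=1) / (ref.size * ref.mean() ** 2)
        + tst.var(ddof=1) / (tst.size * tst.mean() ** 2)
    )


def fold_change(
    reference: Sequence[float],
    test: Sequence[float],
    n_boot: int = 10_000,
    seed: int | None = None,
    ci_level: float = 0.95,
    method: str = "bootstrap_t",
    region: str | None = None,
    reference_group: str = "reference",
    test_group: str = "test",
    p_value: float | None = None,
    test_name: str | None = None,
) -> GroupComparison:
    """Fold-change of group means with a seeded bootstrap CI.

    The ratio ``mean(test)/mean(reference)`` is the estimand the reference
    analysis reports.  The CI resamples animals with replacement within each
    group (stratified).  ``method`` selects the interval: ``"bootstrap_t"``
    (default) studentizes the log fold-change with its delta-method standard
    error, which keeps near-nominal coverage at the small group sizes
    typical of perfusion studies (n = 4-10); ``"percentile"`` is the plain
    percentile interval.  When the studentized interval is degenerate (zero
    within-group variance) the percentile interval is used.  If ``p_value``
    is not supplied, a Student t-test is run when both groups allow it.
    """
    if method not in ("bootstrap_t", "percentile"):
        raise ValidationError(f"unknown CI method {method!r}")
    ref = np.asarray(reference, dtype=float)
    tst = np.asarray(test, dtype=float)
    if ref.size == 0 or tst.size == 0:
        raise ValidationError("both groups must be non-empty")
    mean_ref, sd_ref, n_ref = summarize(ref)
    mean_test, sd_test, n_test = summarize(tst)
    if not mean_ref > 0:
        raise ValidationError("reference mean must be > 0")
    fold = mean_test / mean_ref

    rng = np.random.default_rng(seed)
    ref_idx = rng.integers(0, n_ref, size=(n_boot, n_ref))
    tst_idx = rng.integers(0, n_test, size=(n_boot, n_test))
    boot_ref = ref[ref_idx]
    boot_tst = tst[tst_idx]
    bm_ref = boot_ref.mean(axis=1)
    bm_tst = boot_tst.mean(axis=1)
    tail = (1.0 - ci_level) / 2.0

    se = _se_log_fold(ref, tst) if n_ref > 1 and n_test > 1 and fold > 0 else 0.0
    if method == "bootstrap_t" and se > 0.0 and np.isfinite(se):
        log_fold = math.log(fold)
        with np.errstate(divide="ignore", invalid="ignore"):
            bse = np.sqrt(
                boot_ref.var(ddof=1, axis=1) / (n_ref * bm_ref**2)
                + boot_tst.var(ddof=1, axis=1) / (n_test * bm_tst**2)
            )
        ok = (bm_ref > 0) & (bm_tst > 0) & (bse > 0) & np.isfinite(bse)
        t_star = (np.log(bm_tst[ok] / bm_ref[ok]) - log_fold) / bse[ok]
        q_lo, q_hi = np.quantile(t_star, [tail, 1.0 - tail])
        lo = math.exp(log_fold - q_hi * se)
        hi = math.exp(log_fold - q_lo * se)
    else:
        ok = bm_ref > 0
        folds = bm_tst[ok] / bm_ref[ok]
        lo, hi = np.percentile(folds, [100.0 * tail, 100.0 * (1.0 - tail)])

    if p_value is None:
        if n_ref >= 2 and n_test >= 2:
            p_value = two_group_test(ref, tst)
            test_name = test_name or "student_t"
        else:
            p_value, test_name = 1.0, test_name or "insufficient_n"

    return GroupComparison(
        region=region,
        reference_group=reference_group,
        test_group=test_group,
        mean_ref=mean_ref,
        sd_ref=sd_ref,
        n_ref=n_ref,
        mean_test=mean_test,
        sd_test=sd_test,
        n_test=n_test,
        fold_change=fold,
        fold_ci=(float(lo), float(hi)),
        p_value=float(p_value),
        test_name=test_name or "student_t",
    )


def compare_table(
    results: Sequence[RegionPK] | pd.DataFrame,
    reference_group: str,
    by: Sequence[str] = ("region", "treatment"),
    value: str = "Kin_uL_per_s_per_g",
    group_col: str = "group",
    n_boot: int = 10_000,
    seed: int = 0,
) -> list[GroupComparison]:
    """Group contrasts of Kin against a reference group, per stratum.

    ``by`` names the stratifying columns of the tabulated results (e.g.
    region and treatment, so that each inhibitor arm is compared against the
    untreated reference within its region).  When a stratum holds more than
    two groups the pairwise p-values come from one-way ANOVA with Tukey's
    adjustment; with exactly two groups, from the Student t-test.
    """
    df = results if isinstance(results, pd.DataFrame) else regionpk_to_frame(results)
    comparisons: list[GroupComparison] = []
    for key, stratum in df.groupby(list(by), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        groups = {
            g: sub[value].to_numpy(dtype=float)
            for g, sub in stratum.groupby(group_col, sort=True)
        }
        if reference_group not in groups:
            continue
        others = [g for g in groups if g != reference_group]
        if not others:
            continue
        tukey = None
        if len(groups) > 2 and all(len(v) >= 2 for v in groups.values()):
            tukey = anova_tukey(groups)
        region = None
        if "region" in by:
            region = str(key[list(by).index("region")])
        for g in others:
            if tukey is not None:
                p = tukey.pairwise[tuple(sorted((reference_group, g)))]
                name = "anova_tukey"
            else:
                p = None
                name = None
            comparisons.append(
                fold_change(
                    groups[reference_group],
                    groups[g],
                    n_boot=n_boot,
                    seed=seed,
                    region=region,
                    reference_group=reference_group,
                    test_group=g,
                    p_value=p,
                    test_name=name,
                )
            )
    return comparisons
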