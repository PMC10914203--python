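"""Subject-paired resampled inference over grouped arousal measurements.

Arousal groups share subjects, so measurements are not independent across
groups; comparisons therefore use the Wilcoxon signed-rank test on
within-subject pairs, iterated over random subsamplings:

* per iteration, for each subject present in both groups, the larger side is
  sampled without replacement down to the smaller side's count and randomly
  paired with the other side's measurements from the same subject;
* pairs are pooled across subjects and the signed-rank test is run;
* the median p-value over the iterations (default 1000) is the reported
  significance measure, at a global threshold of p = 0.01.

Group proportions (response / recovery present) are compared with relative
risks of *not* detecting the outcome, with log-normal 99% confidence
intervals. Before/after characteristic levels are compared against a
stable-sleep baseline (the median over stable-sample means), and
magnitude-delay relationships with the Pearson correlation.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

ALPHA = 0.01  # global significance threshold
CI_LEVEL = 0.99

#: subject_id -> measurements for one arousal group
GroupedMeasures = dict[str, list[float]]


@dataclass
class IteratedTestResult:
    median_p: float
    n_iterations: int
    p_values: np.ndarray
    alternative: str
    n_pairs: int  # pairs per iteration (pooled across subjects)
    degenerate: bool = False  # all-zero differences in every iteration

    @property
    def significant(self) -> bool:
        return self.median_p < ALPHA


@dataclass
class RelativeRiskResult:
    rr: float
    ci99: tuple[float, float]
    counts: tuple[int, int, int, int]  # x1, n1, x2, n2
    corrected: bool = False

    @property
    def significant(self) -> bool:
        lo, hi = self.ci99
        return lo > 1.0 or hi < 1.0


def signed_rank_p(diffs: np.ndarray, alternative: str = "two-sided") -> float:
    """Wilcoxon signed-rank p-value of paired differences.

    Exact null distribution for <= 25 non-zero-free pairs; otherwise the
    normal approximation with Pratt zero handling. All-zero differences are a
    degenerate case where the test is undefined; p = 1 is returned (no
    evidence of a shift).
    """
    d = np.asarray(diffs, float)
    if len(d) == 0 or np.all(d == 0):
        return 1.0
    try:
        if len(d) <= 25 and not np.any(d == 0):
            res = sps.wilcoxon(d, alternative=alternative, method="exact")
        else:
            res = sps.wilcoxon(
                d, alternative=alternative, zero_method="pratt", method="approx",
                correction=True,
            )
    except ValueError:
        res = sps.wilcoxon(
            d, alternative=alternative, zero_method="pratt", method="approx",
            correction=True,
        )
    return float(res.pvalue)


def _paired_differences(
    a: np.ndarray, b: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One random down-sampled pairing of two same-subject measurement sets."""
    m = min(len(a), len(b))
    ia = rng.choice(len(a), size=m, replace=False)
    ib = rng.choice(len(b), size=m, replace=False)
    return a[ia] - b[ib]


def iterated_wilcoxon(
    group_a: GroupedMeasures,
    group_b: GroupedMeasures,
    n_iter: int = 1000,
    alternative: str = "two-sided",
    rng: np.random.Generator | None = None,
) -> IteratedTestResult:
    """Iterated subject-paired signed-rank test between two arousal groups."""
    rng = np.random.default_rng(rng)
    shared = sorted(
        s for s in group_a if s in group_b and len(group_a[s]) and len(group_b[s])
    )
    if not shared:
        raise ValueError("no paired support: no subject has measurements in both groups")
    arrays = [(np.asarray(group_a[s], float), np.asarray(group_b[s], float)) for s in shared]
    n_pairs = sum(min(len(a), len(b)) for a, b in arrays)
    ps = np.empty(n_iter)
    any_nondegenerate = False
    for it in range(n_iter):
        diffs = np.concatenate([_paired_differences(a, b, rng) for a, b in arrays])
        if np.any(diffs != 0):
            any_nondegenerate = True
        ps[it] = signed_rank_p(diffs, alternative)
    if not any_nondegenerate:
        logger.info("iterated_wilcoxon: all iterations degenerate (identical groups)")
    return IteratedTestResult(
        median_p=float(np.median(ps)),
        n_iterations=n_iter,
        p_values=ps,
        alternative=alternative,
        n_pairs=n_pairs,
        degenerate=not any_nondegenerate,
    )


def relative_risk(x1: int, n1: int, x2: int, n2: int) -> RelativeRiskResult:
    """Relative risk (x1/n1) / (x2/n2) with a log-normal 99% CI.

    CI = exp(log rr +/- z_{0.995} * sqrt(1/x1 - 1/n1 + 1/x2 - 1/n2)); zero
    numerators fall back to a 0.5 continuity correction (flagged).
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group sizes must be positive")
    corrected = x1 == 0 or x2 == 0
    fx1, fn1, fx2, fn2 = (
        (x1 + 0.5, n1 + 0.5, x2 + 0.5, n2 + 0.5) if corrected else (x1, n1, x2, n2)
    )
    rr = (fx1 / fn1) / (fx2 / fn2)
    z = sps.norm.ppf(0.5 + CI_LEVEL / 2)
    se = np.sqrt(1 / fx1 - 1 / fn1 + 1 / fx2 - 1 / fn2)
    ci = (float(rr * np.exp(-z * se)), float(rr * np.exp(z * se)))
    return RelativeRiskResult(float(rr), ci, (x1, n1, x2, n2), corrected)


def baseline_compare(
    levels: GroupedMeasures,
    stable_means: GroupedMeasures,
    n_iter: int = 1000,
    alternative: str = "two-sided",
    rng: np.random.Generator | None = None,
    iterate: bool = True,
) -> tuple[float, IteratedTestResult]:
    """Compare characteristic levels against the stable-sleep baseline.

    The baseline is the median over all stable-sample means (pooled across
    subjects). With ``iterate`` (default) the one-sample signed-rank test on
    (level - baseline) is subsampled per subject down to the subject's
    stable-sample count, mirroring the two-group procedure with the baseline
    as a constant pair member; otherwise a single test uses all levels.

    Returns (baseline, test result).
    """
    pooled = np.concatenate([np.asarray(v, float) for v in stable_means.values() if len(v)])
    if len(pooled) == 0:
        raise ValueError("no stable-sleep samples to define a baseline")
    baseline = float(np.median(pooled))
    if not iterate:
        diffs = np.concatenate(
            [np.asarray(v, float) - baseline for v in levels.values() if len(v)]
        )
        p = signed_rank_p(diffs, alternative)
        res = IteratedTestResult(p, 1, np.array([p]), alternative, len(diffs))
        return baseline, res
    const = {
        s: [baseline] * len(stable_means.get(s, [])) for s in levels
        if len(stable_means.get(s, []))
    }
    res = iterated_wilcoxon(
        {s: v for s, v in levels.items() if s in const},
        const,
        n_iter=n_iter,
        alternative=alternative,
        rng=rng,
    )
    return baseline, res


def magnitude_delay_correlation(
    magnitudes: np.ndarray, delays: np.ndarray
) -> tuple[float, float]:
    """Pearson correlation between response delays and magnitudes."""
    m = np.asarray(magnitudes, float)
    d = np.asarray(delays, float)
    if len(m) < 3:
        raise ValueError("need at least 3 responding arousals")
    if np.std(m) == 0 or np.std(d) == 0:
        raise ValueError("zero variance in magnitudes or delays")
    rho, p = sps.pearsonr(d, m)
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# cohort-level report
# ---------------------------------------------------------------------------


@dataclass
class ReportConfig:
    n_iterations: int = 1000
    seed: int = 0
    alpha: float = ALPHA
    iterate_baseline: bool = True


def _grouped(df: pd.DataFrame, value_col: str) -> dict[str, GroupedMeasures]:
    """cause -> subject -> finite values of value_col."""
    out: dict[str, GroupedMeasures] = {}
    for (cause, subject), sub in df.groupby(["cause", "subject_id"]):
        vals = sub[value_col].dropna().tolist()
        if vals:
            out.setdefault(cause, {}).setdefault(subject, []).extend(vals)
    return out


def proportion_table(calls: pd.DataFrame) -> pd.DataFrame:
    """Per cause and characteristic: response and recovery proportions."""
    rows = []
    for (cause, kind), sub in calls.groupby(["cause", "kind"]):
        n = len(sub)
        n_resp = int(sub["response_present"].sum())
        with_resp = sub[sub["response_present"]]
        n_rec = int(with_resp["recovery_present"].sum())
        rows.append(
            {
                "cause": cause,
                "kind": kind,
                "n_arousals": n,
                "n_response": n_resp,
                "prop_response": n_resp / n if n else np.nan,
                "n_recovery": n_rec,
                "prop_recovery": n_rec / n_resp if n_resp else np.nan,
            }
        )
    return pd.DataFrame(rows).sort_values(["kind", "cause"]).reset_index(drop=True)


def relative_risk_table(calls: pd.DataFrame, outcome: str = "response") -> pd.DataFrame:
    """Pairwise relative risks of NOT detecting a response (or recovery)."""
    rows = []
    for kind, sub in calls.groupby("kind"):
        counts: dict[str, tuple[int, int]] = {}
        for cause, csub in sub.groupby("cause"):
            if outcome == "response":
                n = len(csub)
                x = int((~csub["response_present"]).sum())
            else:  # recovery among responders
                resp = csub[csub["response_present"]]
                n = len(resp)
                x = int((~resp["recovery_present"]).sum())
            if n > 0:
                counts[cause] = (x, n)
        for c1, c2 in itertools.permutations(sorted(counts), 2):
            x1, n1 = counts[c1]
            x2, n2 = counts[c2]
            try:
                rr = relative_risk(x1, n1, x2, n2)
            except ValueError:
                continue
            rows.append(
                {
                    "kind": kind,
                    "outcome": outcome,
                    "cause_row": c1,
                    "cause_col": c2,
                    "rr": rr.rr,
                    "ci99_low": rr.ci99[0],
                    "ci99_high": rr.ci99[1],
                    "significant": rr.significant,
                    "corrected": rr.corrected,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["kind", "outcome", "cause_row", "cause_col", "rr", "ci99_low",
                 "ci99_high", "significant", "corrected"],
    )


def pairwise_comparison_table(
    calls: pd.DataFrame,
    value_col: str,
    config: ReportConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Per-cause medians plus one-sided iterated signed-rank p-value matrices.

    The one-sided direction for each pair is taken from the sign of the
    median difference (the tested hypothesis is that the group with the
    larger median is shifted upward); the direction is recorded.
    """
    rows = []
    responders = calls[calls["response_present"]]
    for kind, sub in responders.groupby("kind"):
        groups = _grouped(sub, value_col)
        medians = {
            c: float(np.median(np.concatenate([np.asarray(v) for v in g.values()])))
            for c, g in groups.items()
        }
        for c1, c2 in itertools.combinations(sorted(groups), 2):
            alt = "greater" if medians[c1] >= medians[c2] else "less"
            try:
                res = iterated_wilcoxon(
                    groups[c1], groups[c2], n_iter=config.n_iterations,
                    alternative=alt, rng=rng,
                )
            except ValueError:
                logger.warning("%s %s: no paired support for %s vs %s",
                               kind, value_col, c1, c2)
                continue
            rows.append(
                {
                    "kind": kind,
                    "measure": value_col,
                    "cause_a": c1,
                    "cause_b": c2,
                    "median_a": medians[c1],
                    "median_b": medians[c2],
                    "alternative": alt,
                    "median_p": res.median_p,
                    "n_pairs": res.n_pairs,
                    "significant": res.median_p < config.alpha,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["kind", "measure", "cause_a", "cause_b", "median_a", "median_b",
                 "alternative", "median_p", "n_pairs", "significant"],
    )


def level_table(
    calls: pd.DataFrame,
    stable: pd.DataFrame,
    config: ReportConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Before/after response levels relative to the stable-sleep median."""
    rows = []
    responders = calls[calls["response_present"]]
    for kind, stable_col in (("frequency", "mean_frequency"), ("amplitude", "mean_amplitude")):
        stable_means: GroupedMeasures = {
            s: sub[stable_col].dropna().tolist()
            for s, sub in stable.groupby("subject_id")
        }
        if not any(stable_means.values()):
            logger.warning("no stable samples for %s levels", kind)
            continue
        sub = responders[responders["kind"] == kind]
        for which, col in (("before", "level_before"), ("after", "level_after")):
            for cause, csub in sub.groupby("cause"):
                levels = {
                    s: g[col].dropna().tolist() for s, g in csub.groupby("subject_id")
                }
                levels = {s: v for s, v in levels.items() if v}
                if not levels:
                    continue
                try:
                    baseline, res = baseline_compare(
                        levels, stable_means, n_iter=config.n_iterations,
                        rng=rng, iterate=config.iterate_baseline,
                    )
                except ValueError:
                    continue
                pooled = np.concatenate([np.asarray(v) for v in levels.values()])
                rows.append(
                    {
                        "kind": kind,
                        "level": which,
                        "cause": cause,
                        "median_level": float(np.median(pooled)),
                        "baseline": baseline,
                        "median_minus_baseline": float(np.median(pooled) - baseline),
                        "median_p": res.median_p,
                        "significant": res.median_p < config.alpha,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["kind", "level", "cause", "median_level", "baseline",
                 "median_minus_baseline", "median_p", "significant"],
    )


def correlation_table(calls: pd.DataFrame) -> pd.DataFrame:
    rows = []
    responders = calls[calls["response_present"]]
    for kind, sub in responders.groupby("kind"):
        mags = sub["magnitude"].to_numpy(float)
        delays = sub["delay"].to_numpy(float)
        try:
            rho, p = magnitude_delay_correlation(mags, delays)
        except ValueError as exc:
            logger.warning("correlation skipped for %s: %s", kind, exc)
            continue
        rows.append({"kind": kind, "n": len(sub), "rho": rho, "p": p})
    return pd.DataFrame(rows, columns=["kind", "n", "rho", "p"])


def build_report(
    calls: pd.DataFrame,
    stable: pd.DataFrame,
    config: ReportConfig | None = None,
) -> dict[str, pd.DataFrame]:
    """Assemble the cohort-level report tables.

    ``calls`` is the per-arousal response table (one row per arousal and
    characteristic, columns subject_id, cause, kind, response_present,
    magnitude, delay, recovery_present, level_before, level_after);
    ``stable`` is the stable-sleep sample table.
    """
    config = config or ReportConfig()
    rng = np.random.default_rng(config.seed)
    report = {
        "proportions": proportion_table(calls),
        "relative_risk_response": relative_risk_table(calls, "response"),
        "relative_risk_recovery": relative_risk_table(calls, "recovery"),
        "magnitude_comparisons": pairwise_comparison_table(calls, "magnitude", config, rng),
        "delay_comparisons": pairwise_comparison_table(calls, "delay", config, rng),
        "levels_vs_baseline": level_table(calls, stable, config, rng),
        "magnitude_delay_correlation": correlation_table(calls),
    }
    return report
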