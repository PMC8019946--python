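"""Statistics and behavioral scoring.

One-sided Wilcoxon signed-rank (the workhorse group test), Spearman and
Pearson correlations, content-questionnaire scoring, and the rule-based
conversion of retrospective name-detection reports into per-condition
estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class WilcoxonResult:
    z: float
    p: float
    w: float  # signed-rank statistic (sum of positive ranks)
    n: int  # pairs after dropping zero differences
    alternative: str


def wilcoxon_signed_rank(
    x: np.ndarray, y: np.ndarray | None = None, alternative: str = "greater"
) -> WilcoxonResult:
    """Paired signed-rank test on x - y (or on x directly when y is None).

    Zero differences are dropped (Wilcoxon's rule), ties mid-ranked. The
    Z statistic uses the normal approximation with continuity correction;
    the p-value is exact for n <= 25 without ties, asymptotic otherwise.
    """
    d = np.asarray(x, float) if y is None else np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all paired differences are zero")
    approx = sps.wilcoxon(
        d, alternative=alternative, zero_method="wilcox", correction=True, method="approx"
    )
    ranks = sps.rankdata(np.abs(d))
    has_ties = np.unique(np.abs(d)).size < d.size
    if d.size <= 25 and not has_ties:
        exact = sps.wilcoxon(d, alternative=alternative, zero_method="wilcox", method="exact")
        p = float(exact.pvalue)
    else:
        p = float(approx.pvalue)
    w_plus = float(ranks[d > 0].sum())
    return WilcoxonResult(
        z=float(approx.zstatistic), p=p, w=w_plus, n=int(d.size), alternative=alternative
    )


def rank_correlations(
    x: np.ndarray, y: np.ndarray, method: str = "spearman", alternative: str = "two-sided"
) -> tuple[float, float]:
    """Spearman rho or Pearson r with the stated-direction p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3 or y.size != x.size:
        raise ValueError("need n >= 3 equal-length samples")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the inputs")
    if method == "spearman":
        res = sps.spearmanr(x, y, alternative=alternative)
        return float(res.statistic), float(res.pvalue)
    if method == "pearson":
        res = sps.pearsonr(x, y, alternative=alternative)
        return float(res.statistic), float(res.pvalue)
    raise ValueError("method must be 'spearman' or 'pearson'")


def score_content_questionnaire(answers) -> float:
    """Percent correct; 'I don't know' counts as incorrect.

    Accepts booleans or the strings 'correct' / 'incorrect' / 'dont_know'.
    """
    answers = list(answers)
    if not answers:
        raise ValueError("need at least one question")
    correct = 0
    for a in answers:
        if isinstance(a, str):
            if a not in {"correct", "incorrect", "dont_know"}:
                raise ValueError(f"unknown answer {a!r}")
            correct += a == "correct"
        else:
            correct += bool(a)
    return 100.0 * correct / len(answers)


@dataclass
class RetrospectiveReport:
    """End-of-experiment report on noticing one's name.

    ``overall_estimate`` (1-10 names per block) is asked when the name was
    noticed; the per-condition estimates (0-10 each) only when a loudness
    difference between conditions was noticed as well.
    """

    noticed_name: bool
    noticed_condition_difference: bool = False
    overall_estimate: int | None = None
    higher_estimate: int | None = None
    lower_estimate: int | None = None

    def validate(self) -> None:
        if not self.noticed_name:
            if self.noticed_condition_difference:
                raise ValueError("cannot notice a condition difference without the name")
            return
        if self.noticed_condition_difference:
            for v, lo in ((self.higher_estimate, 0), (self.lower_estimate, 0)):
                if v is None or not lo <= v <= 10:
                    raise ValueError("per-condition estimates must be on the 0-10 scale")
        else:
            if self.overall_estimate is None or not 1 <= self.overall_estimate <= 10:
                raise ValueError("overall estimate must be on the 1-10 scale")


def score_retrospective(report: RetrospectiveReport) -> tuple[float, float, float]:
    """(higher, lower, condition-independent) detected-name estimates.

    Name not noticed -> both zero. Condition difference not noticed ->
    both set to the overall estimate. Otherwise the per-condition values
    are used directly. The condition-independent value is their mean.
    """
    report.validate()
    if not report.noticed_name:
        higher = lower = 0.0
    elif not report.noticed_condition_difference:
        higher = lower = float(report.overall_estimate)
    else:
        higher, lower = float(report.higher_estimate), float(report.lower_estimate)
    return higher, lower, (higher + lower) / 2.0


def detected_names_percent(estimate: float, names_per_block: int = 10) -> float:
    """Map a 0-10 per-block estimate onto percent of the 10 names detected."""
    return 100.0 * estimate / names_per_block
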