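"""Agreement and diagnostic-accuracy statistics for the clinical validation.

The clinical question is whether diagnoses made from de-identified
(reconstructed) videos agree with diagnoses made from the original videos.
This module provides: majority-rule aggregation over raters, Cohen's kappa
with Landis-Koch interpretation labels, the McNemar test for paired
diagnostic accuracy, and the kappa-based sample-size calculation used to
plan such a study.

Diagnosis tables are tidy DataFrames with columns
``patient, eye, disease, rater, source, call`` (``source`` in
{original, masked}; ``call`` in {abnormal, normal}) plus an optional ground
truth table keyed by (patient, eye, disease).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil, sqrt
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

from .errors import ContractViolationError, InsufficientDataError

LANDIS_KOCH = (
    (0.0, "poor"),
    (0.20, "slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.0, "almost perfect"),
)


def landis_koch_label(kappa: float) -> str:
    """Magnitude label for a kappa value (<=0 poor ... >0.80 almost perfect)."""
    if kappa <= 0:
        return "poor"
    for cut, label in LANDIS_KOCH[1:]:
        if kappa <= cut + 1e-12:
            return label
    return "almost perfect"


@dataclass
class AgreementResult:
    kappa: float
    p_observed: float
    p_expected: float
    label: str
    n: int


def majority_call(calls: Sequence[str]):
    """Majority vote over an odd number of rater calls."""
    calls = list(calls)
    if len(calls) % 2 == 0:
        raise ContractViolationError(
            f"majority rule needs an odd number of raters, got {len(calls)}"
        )
    values, counts = np.unique(np.asarray(calls, dtype=object), return_counts=True)
    return values[np.argmax(counts)]


def cohens_kappa(calls_a: Sequence, calls_b: Sequence) -> AgreementResult:
    """Cohen's kappa between two paired call sequences.

    kappa = (p_o - p_e) / (1 - p_e) with p_o the observed agreement and p_e
    the chance agreement from the marginal call frequencies.
    """
    a = np.asarray(list(calls_a), dtype=object)
    b = np.asarray(list(calls_b), dtype=object)
    if a.shape != b.shape or a.size == 0:
        raise InsufficientDataError("need >= 1 paired call")
    n = a.size
    cats = np.unique(np.concatenate([a, b]))
    p_o = float(np.mean(a == b))
    p_e = float(
        sum(np.mean(a == c) * np.mean(b == c) for c in cats)
    )
    if p_e >= 1.0:
        raise ContractViolationError(
            "both raters are constant; chance agreement is 1 and kappa undefined"
        )
    kappa = (p_o - p_e) / (1 - p_e)
    return AgreementResult(kappa, p_o, p_e, landis_koch_label(kappa), n)


@dataclass
class McNemarResult:
    statistic: float
    p_value: float
    method: str  # "exact" or "chi2"
    b: int
    c: int


def mcnemar_test(b: int, c: int, exact_threshold: int = 25) -> McNemarResult:
    """Two-sided McNemar test from the discordant-pair counts.

    Exact binomial version for small discordant totals (b + c below the
    threshold), chi-square without continuity correction otherwise.
    ``b = c = 0`` gives p = 1.
    """
    if b < 0 or c < 0:
        raise ContractViolationError("discordant counts must be >= 0")
    if b + c == 0:
        return McNemarResult(0.0, 1.0, "exact", b, c)
    table = [[0, b], [c, 0]]
    exact = (b + c) < exact_threshold
    res = _sm_mcnemar(table, exact=exact, correction=False)
    return McNemarResult(
        float(res.statistic), float(min(1.0, res.pvalue)),
        "exact" if exact else "chi2", b, c,
    )


def kappa_sample_size(
    k0: float,
    k1: float,
    rate1: float,
    rate2: float,
    alpha: float = 0.05,
    power: float = 0.8,
    twosided: bool = False,
) -> int:
    """Minimum n to distinguish kappa = k1 from kappa = k0 between two raters.

    Follows the Cantor construction: with the raters' positive-call rates
    assumed known, the chance agreement p_e is a design constant, so testing
    kappa reduces to a one-sample normal test on the observed agreement
    p_o = p_e + kappa (1 - p_e), with variance factor
    Q(kappa) = p_o (1 - p_o) / (1 - p_e)^2.  The returned n is

        ceil( ((z_a sqrt(Q(k0)) + z_b sqrt(Q(k1))) / (k1 - k0))^2 )

    This mirrors the convention of the widely used R routine for this
    calculation, including its critical value: ``z_a`` is taken at
    ``1 - alpha/2`` (halved once more when ``twosided``), so ``alpha`` acts
    as a symmetric two-tailed error budget even for the one-sided design.
    With k0 = 0.6, k1 = 0.85, rates 0.3/0.7, alpha = 0.025, power = 0.9 the
    routine returns the standard design value 82.
    """
    for name, r in (("rate1", rate1), ("rate2", rate2)):
        if not 0 < r < 1:
            raise ContractViolationError(f"{name} must be in (0, 1)")
    if k1 <= k0:
        raise ContractViolationError("require k1 > k0")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ContractViolationError("alpha and power must be in (0, 1)")
    if twosided:
        alpha = alpha / 2
    p_e = rate1 * rate2 + (1 - rate1) * (1 - rate2)

    def Q(kappa):
        p_o = p_e + kappa * (1 - p_e)
        return p_o * (1 - p_o) / (1 - p_e) ** 2

    z_a = norm.ppf(1 - alpha / 2)
    z_b = norm.ppf(power)
    n = ((z_a * sqrt(Q(k0)) + z_b * sqrt(Q(k1))) / (k1 - k0)) ** 2
    return ceil(n)


def kappa_test_power(
    n: int,
    k0: float,
    k1: float,
    rate1: float,
    rate2: float,
    alpha: float = 0.05,
    twosided: bool = False,
) -> float:
    """Normal-approximation power of the design tested by kappa_sample_size."""
    if twosided:
        alpha = alpha / 2
    p_e = rate1 * rate2 + (1 - rate1) * (1 - rate2)
    po0 = p_e + k0 * (1 - p_e)
    po1 = p_e + k1 * (1 - p_e)
    z_a = norm.ppf(1 - alpha / 2)
    crit = po0 + z_a * sqrt(po0 * (1 - po0) / n)
    return float(1 - norm.cdf((crit - po1) / sqrt(po1 * (1 - po1) / n)))


# ---------------------------------------------------------------------------
# diagnosis-table pipeline


REQUIRED_COLUMNS = ("patient", "eye", "disease", "rater", "source", "call")


def validate_diagnosis_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise ContractViolationError(f"diagnosis table missing columns: {sorted(missing)}")
    dup = df.duplicated(subset=["patient", "eye", "disease", "rater", "source"])
    if dup.any():
        raise ContractViolationError(
            f"duplicate (patient, eye, disease, rater, source) rows at {list(df.index[dup])[:5]}"
        )
    bad = ~df["call"].isin(["abnormal", "normal"])
    if bad.any():
        raise ContractViolationError("calls must be 'abnormal' or 'normal'")
    return df


def majority_table(df: pd.DataFrame) -> pd.DataFrame:
    """Collapse rater calls to a majority call per (patient, eye, disease, source)."""
    validate_diagnosis_table(df)
    return (
        df.groupby(["patient", "eye", "disease", "source"])["call"]
        .agg(lambda s: majority_call(list(s)))
        .reset_index()
    )


def agreement_by_disease_eye(df: pd.DataFrame) -> pd.DataFrame:
    """Cohen's kappa between sources per (disease, eye) on majority calls."""
    maj = majority_table(df)
    wide = maj.pivot_table(
        index=["patient", "eye", "disease"], columns="source", values="call",
        aggfunc="first",
    ).reset_index()
    sources = [c for c in wide.columns if c not in ("patient", "eye", "disease")]
    if len(sources) != 2:
        raise ContractViolationError(
            f"need exactly two sources for agreement, got {sources}"
        )
    rows = []
    for (disease, eye), grp in wide.groupby(["disease", "eye"]):
        res = cohens_kappa(grp[sources[0]], grp[sources[1]])
        rows.append(
            {"disease": disease, "eye": eye, "kappa": res.kappa,
             "p_observed": res.p_observed, "p_expected": res.p_expected,
             "label": res.label, "n": res.n}
        )
    return pd.DataFrame(rows)


def accuracy_comparison(
    df: pd.DataFrame, truth: pd.DataFrame
) -> pd.DataFrame:
    """Accuracy of each source against ground truth + McNemar comparison.

    ``truth`` columns: patient, eye, disease, call.  Per (disease, eye):
    accuracy of both sources' majority calls and the two-sided McNemar
    p-value on the discordant correctness pairs.
    """
    maj = majority_table(df)
    merged = maj.merge(
        truth.rename(columns={"call": "truth"}),
        on=["patient", "eye", "disease"], how="inner",
    )
    merged["correct"] = merged["call"] == merged["truth"]
    wide = merged.pivot_table(
        index=["patient", "eye", "disease"], columns="source", values="correct",
        aggfunc="first",
    ).reset_index()
    sources = [c for c in wide.columns if c not in ("patient", "eye", "disease")]
    rows = []
    for (disease, eye), grp in wide.groupby(["disease", "eye"]):
        a, bcol = grp[sources[0]].astype(bool), grp[sources[1]].astype(bool)
        b = int((a & ~bcol).sum())
        c = int((~a & bcol).sum())
        res = mcnemar_test(b, c)
        rows.append(
            {"disease": disease, "eye": eye,
             f"accuracy_{sources[0]}": float(a.mean()),
             f"accuracy_{sources[1]}": float(bcol.mean()),
             "mcnemar_p": res.p_value, "method": res.method, "b": b, "c": c,
             "n": len(grp)}
        )
    return pd.DataFrame(rows)
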