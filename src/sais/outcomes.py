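"""Association between video-derived skill probabilities and patient outcomes.

A binary postoperative outcome Y (e.g. urinary continence recovery at three
months) is regressed on the model's high-skill probability Z1, adjusting for
surgeon caseload Z2 and patient age Z3:

    Y = sigma(b0 + b1*Z1 + b2*Z2 + b3*Z3)

The quantity of interest is the adjusted odds ratio exp(b1) comparing a
certainly-high-skill to a certainly-low-skill assessment, with a Wald 95%
confidence interval.  Two variants mirror the per-sample and per-case
analyses: the latter first averages Z1 over all video samples of a surgical
case.  Per-sample fits do not adjust standard errors for within-case
correlation; that is a documented limitation of the per-sample variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["OutcomeFit", "SeparationError", "aggregate_case", "fit_outcome_model"]

REQUIRED = ["case_id", "Z1", "Z2", "Z3", "Y"]


class SeparationError(RuntimeError):
    """The outcome is perfectly separated; coefficients are unbounded."""


@dataclass(frozen=True)
class OutcomeFit:
    """Fitted logistic model: coefficients, odds ratio and Wald 95% CI."""

    b0: float
    b1: float
    b2: float
    b3: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    variant: str

    def as_dict(self) -> dict:
        return {
            "b0": self.b0, "b1": self.b1, "b2": self.b2, "b3": self.b3,
            "odds_ratio": self.odds_ratio,
            "ci95": [self.ci_low, self.ci_high],
            "p_value": self.p_value, "n": self.n, "variant": self.variant,
        }


def _validate(records: pd.DataFrame) -> pd.DataFrame:
    missing = set(REQUIRED) - set(records.columns)
    if missing:
        raise ValueError(f"outcome records missing columns: {sorted(missing)}")
    df = records[REQUIRED].copy()
    if ((df["Z1"] < 0) | (df["Z1"] > 1)).any():
        raise ValueError("Z1 must lie in [0, 1]")
    if (df["Z2"] < 0).any():
        raise ValueError("Z2 (caseload) must be >= 0")
    if not set(df["Y"].unique()) <= {0, 1}:
        raise ValueError("Y must be binary 0/1")
    return df


def aggregate_case(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-sample records to one record per surgical case.

    Z1 is replaced by its within-case mean; Z2, Z3 and Y must be constant
    within a case (they describe the case, not the sample).
    """
    df = _validate(records)
    for col in ("Z2", "Z3", "Y"):
        conflicting = df.groupby("case_id")[col].nunique()
        bad = conflicting[conflicting > 1]
        if len(bad):
            raise ValueError(f"{col} differs within case(s) {list(bad.index)[:5]}")
    out = df.groupby("case_id", as_index=False).agg(
        Z1=("Z1", "mean"), Z2=("Z2", "first"), Z3=("Z3", "first"), Y=("Y", "first")
    )
    return out[REQUIRED]


def fit_outcome_model(records: pd.DataFrame, variant: str = "per-sample") -> OutcomeFit:
    """Maximum-likelihood logistic fit of Y on (Z1, Z2, Z3) with intercept.

    Raises :class:`SeparationError` when the classes are perfectly separated
    (the odds ratio is then unbounded and no estimate is reported).
    """
    df = _validate(records)
    if variant == "per-case":
        df = aggregate_case(df)
    if len(df) <= 4:
        raise ValueError("need more than 4 records to fit four coefficients")
    y = df["Y"].to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")
    X = sm.add_constant(df[["Z1", "Z2", "Z3"]].to_numpy(dtype=float))
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception as exc:
        # statsmodels reports perfect separation either explicitly or as a
        # singular Hessian once the Newton iterates diverge
        if ("separation" in str(exc).lower()
                or "singular" in str(exc).lower()
                or type(exc).__name__ == "PerfectSeparationError"):
            raise SeparationError(str(exc)) from exc
        raise
    params = res.params
    if not np.all(np.isfinite(res.bse)) or np.any(np.abs(params) > 50):
        raise SeparationError("unbounded coefficients: outcome is (quasi-)separated")
    ci = res.conf_int()[1]  # row for Z1
    return OutcomeFit(
        b0=float(params[0]), b1=float(params[1]),
        b2=float(params[2]), b3=float(params[3]),
        odds_ratio=float(np.exp(params[1])),
        ci_low=float(np.exp(ci[0])), ci_high=float(np.exp(ci[1])),
        p_value=float(res.pvalues[1]), n=len(df), variant=variant,
    )
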