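"""Survival modelling: Kaplan-Meier estimation, log-rank tests, and Cox
proportional-hazards models with stepwise backward elimination.

The module follows a Model/Results layout: :class:`KaplanMeier` and
:class:`CoxModel` are built from a cohort DataFrame and their ``fit``
methods return result objects (:class:`KMResult`, :class:`CoxResult`)
carrying estimates, 95% confidence intervals, Wald p-values and — for the
multivariate model — the full elimination trace. Partial-likelihood ties
are handled with the Efron approximation (the lifelines default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test

from .errors import ContractViolation, UndefinedResultError, ValidationError

#: hazard-ratio sentinel for perfectly separated binary covariates
DIVERGED = float("inf")


@dataclass
class KMCurve:
    """One product-limit curve: right-continuous step function S(t)."""

    label: str
    times: np.ndarray            # event/censoring times, ascending, starts at 0
    survival: np.ndarray         # S(t) at each time
    at_risk: np.ndarray          # number at risk entering each time
    median_years: float | None   # first time S(t) <= 0.5, None if never reached

    def survival_at(self, t: float) -> float:
        """Step-function lookup S(t); beyond the last observed time the last
        value is carried forward with an extrapolation warning."""
        if t < 0:
            raise ValidationError("time must be non-negative")
        if t > self.times[-1]:
            warnings.warn(
                f"survival_at({t}) extrapolates beyond the last observed "
                f"time {self.times[-1]:.3g}",
                stacklevel=2,
            )
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[max(idx, 0)])


def survival_at_years(curve: KMCurve, t: float) -> float:
    """Kaplan-Meier survival probability at ``t`` years."""
    return curve.survival_at(t)


@dataclass
class KMResult:
    curves: dict[str, KMCurve]
    logrank_p: float | None
    n: int
    n_events: int

    def summary(self) -> pd.DataFrame:
        rows = [
            {
                "group": c.label,
                "n": int(c.at_risk[0]),
                "median_years": c.median_years,
                "S(5y)": c.survival_at(5.0) if c.times[-1] >= 5.0 else np.nan,
            }
            for c in self.curves.values()
        ]
        df = pd.DataFrame(rows)
        df.attrs["logrank_p"] = self.logrank_p
        return df


class KaplanMeier:
    """Product-limit estimator, optionally stratified by a grouping column."""

    def __init__(
        self,
        data: pd.DataFrame,
        duration_col: str = "time_years",
        event_col: str = "event",
        group_col: str | None = None,
    ) -> None:
        cols = [duration_col, event_col] + ([group_col] if group_col else [])
        self.data = data[cols].dropna().copy()
        self.duration_col = duration_col
        self.event_col = event_col
        self.group_col = group_col
        if (self.data[duration_col] <= 0).any():
            raise ValidationError("survival times must be positive")

    def fit(self) -> KMResult:
        df = self.data
        if df[self.event_col].sum() == 0 and self.group_col is not None:
            raise UndefinedResultError("log-rank undefined: no events in any group")
        groups = (
            {str(g): sub for g, sub in df.groupby(self.group_col)}
            if self.group_col
            else {"all": df}
        )
        curves = {}
        for label, sub in groups.items():
            kmf = KaplanMeierFitter()
            kmf.fit(sub[self.duration_col], sub[self.event_col], label=label)
            sf = kmf.survival_function_
            times = sf.index.to_numpy(dtype=float)
            surv = sf[label].to_numpy(dtype=float)
            at_risk = kmf.event_table["at_risk"].reindex(sf.index).to_numpy(dtype=float)
            med = kmf.median_survival_time_
            curves[label] = KMCurve(
                label=label,
                times=times,
                survival=surv,
                at_risk=at_risk,
                median_years=None if np.isinf(med) else float(med),
            )
        logrank_p = None
        if self.group_col and len(groups) > 1:
            res = multivariate_logrank_test(
                df[self.duration_col], df[self.group_col], df[self.event_col]
            )
            logrank_p = float(res.p_value)
        return KMResult(
            curves=curves,
            logrank_p=logrank_p,
            n=len(df),
            n_events=int(df[self.event_col].sum()),
        )


def km_estimate(
    data: pd.DataFrame,
    duration_col: str = "time_years",
    event_col: str = "event",
    group_col: str | None = None,
) -> KMResult:
    """Convenience wrapper: ``KaplanMeier(...).fit()``."""
    return KaplanMeier(data, duration_col, event_col, group_col).fit()


@dataclass(frozen=True)
class CoxTerm:
    name: str
    hazard_ratio: float
    ci95_low: float
    ci95_high: float
    wald_p: float
    coef: float
    se: float
    diverged: bool = False


@dataclass
class CoxResult:
    """A fitted proportional-hazards model plus, for the multivariate
    backward-elimination fit, the ordered trace of dropped terms."""

    terms: list[CoxTerm]
    n_patients: int
    n_events: int
    endpoint: str = ""
    cohort: str = ""
    elimination_trace: list[tuple[int, str, float]] = field(default_factory=list)
    candidate_order: list[str] = field(default_factory=list)

    def term(self, name: str) -> CoxTerm | None:
        for t in self.terms:
            if t.name == name:
                return t
        return None

    def hazard_ratio(self, name: str) -> float | None:
        t = self.term(name)
        return t.hazard_ratio if t else None

    def summary(self) -> pd.DataFrame:
        df = pd.DataFrame(
            [
                {
                    "term": t.name,
                    "HR": t.hazard_ratio,
                    "ci95_low": t.ci95_low,
                    "ci95_high": t.ci95_high,
                    "p": t.wald_p,
                    "coef": t.coef,
                    "se": t.se,
                    "diverged": t.diverged,
                }
                for t in self.terms
            ]
        )
        df.attrs["n_patients"] = self.n_patients
        df.attrs["n_events"] = self.n_events
        df.attrs["elimination_trace"] = list(self.elimination_trace)
        return df

    def to_dict(self) -> dict:
        return {
            "endpoint": self.endpoint,
            "cohort": self.cohort,
            "n_patients": self.n_patients,
            "n_events": self.n_events,
            "terms": [
                {
                    "name": t.name,
                    "hazard_ratio": t.hazard_ratio,
                    "ci95_low": t.ci95_low,
                    "ci95_high": t.ci95_high,
                    "wald_p": t.wald_p,
                }
                for t in self.terms
            ],
            "elimination_trace": [
                {"step": s, "dropped": d, "p_at_drop": p}
                for s, d, p in self.elimination_trace
            ],
        }


def _terms_from_fitter(cph: CoxPHFitter) -> list[CoxTerm]:
    s = cph.summary
    return [
        CoxTerm(
            name=str(idx),
            hazard_ratio=float(row["exp(coef)"]),
            ci95_low=float(np.exp(row["coef lower 95%"])),
            ci95_high=float(np.exp(row["coef upper 95%"])),
            wald_p=float(row["p"]),
            coef=float(row["coef"]),
            se=float(row["se(coef)"]),
        )
        for idx, row in s.iterrows()
    ]


class CoxModel:
    """Cox proportional-hazards model over a cohort DataFrame.

    ``features`` are covariate columns (binary flags or continuous values);
    complete cases across all features are used (the model's n therefore
    shrinks with the candidate set, as in any multivariate analysis of a
    partially observed cohort).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        duration_col: str = "time_years",
        event_col: str = "event",
        features: Sequence[str] = (),
        endpoint: str = "",
        cohort: str = "",
    ) -> None:
        if not features:
            raise ContractViolation("at least one candidate feature is required")
        self.features = list(features)
        cols = [duration_col, event_col] + self.features
        df = data[cols].dropna().copy()
        for f in self.features:
            df[f] = df[f].astype(float)
        self.data = df
        self.duration_col = duration_col
        self.event_col = event_col
        self.endpoint = endpoint
        self.cohort = cohort

    def _check_separation(self, features: Sequence[str]) -> list[str]:
        """Binary covariates with zero events on one side cannot be
        estimated (the partial likelihood diverges)."""
        diverged = []
        ev = self.data[self.event_col].astype(bool)
        for f in features:
            x = self.data[f]
            if set(np.unique(x)) <= {0.0, 1.0}:
                if ev[x == 1].sum() == 0 or ev[x == 0].sum() == 0:
                    diverged.append(f)
        return diverged

    def _fit_once(self, features: Sequence[str]) -> CoxPHFitter:
        cph = CoxPHFitter()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(
                    self.data[[self.duration_col, self.event_col] + list(features)],
                    duration_col=self.duration_col,
                    event_col=self.event_col,
                )
        except ConvergenceError as exc:
            bad = self._check_separation(features)
            raise ConvergenceError(
                f"Cox fit failed to converge; suspected separation in: {bad or features}"
            ) from exc
        return cph

    def fit(self) -> CoxResult:
        """Fit with all features (no elimination)."""
        diverged = self._check_separation(self.features)
        usable = [f for f in self.features if f not in diverged]
        terms: list[CoxTerm] = []
        if usable:
            cph = self._fit_once(usable)
            terms = _terms_from_fitter(cph)
        for f in diverged:
            x = self.data[f]
            ev = self.data[self.event_col].astype(bool)
            hr = DIVERGED if ev[x == 0].sum() == 0 else 0.0
            terms.append(
                CoxTerm(
                    name=f, hazard_ratio=hr, ci95_low=np.nan, ci95_high=np.nan,
                    wald_p=np.nan, coef=np.log(hr) if hr > 0 else -np.inf,
                    se=np.nan, diverged=True,
                )
            )
        return CoxResult(
            terms=terms,
            n_patients=len(self.data),
            n_events=int(self.data[self.event_col].sum()),
            endpoint=self.endpoint,
            cohort=self.cohort,
            candidate_order=list(self.features),
        )

    def fit_backward(self, alpha: float = 0.05) -> CoxResult:
        """Stepwise backward elimination on the Wald p-value.

        At each step the term with the largest p >= ``alpha`` is dropped
        (ties broken by earliest position in the candidate order) and the
        model refit, until every remaining term has p < ``alpha`` or no
        terms remain. The trace records every drop.
        """
        current = list(self.features)
        trace: list[tuple[int, str, float]] = []
        step = 0
        terms: list[CoxTerm] = []
        while current:
            cph = self._fit_once(current)
            terms = _terms_from_fitter(cph)
            by_name = {t.name: t for t in terms}
            worst_name, worst_p = None, -1.0
            for name in current:  # candidate order is the tie-break
                p = by_name[name].wald_p
                if p > worst_p:
                    worst_name, worst_p = name, p
            if worst_p >= alpha:
                step += 1
                trace.append((step, worst_name, float(worst_p)))
                current.remove(worst_name)
                terms = []
            else:
                break
        return CoxResult(
            terms=terms,
            n_patients=len(self.data),
            n_events=int(self.data[self.event_col].sum()),
            endpoint=self.endpoint,
            cohort=self.cohort,
            elimination_trace=trace,
            candidate_order=list(self.features),
        )


def cox_univariate(
    data: pd.DataFrame,
    feature: str,
    duration_col: str = "time_years",
    event_col: str = "event",
    **kwargs,
) -> CoxResult:
    """Single-covariate Cox screen (complete cases for that covariate)."""
    return CoxModel(
        data, duration_col, event_col, features=[feature], **kwargs
    ).fit()


def cox_backward_eliminate(
    data: pd.DataFrame,
    candidate_features: Sequence[str],
    duration_col: str = "time_years",
    event_col: str = "event",
    alpha: float = 0.05,
    **kwargs,
) -> CoxResult:
    """Multivariate Cox with stepwise backward elimination at ``alpha``."""
    return CoxModel(
        data, duration_col, event_col, features=candidate_features, **kwargs
    ).fit_backward(alpha=alpha)


def km_table(result: KMResult) -> pd.DataFrame:
    """Long-format KM table (group, time, survival, at_risk) for export."""
    rows = []
    for label, c in result.curves.items():
        for t, s, r in zip(c.times, c.survival, c.at_risk):
            rows.append({"group": label, "time": t, "survival": s, "at_risk": r})
    return pd.DataFrame(rows)


def plot_km(result: KMResult, ax=None, title: str = ""):
    """Step plot of the fitted curves (requires matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for label, c in result.curves.items():
        ax.step(c.times, c.survival, where="post", label=label)
    ax.set_xlabel("years")
    ax.set_ylabel("S(t)")
    ax.set_ylim(0, 1.02)
    ax.legend()
    if title:
        ax.set_title(title)
    return ax
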