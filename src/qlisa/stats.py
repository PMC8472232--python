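"""Assay-level statistics: standard curves, LOD, CVs, crossover testing.

The statistic flowing in from image quantification is RFU/Bead Area per
detection band.  This module turns replicate band measurements into the
quantities an assay developer reports:

* a fitted standard curve (four-parameter logistic by default, linear in
  log-concentration as a fallback), constrained to be monotone
  non-decreasing;
* the limit of detection, defined as the blank mean plus three standard
  deviations (blank n = 10 by convention), converted to concentration
  units through the inverse curve;
* intra-assay CV (sample sd / mean of same-day replicates, n = 3 by
  convention) and inter-assay CV (mean of the daily CVs across days);
* a two-sample two-tailed t-test used to ask whether bead carryover into
  an upstream band generates a false-positive signal;
* method comparison of a new assay against a reference assay (OLS trend
  plus mean bias against the identity line).
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats as sps

__all__ = [
    "StandardCurve",
    "LodResult",
    "InverseResult",
    "RangeStatus",
    "CurveFitError",
    "fit_standard_curve",
    "inverse_concentration",
    "lod",
    "intra_assay_cv",
    "inter_assay_cv",
    "crossover_test",
    "method_comparison",
    "MethodComparison",
]


class CurveFitError(RuntimeError):
    """The standard-curve fit failed or produced a non-monotone response."""


class RangeStatus(str, enum.Enum):
    OK = "ok"
    BELOW_RANGE = "below_range"
    ABOVE_RANGE = "above_range"


@dataclass(frozen=True)
class InverseResult:
    """Back-calculated concentration with an in/out-of-range status."""

    concentration: float  # NaN when out of range
    status: RangeStatus

    def __float__(self) -> float:
        return self.concentration


@dataclass
class StandardCurve:
    """Fitted concentration–response relation for one analyte.

    ``model`` is ``"four_parameter_logistic"`` with parameters
    (a, b, c0, d): r(c) = d + (a - d) / (1 + (c / c0)^b), where a is the
    zero-concentration asymptote, d the saturation asymptote, c0 the
    inflection concentration and b > 0 the slope factor; or
    ``"linear_log"`` with parameters (p0, p1): r = p0 + p1 log10(c).
    """

    model: str
    params: dict[str, float]
    concentrations: np.ndarray
    responses: np.ndarray
    sems: np.ndarray | None
    residual_sd: float

    def predict(self, concentration) -> np.ndarray | float:
        c = np.asarray(concentration, dtype=float)
        if self.model == "four_parameter_logistic":
            a, b, c0, d = (self.params[k] for k in "a b c0 d".split())
            r = np.where(c > 0, d + (a - d) / (1.0 + (c / np.where(c > 0, c0, 1.0)) ** b), a)
        else:
            p0, p1 = self.params["p0"], self.params["p1"]
            r = p0 + p1 * np.log10(c)
        return float(r) if np.isscalar(concentration) else r

    @property
    def lower_asymptote(self) -> float:
        if self.model == "four_parameter_logistic":
            return self.params["a"]
        return float(self.predict(float(self.concentrations[self.concentrations > 0].min())))

    @property
    def upper_asymptote(self) -> float:
        if self.model == "four_parameter_logistic":
            return self.params["d"]
        return float(self.predict(float(self.concentrations.max())))


def _fit_4pl(conc: np.ndarray, resp: np.ndarray) -> tuple[dict[str, float], float]:
    def model(c, a, b, c0, d):
        out = np.where(
            c > 0, d + (a - d) / (1.0 + (np.where(c > 0, c, 1.0) / c0) ** b), a
        )
        return out

    a0 = float(resp.min())
    d0 = float(resp.max())
    pos = conc[conc > 0]
    c0_0 = float(np.exp(np.mean(np.log(pos)))) if pos.size else 1.0
    p0 = [a0, 1.0, c0_0, d0 * 1.05 + 1e-9]
    bounds = (
        [-np.inf, 1e-6, 1e-12, -np.inf],
        [np.inf, 50.0, np.inf, np.inf],
    )
    try:
        popt, _ = optimize.curve_fit(
            model, conc, resp, p0=p0, bounds=bounds, maxfev=20000
        )
    except (RuntimeError, ValueError) as exc:
        raise CurveFitError(
            f"4PL fit did not converge (p0={p0}, bounds={bounds}): {exc}"
        ) from exc
    params = dict(zip("a b c0 d".split(), map(float, popt)))
    resid = resp - model(conc, *popt)
    dof = max(len(conc) - 4, 1)
    return params, float(np.sqrt((resid**2).sum() / dof))


def fit_standard_curve(
    concentrations: Sequence[float],
    responses: Sequence[float],
    model: str = "four_parameter_logistic",
    sems: Sequence[float] | None = None,
) -> StandardCurve:
    """Least-squares monotone standard-curve fit.

    4PL needs >= 4 distinct concentrations (including 0); linear_log needs
    >= 2 strictly positive ones.  A fit whose response decreases with
    concentration is refused.
    """
    conc = np.asarray(concentrations, dtype=float)
    resp = np.asarray(responses, dtype=float)
    if conc.shape != resp.shape:
        raise ValueError("concentrations and responses differ in length")
    if np.any(conc < 0):
        raise ValueError("concentrations must be non-negative")

    if model == "four_parameter_logistic":
        if len(np.unique(conc)) < 4:
            raise ValueError("4PL fit needs >= 4 distinct concentrations")
        params, resid_sd = _fit_4pl(conc, resp)
        if params["d"] <= params["a"]:
            raise CurveFitError(
                "fitted response is non-increasing (d <= a); the data do not "
                "support a monotone increasing standard curve"
            )
    elif model == "linear_log":
        pos = conc > 0
        if pos.sum() < 2:
            raise ValueError("linear_log fit needs >= 2 positive concentrations")
        p1, p0 = np.polyfit(np.log10(conc[pos]), resp[pos], 1)
        if p1 <= 0:
            raise CurveFitError("fitted log-linear slope is non-positive")
        pred = p0 + p1 * np.log10(conc[pos])
        resid = resp[pos] - pred
        dof = max(pos.sum() - 2, 1)
        params, resid_sd = {"p0": float(p0), "p1": float(p1)}, float(
            np.sqrt((resid**2).sum() / dof)
        )
    else:
        raise ValueError(f"unknown curve model {model!r}")

    return StandardCurve(
        model=model,
        params=params,
        concentrations=conc,
        responses=resp,
        sems=None if sems is None else np.asarray(sems, dtype=float),
        residual_sd=resid_sd,
    )


def inverse_concentration(curve: StandardCurve, signal: float) -> InverseResult:
    """Back-calculate concentration from a signal through the fitted curve.

    Signals at or below the zero-concentration asymptote are reported as
    below-range; at or above the saturation asymptote, above-range.
    """
    s = float(signal)
    if curve.model == "four_parameter_logistic":
        a, b, c0, d = (curve.params[k] for k in "a b c0 d".split())
        if s <= a:
            return InverseResult(float("nan"), RangeStatus.BELOW_RANGE)
        if s >= d:
            return InverseResult(float("nan"), RangeStatus.ABOVE_RANGE)
        c = c0 * ((s - a) / (d - s)) ** (1.0 / b)
        return InverseResult(float(c), RangeStatus.OK)
    p0, p1 = curve.params["p0"], curve.params["p1"]
    c = 10.0 ** ((s - p0) / p1)
    cmin = float(curve.concentrations[curve.concentrations > 0].min())
    cmax = float(curve.concentrations.max())
    if c < cmin:
        return InverseResult(float("nan"), RangeStatus.BELOW_RANGE)
    if c > cmax:
        return InverseResult(float("nan"), RangeStatus.ABOVE_RANGE)
    return InverseResult(float(c), RangeStatus.OK)


@dataclass
class LodResult:
    """Limit of detection in signal units and (if a curve is given) pg/mL."""

    blank_mean: float
    blank_sd: float
    n_blank: int
    signal_lod: float
    concentration_lod: float | None = None
    concentration_status: RangeStatus | None = None


def lod(blank_signals: Sequence[float], curve: StandardCurve | None = None) -> LodResult:
    """LOD = blank mean + 3 x blank sample sd (convention: 10 blanks).

    With a standard curve supplied, the signal LOD is converted to
    concentration units through the inverse curve.
    """
    blanks = np.asarray(blank_signals, dtype=float)
    if blanks.size < 2:
        raise ValueError("need >= 2 blank measurements")
    if blanks.size != 10:
        warnings.warn(
            f"LOD conventionally uses 10 blanks; got {blanks.size}", stacklevel=2
        )
    mean = float(blanks.mean())
    sd = float(blanks.std(ddof=1))
    signal_lod = mean + 3.0 * sd
    result = LodResult(mean, sd, int(blanks.size), signal_lod)
    if curve is not None:
        inv = inverse_concentration(curve, signal_lod)
        result.concentration_lod = inv.concentration
        result.concentration_status = inv.status
    return result


def intra_assay_cv(replicates: Sequence[float]) -> float:
    """Within-day CV: sample sd / mean of same-sample replicates."""
    reps = np.asarray(replicates, dtype=float)
    if reps.size < 2:
        raise ValueError("intra-assay CV needs >= 2 replicates")
    mean = reps.mean()
    if mean == 0:
        return float("nan")
    return float(reps.std(ddof=1) / mean)


def inter_assay_cv(per_day_cvs: Sequence[float]) -> float:
    """Between-day CV: arithmetic mean of the daily CVs (3 days by convention)."""
    cvs = np.asarray(per_day_cvs, dtype=float)
    if cvs.size == 0:
        raise ValueError("need at least one daily CV")
    if cvs.size < 2:
        warnings.warn(
            "inter-assay CV conventionally averages >= 2 days", stacklevel=2
        )
    return float(cvs.mean())


def crossover_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    equal_var: bool = True,
) -> tuple[float, float]:
    """Two-sample two-tailed t-test between band intensity groups.

    Student's pooled-variance test by default (``equal_var=False`` gives
    Welch).  Used to ask whether a band's signal differs between two
    conditions — e.g. the same 0 pg/mL band with and without a second
    analyte present upstream.  Returns (t, p).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 values per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if np.allclose(a.mean(), b.mean()):
            return 0.0, 1.0
        raise ValueError("both groups have zero variance; t is undefined")
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


@dataclass
class MethodComparison:
    slope: float
    intercept: float
    r_value: float
    mean_bias: float  # mean(test - reference); deviation from identity line
    n: int


def method_comparison(
    reference: Sequence[float], test: Sequence[float]
) -> MethodComparison:
    """Compare a new assay against a reference on paired samples.

    Ordinary least-squares trend of test on reference, plus the mean bias
    (mean of test - reference) summarising deviation from the identity
    line.  A slope below 1 with negative bias indicates systematic
    underestimation by the test method.
    """
    ref = np.asarray(reference, dtype=float)
    tst = np.asarray(test, dtype=float)
    if ref.shape != tst.shape:
        raise ValueError("paired samples differ in length")
    if ref.size < 3:
        raise ValueError("need >= 3 paired samples")
    res = sps.linregress(ref, tst)
    return MethodComparison(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_value=float(res.rvalue),
        mean_bias=float((tst - ref).mean()),
        n=int(ref.size),
    )
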