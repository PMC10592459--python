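"""The four balance/navigation models, as Model -> Results pairs.

Each model is built from data (directly, or with a ``from_features`` /
``from_ibis`` constructor that applies the model's selection rules), and
``fit()`` returns a results object carrying the coefficient estimates,
their standard errors, goodness of fit, and a ``summary()`` table.

Models
------
BoutTimingModel
    Bout frequency vs. IBI pitch, quadratic ``y = a (x - b)^2 + c`` fitted
    by least squares on raw IBIs.  ``a`` is the *sensitivity* (how strongly
    postural eccentricity accelerates movement initiation, Hz/deg^2),
    ``b`` the baseline posture (deg) and ``c`` the base rate (Hz).
BoutTimingModel is fitted in the polynomial parameterization (closed-form
    least squares) and converted; the optimum is identical.
SteeringModel
    Pitch at peak speed regressed on bout trajectory; the slope is the
    *steering gain* (1 = trajectory fully explained by posture).
FinBodyModel
    Attack angle vs. pre-peak body rotation, fitted with an increasing
    logistic ``y = a + h / (1 + exp(-k (x + b)))``; the maximal slope
    ``k h / 4`` is the *fin-body ratio* (trunk-fin division of labor).
RightingModel
    Post-peak righting rotation vs. initial posture; the *righting gain*
    is the absolute slope and the *set point* the x-intercept (posture
    producing zero corrective rotation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .config import AnalysisConfig

__all__ = [
    "FitError",
    "BoutTimingModel",
    "SteeringModel",
    "FinBodyModel",
    "RightingModel",
    "finbody_variance",
    "binned_average",
    "logistic",
]


class FitError(RuntimeError):
    """A model fit failed; the message carries diagnostics."""


def binned_average(
    x: np.ndarray, y: np.ndarray, bin_width: float
) -> pd.DataFrame:
    """Mean of ``y`` (and ``x``) in fixed-width bins of ``x`` — display only."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    edges = np.floor(x / bin_width).astype(np.int64)
    df = pd.DataFrame({"bin": edges, "x": x, "y": y})
    out = df.groupby("bin").agg(x_mean=("x", "mean"), y_mean=("y", "mean"), n=("y", "size"))
    out["bin_center"] = (out.index + 0.5) * bin_width
    return out.reset_index(drop=True)


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Closed-form least squares.

    Returns ``(beta, cov, rsquared, sigma2)`` with ``cov`` the coefficient
    covariance ``sigma2 * (X'X)^-1``.
    """
    n, p = X.shape
    if n <= p:
        raise FitError(f"need more than {p} points, got {n}")
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p:
        raise FitError("degenerate design (collinear or constant regressor)")
    resid = y - X @ beta
    ssr = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    sigma2 = ssr / (n - p)
    cov = sigma2 * np.linalg.inv(X.T @ X)
    rsq = 1.0 - ssr / sst if sst > 0 else 1.0
    return beta, cov, rsq, sigma2


@dataclass
class FitResultsBase:
    """Common fields of all fit results."""

    params: pd.Series
    bse: pd.Series
    rsquared: float
    nobs: int
    model_name: str
    extras: dict = field(default_factory=dict)

    def conf_int(self, z: float = 1.959964) -> pd.DataFrame:
        lo = self.params - z * self.bse
        hi = self.params + z * self.bse
        return pd.DataFrame({"lower": lo, "upper": hi})

    def summary(self) -> str:
        lines = [
            f"{self.model_name}",
            "=" * 58,
            f"n obs: {self.nobs}    R-squared: {self.rsquared:.4f}",
            "-" * 58,
            f"{'coef':>16} {'estimate':>12} {'std err':>12}",
        ]
        for name in self.params.index:
            lines.append(
                f"{name:>16} {self.params[name]:>12.5g} {self.bse[name]:>12.3g}"
            )
        for key, val in self.extras.items():
            if isinstance(val, (int, float)) and not isinstance(val, bool):
                lines.append(f"{key:>16} {val:>12.5g}")
        lines.append("=" * 58)
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# bout timing


class TimingResults(FitResultsBase):
    @property
    def sensitivity(self) -> float:
        return float(self.params["sensitivity"])

    @property
    def baseline_posture(self) -> float:
        return float(self.params["baseline_posture"])

    @property
    def base_rate(self) -> float:
        return float(self.params["base_rate"])


class BoutTimingModel:
    """Quadratic model of bout frequency as a function of IBI pitch.

    Fitted on raw (pitch, frequency) pairs; the 3-degree-wide binned means
    are computed separately for display (:meth:`binned`).
    """

    param_names = ["sensitivity", "baseline_posture", "base_rate"]

    def __init__(self, ibi_pitch: np.ndarray, bout_frequency: np.ndarray):
        self.x = np.asarray(ibi_pitch, float)
        self.y = np.asarray(bout_frequency, float)
        if len(self.x) < 3:
            raise FitError("timing fit needs at least 3 IBIs")

    @classmethod
    def from_ibis(cls, ibis: pd.DataFrame) -> "BoutTimingModel":
        return cls(ibis["ibi_pitch"].to_numpy(), ibis["bout_frequency"].to_numpy())

    def fit(self) -> TimingResults:
        X = np.column_stack([np.ones_like(self.x), self.x, self.x**2])
        beta, cov, rsq, _ = _ols(X, self.y)
        b0, b1, b2 = beta
        if b2 == 0:
            raise FitError("quadratic coefficient is exactly zero; vertex undefined")
        a = b2
        b = -b1 / (2 * b2)
        c = b0 - b1**2 / (4 * b2)
        # delta-method gradients of (b, c) w.r.t. (b0, b1, b2)
        gb = np.array([0.0, -1 / (2 * b2), b1 / (2 * b2**2)])
        gc = np.array([1.0, -b1 / (2 * b2), b1**2 / (4 * b2**2)])
        se = np.sqrt(
            [cov[2, 2], gb @ cov @ gb, gc @ cov @ gc]
        )
        return TimingResults(
            params=pd.Series([a, b, c], index=self.param_names),
            bse=pd.Series(se, index=self.param_names),
            rsquared=rsq,
            nobs=len(self.x),
            model_name="Bout timing (parabola: frequency ~ a*(pitch-b)^2 + c)",
        )

    def binned(self, bin_deg: float = 3.0) -> pd.DataFrame:
        return binned_average(self.x, self.y, bin_deg)


# ---------------------------------------------------------------------------
# steering


class SteeringResults(FitResultsBase):
    @property
    def steering_gain(self) -> float:
        return float(self.params["steering_gain"])

    @property
    def intercept(self) -> float:
        return float(self.params["intercept"])

    @property
    def pearson_r(self) -> float:
        return float(self.extras["pearson_r"])


class SteeringModel:
    """Linear model of pitch at peak speed as a function of bout trajectory."""

    param_names = ["steering_gain", "intercept"]

    def __init__(self, trajectory: np.ndarray, pitch_peak: np.ndarray):
        self.x = np.asarray(trajectory, float)
        self.y = np.asarray(pitch_peak, float)
        if len(self.x) < 2:
            raise FitError("steering fit needs at least 2 bouts")

    @classmethod
    def from_features(cls, features: pd.DataFrame) -> "SteeringModel":
        return cls(features["trajectory"].to_numpy(), features["pitch_peak"].to_numpy())

    def fit(self) -> SteeringResults:
        X = np.column_stack([self.x, np.ones_like(self.x)])
        beta, cov, rsq, _ = _ols(X, self.y)
        r = float(np.corrcoef(self.x, self.y)[0, 1])
        return SteeringResults(
            params=pd.Series(beta, index=self.param_names),
            bse=pd.Series(np.sqrt(np.diag(cov)), index=self.param_names),
            rsquared=rsq,
            nobs=len(self.x),
            model_name="Steering (pitch at peak speed ~ trajectory)",
            extras={"pearson_r": r},
        )


# ---------------------------------------------------------------------------
# fin-body coordination


def logistic(x: np.ndarray, a: float, b: float, h: float, k: float) -> np.ndarray:
    """Increasing sigmoid ``a + h / (1 + exp(-k (x + b)))``."""
    return a + h / (1.0 + np.exp(-k * (np.asarray(x, float) + b)))


def finbody_variance(
    E_k: float, E_h: float, V_k: float, V_h: float, convention: str = "as_printed"
) -> float:
    """Variance of the fin-body ratio (the maximal sigmoid slope k*h/4).

    ``as_printed`` uses ``Ek^2*Vh + Eh^2*Vk + Vk*Vh*(1/4)^2``; the
    ``delta_method`` convention for ``var(k*h/4)`` places the (1/4)^2
    factor on all three terms.
    """
    if V_k < 0 or V_h < 0:
        raise ValueError("variances must be nonnegative")
    if convention == "as_printed":
        return E_k**2 * V_h + E_h**2 * V_k + V_k * V_h * (1.0 / 4.0) ** 2
    if convention == "delta_method":
        return (E_k**2 * V_h + E_h**2 * V_k + V_k * V_h) * (1.0 / 4.0) ** 2
    raise ValueError(f"unknown convention {convention!r}")


class FinBodyResults(FitResultsBase):
    @property
    def fin_body_ratio(self) -> float:
        return float(self.extras["fin_body_ratio"])

    @property
    def V_slope(self) -> float:
        return float(self.extras["V_slope"])


class FinBodyModel:
    """Logistic model of attack angle as a function of pre-peak body rotation.

    :meth:`from_features` applies the two selection rules: bouts with peak
    speed below the fin-body floor (7 mm/s) are dropped first, then bouts
    whose steering rotation exceeds the 50th percentile of the remaining
    sample while having a negative attack angle are excluded.  The counts
    of both exclusions are stored in ``filter_counts``.
    """

    param_names = ["a", "b", "h", "k"]

    def __init__(
        self,
        body_rotation: np.ndarray,
        attack_angle: np.ndarray,
        variance_convention: str = "as_printed",
        filter_counts: dict | None = None,
    ):
        self.x = np.asarray(body_rotation, float)
        self.y = np.asarray(attack_angle, float)
        self.variance_convention = variance_convention
        self.filter_counts = filter_counts or {}
        if len(self.x) < 5:
            raise FitError("fin-body fit needs at least 5 bouts")

    @classmethod
    def from_features(
        cls, features: pd.DataFrame, config: AnalysisConfig | None = None
    ) -> "FinBodyModel":
        config = config or AnalysisConfig()
        fast = features[features["peak_speed"] >= config.finbody_speed_floor_mm_s]
        n_slow = len(features) - len(fast)
        cutoff = float(np.percentile(fast["steering_rotation"], 50))
        excl = (fast["steering_rotation"] > cutoff) & (fast["attack_angle"] < 0)
        kept = fast[~excl]
        return cls(
            kept["body_rotation"].to_numpy(),
            kept["attack_angle"].to_numpy(),
            variance_convention=config.variance_convention,
            filter_counts={
                "below_speed_floor": int(n_slow),
                "neg_attack_high_steer": int(excl.sum()),
                "steering_cutoff_deg": cutoff,
            },
        )

    def _initial_guess(self) -> list[float]:
        h0 = max(float(np.ptp(self.y)), 1e-3)
        b0 = -float(np.median(self.x))
        # crude range slope of y over x gives the starting maximal slope
        slope0 = max(
            float(np.polyfit(self.x, self.y, 1)[0]), 1e-3
        )
        k0 = 4.0 * slope0 / h0
        a0 = float(np.min(self.y))
        return [a0, b0, h0, k0]

    def fit(self) -> FinBodyResults:
        p0 = self._initial_guess()
        bounds = ([-np.inf, -np.inf, 1e-9, 1e-9], [np.inf, np.inf, np.inf, np.inf])
        try:
            popt, pcov = curve_fit(
                logistic, self.x, self.y, p0=p0, bounds=bounds, maxfev=10000
            )
        except (RuntimeError, ValueError) as err:
            raise FitError(
                f"logistic fit failed on n={len(self.x)} "
                f"(x range {self.x.min():.2f}..{self.x.max():.2f}, p0={p0}): {err}"
            ) from err
        a, b, h, k = popt
        resid = self.y - logistic(self.x, *popt)
        sst = float(np.sum((self.y - self.y.mean()) ** 2))
        rsq = 1.0 - float(resid @ resid) / sst if sst > 0 else 1.0
        V_h, V_k = float(pcov[2, 2]), float(pcov[3, 3])
        ratio = k * h / 4.0
        V_slope = finbody_variance(k, h, V_k, V_h, self.variance_convention)
        return FinBodyResults(
            params=pd.Series(popt, index=self.param_names),
            bse=pd.Series(np.sqrt(np.diag(pcov)), index=self.param_names),
            rsquared=rsq,
            nobs=len(self.x),
            model_name="Fin-body coordination (attack angle ~ logistic(body rotation))",
            extras={
                "fin_body_ratio": ratio,
                "V_slope": V_slope,
                "se_ratio": float(np.sqrt(V_slope)),
                "filter_counts": self.filter_counts,
            },
        )

    def binned(self, bin_deg: float = 0.8) -> pd.DataFrame:
        return binned_average(self.x, self.y, bin_deg)


# ---------------------------------------------------------------------------
# righting


class RightingResults(FitResultsBase):
    @property
    def righting_gain(self) -> float:
        return float(self.extras["righting_gain"])

    @property
    def slope(self) -> float:
        return float(self.params["slope"])

    @property
    def set_point(self) -> float:
        return float(self.extras["set_point"])


class RightingModel:
    """Linear model of righting rotation as a function of initial posture.

    The regressor is pitch at -250 ms by default; set
    ``config.righting_initial = "ibi_pitch"`` and supply a feature table
    carrying an ``ibi_pitch`` column to use the preceding IBI's mean pitch
    instead.
    """

    param_names = ["slope", "intercept"]

    def __init__(self, pitch_initial: np.ndarray, righting_rotation: np.ndarray):
        self.x = np.asarray(pitch_initial, float)
        self.y = np.asarray(righting_rotation, float)
        if len(self.x) < 2:
            raise FitError("righting fit needs at least 2 bouts")

    @classmethod
    def from_features(
        cls, features: pd.DataFrame, config: AnalysisConfig | None = None
    ) -> "RightingModel":
        config = config or AnalysisConfig()
        col = "pitch_initial" if config.righting_initial == "pre_bout_pitch" else "ibi_pitch"
        if col not in features:
            raise KeyError(f"feature table lacks column {col!r}")
        return cls(features[col].to_numpy(), features["righting_rotation"].to_numpy())

    def fit(self) -> RightingResults:
        X = np.column_stack([self.x, np.ones_like(self.x)])
        beta, cov, rsq, _ = _ols(X, self.y)
        slope, intercept = beta
        if abs(slope) < 1e-12:  # numerically flat line: no x-intercept
            set_point = np.nan
            se_sp = np.nan
        else:
            set_point = -intercept / slope
            g = np.array([intercept / slope**2, -1.0 / slope])
            se_sp = float(np.sqrt(g @ cov @ g))
        return RightingResults(
            params=pd.Series(beta, index=self.param_names),
            bse=pd.Series(np.sqrt(np.diag(cov)), index=self.param_names),
            rsquared=rsq,
            nobs=len(self.x),
            model_name="Righting (righting rotation ~ initial posture)",
            extras={
                "righting_gain": abs(float(slope)),
                "set_point": float(set_point),
                "se_set_point": se_sp,
                "set_point_defined": bool(np.isfinite(set_point)),
            },
        )
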