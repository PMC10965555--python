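"""Allometric scaling of aortic luminal diameter with body mass.

The luminal diameter follows a power law ``di = alpha * BM^beta``. A log
transform makes this linear, so ``alpha`` and ``beta`` come from ordinary
least squares of ln(di) on ln(BM) fitted to healthy (wild-type) animals.
A vessel is called *dilated* when its log-diameter exceeds the upper bound
of the 95% prediction interval for a new individual at its body mass, and
*aneurysmal* when the normalized diameter (measured over expected) exceeds
1.5, the clinical convention. Lower-tail outliers are flagged as small, not
dilated, since the screen is one-sided toward enlargement.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "AllometricScaling",
    "AllometricResults",
    "VesselClassification",
    "fit_allometric",
    "classify_vessel",
]

ANEURYSM_THRESHOLD = 1.5


@dataclass(frozen=True)
class VesselClassification:
    """Outcome of the dilatation screen for one vessel."""

    normalized_diameter: float
    status: str  # normal | dilated | aneurysmal
    small: bool  # below the lower prediction bound (flagged, not "dilated")
    expected_diameter: float
    lower_bound: float
    upper_bound: float


@dataclass(frozen=True)
class AllometricResults:
    """Fitted power law di = alpha * BM^beta with log-scale scatter.

    alpha is in the diameter unit times g^-beta; s_log is the residual
    standard deviation of ln(di) with an n-2 denominator.
    """

    alpha: float
    beta: float
    n: int
    s_log: float
    interval_level: float
    log_mass_mean: float
    log_mass_ssq: float  # centered sum of squares of ln(BM)

    def predict(self, body_mass_g):
        """Expected diameter at the given body mass (same unit as the fit)."""
        return self.alpha * np.asarray(body_mass_g, dtype=float) ** self.beta

    def _halfwidth(self, body_mass_g, interval: str) -> np.ndarray:
        """Half-width of the log-scale interval at each query mass."""
        x = np.log(np.asarray(body_mass_g, dtype=float))
        lev = 1.0 / self.n + (x - self.log_mass_mean) ** 2 / self.log_mass_ssq
        extra = 1.0 if interval == "prediction" else 0.0
        tq = stats.t.ppf(0.5 + self.interval_level / 2.0, self.n - 2)
        return tq * self.s_log * np.sqrt(extra + lev)

    def interval(self, body_mass_g, interval: str = "prediction"):
        """(lower, upper) diameter bounds for a new individual (or the mean response)."""
        if interval not in ("prediction", "mean"):
            raise ValueError("interval must be 'prediction' or 'mean'")
        d_hat = self.predict(body_mass_g)
        hw = self._halfwidth(body_mass_g, interval)
        return d_hat * np.exp(-hw), d_hat * np.exp(hw)

    def classify(
        self,
        body_mass_g: float,
        diameter: float,
        interval: str = "prediction",
        aneurysm_threshold: float = ANEURYSM_THRESHOLD,
    ) -> VesselClassification:
        """Dilatation status of one vessel relative to the healthy scaling band."""
        d_hat = float(self.predict(body_mass_g))
        lo, hi = (float(b) for b in self.interval(body_mass_g, interval))
        normalized = diameter / d_hat
        if normalized > aneurysm_threshold:
            status = "aneurysmal"
        elif diameter > hi:
            status = "dilated"
        else:
            status = "normal"
        return VesselClassification(
            normalized_diameter=normalized,
            status=status,
            small=diameter < lo,
            expected_diameter=d_hat,
            lower_bound=lo,
            upper_bound=hi,
        )

    def summary(self) -> str:
        return "\n".join(
            [
                "Allometric scaling  di = alpha * BM^beta",
                "=" * 42,
                f"{'n':<24}{self.n:>18d}",
                f"{'alpha [um g^-beta]':<24}{self.alpha:>18.4f}",
                f"{'beta [-]':<24}{self.beta:>18.4f}",
                f"{'s_log [-]':<24}{self.s_log:>18.4f}",
                f"{'interval level':<24}{self.interval_level:>18.2f}",
                "=" * 42,
            ]
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "AllometricResults":
        with open(path) as fh:
            return cls(**json.load(fh))


class AllometricScaling:
    """Log-log regression model of diameter on body mass.

    Parameters
    ----------
    body_mass_g, diameter : array-like
        Positive body masses (g) and luminal diameters (any consistent unit;
        um throughout this package) of the reference (healthy) cohort.
    """

    def __init__(self, body_mass_g, diameter, interval_level: float = 0.95):
        bm = np.asarray(body_mass_g, dtype=float)
        d = np.asarray(diameter, dtype=float)
        if bm.shape != d.shape or bm.ndim != 1:
            raise ValueError("body_mass_g and diameter must be 1-D of equal length")
        if len(bm) < 3:
            raise ValueError(f"need n >= 3, got {len(bm)}")
        if np.any(bm <= 0) or np.any(d <= 0):
            raise ValueError("body masses and diameters must be positive")
        if not 0 < interval_level < 1:
            raise ValueError("interval_level must be in (0, 1)")
        self.x = np.log(bm)
        self.y = np.log(d)
        self.interval_level = interval_level

    def fit(self) -> AllometricResults:
        ols = sm.OLS(self.y, sm.add_constant(self.x)).fit()
        intercept, beta = ols.params
        resid = ols.resid
        n = len(self.x)
        s_log = float(np.sqrt(resid @ resid / (n - 2)))
        return AllometricResults(
            alpha=float(np.exp(intercept)),
            beta=float(beta),
            n=n,
            s_log=s_log,
            interval_level=self.interval_level,
            log_mass_mean=float(self.x.mean()),
            log_mass_ssq=float(((self.x - self.x.mean()) ** 2).sum()),
        )


def fit_allometric(body_mass_g, diameter, interval_level: float = 0.95) -> AllometricResults:
    """Fit the allometric power law by log-log OLS."""
    return AllometricScaling(body_mass_g, diameter, interval_level).fit()


def classify_vessel(
    model: AllometricResults, body_mass_g: float, diameter: float, **kwargs
) -> VesselClassification:
    """Classify one vessel against a fitted healthy scaling model."""
    return model.classify(body_mass_g, diameter, **kwargs)
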