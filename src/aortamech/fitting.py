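"""Nonlinear regression of the four-fiber-family model to reduced biaxial data.

Usage follows the Model/Results pattern::

    model = FourFiberModel.from_record(record)
    res = model.fit(FitConfig(seed=1, n_starts=24))
    print(res.summary())
    res.params  # FourFiberParams

The objective is least squares on both Cauchy stress components, each
normalized by the mean experimental stress of that component, summed over all
retained protocol points. The exponential fiber terms create local minima, so
the bounded local solver is restarted from Latin-hypercube samples of the
parameter box and the best converged start is kept (ties broken by the
smallest parameter 2-norm, which pins down near-non-identifiable tiny
parameters).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import least_squares
from scipy.stats import qmc

from .experiment import SubjectRecord, reduce_record
from .mech import FourFiberParams

__all__ = [
    "FitConfig",
    "FourFiberModel",
    "FourFiberResults",
    "fit_parameters",
    "InsufficientDataError",
    "FitFailureError",
    "DEFAULT_BOUNDS",
]

#: (lower, upper) per parameter: (c, c1_ax, c2_ax, c1_circ, c2_circ, c1_diag, c2_diag, alpha0)
DEFAULT_BOUNDS = (
    np.array([0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0]),
    np.array([500.0, 500.0, 30.0, 500.0, 30.0, 500.0, 30.0, 90.0]),
)

_MIN_POINTS = 16  # twice the parameter count
_EXP_CAP = 500.0


class InsufficientDataError(ValueError):
    """Fewer reduced data points than required to constrain 8 parameters."""


class FitFailureError(RuntimeError):
    """No optimizer start converged; carries per-start diagnostics."""

    def __init__(self, message: str, diagnostics: list):
        super().__init__(message)
        self.diagnostics = diagnostics


@dataclass(frozen=True)
class FitConfig:
    """Multi-start optimizer configuration (serializable to YAML/JSON)."""

    seed: int = 0
    n_starts: int = 24
    bounds: tuple = DEFAULT_BOUNDS
    ftol: float = 1e-10
    xtol: float = 1e-12
    gtol: float = 1e-12
    max_nfev: int = 4000

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")

    @classmethod
    def from_file(cls, path) -> "FitConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "bounds" in raw:
            raw["bounds"] = (np.asarray(raw["bounds"][0]), np.asarray(raw["bounds"][1]))
        return cls(**raw)


def _model_stresses(vec: np.ndarray, u: np.ndarray, v: np.ndarray):
    """Vectorized in-plane Cauchy stresses for a parameter vector.

    u = lam_theta^2, v = lam_z^2 per point. Mirrors mech.cauchy_stress; kept
    vectorized here because the optimizer evaluates it thousands of times.
    """
    c, c1a, c2a, c1c, c2c, c1d, c2d, a0 = vec
    ar = math.radians(a0)
    s2 = np.array([0.0, 1.0, math.sin(ar) ** 2, math.sin(ar) ** 2])
    co2 = 1.0 - s2
    c1 = np.array([c1a, c1c, c1d, c1d])
    c2 = np.array([c2a, c2c, c2d, c2d])
    sig_t = c * (u - 1.0 / (u * v))
    sig_z = c * (v - 1.0 / (u * v))
    for i in range(4):
        if c1[i] == 0.0:
            continue
        x = u * s2[i] + v * co2[i] - 1.0
        dW = 0.5 * c1[i] * x * np.exp(np.minimum(c2[i] * x * x, _EXP_CAP))
        sig_t = sig_t + 2.0 * u * dW * s2[i]
        sig_z = sig_z + 2.0 * v * dW * co2[i]
    return sig_t, sig_z


@dataclass(frozen=True)
class FourFiberResults:
    """Best-fit parameters and fit diagnostics."""

    params: FourFiberParams
    objective_value: float
    n_points: int
    converged: bool
    n_starts: int
    start_objectives: tuple  # per-start final objective, in run order
    best_so_far: tuple  # running minimum across starts

    @property
    def rmse(self) -> float:
        """Root-mean-square residual of the normalized objective (dimensionless)."""
        return math.sqrt(self.objective_value / (2.0 * self.n_points))

    def summary(self) -> str:
        p = self.params
        lines = [
            "Four-fiber-family model fit",
            "=" * 42,
            f"{'n points':<28}{self.n_points:>14d}",
            f"{'n starts':<28}{self.n_starts:>14d}",
            f"{'converged':<28}{str(self.converged):>14}",
            f"{'objective':<28}{self.objective_value:>14.6g}",
            f"{'RMSE (normalized)':<28}{self.rmse:>14.3f}",
            "-" * 42,
            f"{'c (elastic fibers) [kPa]':<28}{p.c:>14.4g}",
            f"{'c1 axial [kPa]':<28}{p.c1[0]:>14.4g}",
            f"{'c2 axial [-]':<28}{p.c2[0]:>14.4g}",
            f"{'c1 circumferential [kPa]':<28}{p.c1[1]:>14.4g}",
            f"{'c2 circumferential [-]':<28}{p.c2[1]:>14.4g}",
            f"{'c1 diagonal [kPa]':<28}{p.c1[2]:>14.4g}",
            f"{'c2 diagonal [-]':<28}{p.c2[2]:>14.4g}",
            f"{'alpha0 [deg]':<28}{p.alpha0:>14.4g}",
            "=" * 42,
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "params": {
                "c": self.params.c,
                "c1": list(self.params.c1),
                "c2": list(self.params.c2),
                "alpha0": self.params.alpha0,
            },
            "objective_value": self.objective_value,
            "rmse": round(self.rmse, 3),
            "n_points": self.n_points,
            "converged": self.converged,
            "n_starts": self.n_starts,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


class FourFiberModel:
    """Four-fiber-family constitutive model bound to one subject's reduced data.

    Parameters
    ----------
    data : DataFrame
        One row per retained point with columns ``lam_theta``, ``lam_z``,
        ``sigma_theta_kPa``, ``sigma_z_kPa`` (output of
        :func:`aortamech.experiment.reduce_record`).
    """

    def __init__(self, data: pd.DataFrame):
        required = {"lam_theta", "lam_z", "sigma_theta_kPa", "sigma_z_kPa"}
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"reduced data missing columns {sorted(missing)}")
        if len(data) < _MIN_POINTS:
            raise InsufficientDataError(
                f"need >= {_MIN_POINTS} points to fit 8 parameters, got {len(data)}"
            )
        self.data = data.reset_index(drop=True)
        self._u = data["lam_theta"].to_numpy() ** 2
        self._v = data["lam_z"].to_numpy() ** 2
        self._st_exp = data["sigma_theta_kPa"].to_numpy()
        self._sz_exp = data["sigma_z_kPa"].to_numpy()
        self._wt = 1.0 / np.mean(self._st_exp)
        self._wz = 1.0 / np.mean(self._sz_exp)

    @classmethod
    def from_record(cls, record: SubjectRecord) -> "FourFiberModel":
        if not record.has_fitting_data():
            raise InsufficientDataError(
                f"{record.sample_id}: need at least one pressure-diameter and one "
                f"force-length protocol, got {record.protocols()}"
            )
        return cls(reduce_record(record))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "FourFiberModel":
        return cls(df)

    @property
    def n_points(self) -> int:
        return len(self.data)

    def residuals(self, vec) -> np.ndarray:
        """Stacked normalized stress residuals (2 per point)."""
        st, sz = _model_stresses(np.asarray(vec, dtype=float), self._u, self._v)
        r = np.concatenate(
            [(st - self._st_exp) * self._wt, (sz - self._sz_exp) * self._wz]
        )
        # keep squared sums finite when a start probes the stiff corner of the box
        return np.clip(r, -1e8, 1e8)

    def objective(self, params) -> float:
        """Sum of squared normalized residuals at a parameter vector or FourFiberParams."""
        vec = params.as_vector() if isinstance(params, FourFiberParams) else params
        r = self.residuals(vec)
        return float(r @ r)

    def fit(self, config: FitConfig | None = None) -> FourFiberResults:
        """Bounded multi-start least squares; deterministic given config.seed."""
        cfg = config or FitConfig()
        lo, hi = cfg.bounds
        sampler = qmc.LatinHypercube(d=8, seed=cfg.seed)
        starts = qmc.scale(sampler.random(cfg.n_starts), lo, hi)
        solutions = []
        objectives = []
        best_so_far = []
        for x0 in starts:
            try:
                sol = least_squares(
                    self.residuals,
                    x0,
                    bounds=(lo, hi),
                    method="trf",
                    ftol=cfg.ftol,
                    xtol=cfg.xtol,
                    gtol=cfg.gtol,
                    max_nfev=cfg.max_nfev,
                )
                obj = 2.0 * sol.cost
                solutions.append((obj, sol))
            except Exception:  # singular Jacobian etc.: record a failed start
                obj = np.inf
                solutions.append((obj, None))
            objectives.append(obj)
            best_so_far.append(min(objectives))
        converged = [(o, s) for o, s in solutions if s is not None and s.status > 0]
        if not converged:
            raise FitFailureError(
                "no optimizer start converged",
                diagnostics=[
                    (o, None if s is None else s.status) for o, s in solutions
                ],
            )
        best_obj = min(o for o, _ in converged)
        # tie-break equal-objective minima by smallest parameter 2-norm
        tol = max(1e-9 * max(best_obj, 1.0), 1e-14)
        tied = [s for o, s in converged if o <= best_obj + tol]
        best = min(tied, key=lambda s: float(np.linalg.norm(s.x)))
        return FourFiberResults(
            params=FourFiberParams.from_vector(best.x),
            objective_value=self.objective(best.x),
            n_points=self.n_points,
            converged=True,
            n_starts=cfg.n_starts,
            start_objectives=tuple(objectives),
            best_so_far=tuple(best_so_far),
        )


def cohort_fit_table(entries) -> pd.DataFrame:
    """Aggregate per-sample fits into a cohort table (one row per vessel).

    ``entries`` is an iterable of (SubjectRecord, FourFiberResults); the column
    layout mirrors the usual material-parameter report: genotype, age, the
    eight parameters, and the fit RMSE.
    """
    rows = []
    for rec, res in entries:
        p = res.params
        rows.append(
            dict(
                sample_id=rec.sample_id,
                genotype=rec.genotype,
                age_weeks=rec.age_weeks,
                c_kPa=p.c,
                c1_axial_kPa=p.c1[0],
                c2_axial=p.c2[0],
                c1_circ_kPa=p.c1[1],
                c2_circ=p.c2[1],
                c1_diag_kPa=p.c1[2],
                c2_diag=p.c2[2],
                alpha0_deg=p.alpha0,
                rmse=round(res.rmse, 3),
            )
        )
    return pd.DataFrame(rows)


def build_objective(record: SubjectRecord):
    """Objective function over FourFiberParams for one subject's data."""
    model = FourFiberModel.from_record(record)
    return model.objective


def fit_parameters(record: SubjectRecord, config: FitConfig | None = None) -> FourFiberResults:
    """Fit the eight material parameters to one subject's reduced biaxial data."""
    return FourFiberModel.from_record(record).fit(config)


def fit_rmse(result: FourFiberResults) -> float:
    """Normalized root-mean-square fitting error, rounded to 3 decimals."""
    return round(result.rmse, 3)
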