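"""Global weighted fitting of the topology-conversion kinetic model.

``PlasmidKineticsModel`` holds a :class:`~plasmidkinetics.dataset.GelDataset`
plus fitting options; ``fit()`` returns a ``PlasmidKineticsResults`` carrying
the rate estimates, their standard errors, the parameter covariance and fit
diagnostics, in the spirit of statsmodels model/results pairs.

The objective is weighted least squares over all three species jointly:

    WRSS = sum_{species, x} ((observed mean - model) / SD_eff)^2

where SD_eff is the per-point replicate standard deviation (percent scale,
converted to fractions internally) with a floor so single-replicate points
(SD = 0) cannot receive infinite weight.  Parameters are constrained
nonnegative; standard errors come from (J'WJ)^-1, by default rescaled by the
reduced chi-square, and are withheld when the fit has no residual degrees of
freedom.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from . import __version__ as _pkg_version
from .dataset import GelDataset, read_gel_table
from .kinetics import (
    ExposureAxis,
    InitialState,
    KineticParams,
    RateEstimate,
    species_proportions,
)

__all__ = ["PlasmidKineticsModel", "PlasmidKineticsResults", "read_fit_report"]

_SPECIES = ("supercoiled", "relaxed", "linear")

#: SD floor in percentage points applied to per-point weights
DEFAULT_SD_FLOOR_PCT = 1.0


class PlasmidKineticsModel:
    """Kinetic model of S -> R -> L conversion bound to one dataset.

    Parameters
    ----------
    data
        Gel-quantification dataset (one exposure axis, >= 2 distinct
        exposures).
    fit_s0
        Estimate the initial supercoiled fraction S0 (default) or fix it at
        ``init_state.s0``.
    variant
        ``"basic"`` for the two-step scheme, ``"direct_break"`` to add the
        direct supercoiled->linear rate ksl as a free parameter.
    mode
        ``"means"`` fits per-exposure replicate means weighted by 1/SD^2
        (with the SD floor); ``"lanes"`` fits every lane with unit weights.
    sd_floor_pct
        Weight floor, in percentage points, on per-point SDs.
    scale_cov
        Rescale the covariance by the reduced chi-square (errors-in-variance
        convention); set False to use the raw (J'WJ)^-1.
    init_state
        Initial proportions; r0/l0 are held fixed, s0 is the fixed value or
        the starting point depending on ``fit_s0``.
    mask_linear_above
        Optional exposure threshold above which linear-band observations are
        excluded from the objective (high-dose linear quantification can be
        unreliable due to fragment smearing).
    """

    def __init__(
        self,
        data: GelDataset,
        *,
        fit_s0: bool = True,
        variant: str = "basic",
        mode: str = "means",
        sd_floor_pct: float = DEFAULT_SD_FLOOR_PCT,
        scale_cov: bool = True,
        init_state: InitialState | None = None,
        mask_linear_above: float | None = None,
    ) -> None:
        if variant not in ("basic", "direct_break"):
            raise ValueError(f"unknown variant {variant!r}")
        if mode not in ("means", "lanes"):
            raise ValueError(f"unknown mode {mode!r}")
        if len(data.exposures) < 2:
            raise ValueError("fitting requires >= 2 distinct exposure values")
        self.data = data
        self.axis = data.axis
        self.fit_s0 = fit_s0
        self.variant = variant
        self.mode = mode
        self.sd_floor_pct = float(sd_floor_pct)
        self.scale_cov = scale_cov
        self.init_state = init_state or InitialState(s0=1.0)
        self.mask_linear_above = mask_linear_above
        self._obs = self._build_observations()

    # ------------------------------------------------------------------ #
    # constructors

    @classmethod
    def from_dataframe(
        cls,
        table: pd.DataFrame,
        *,
        axis: ExposureAxis | str = ExposureAxis.DOSE,
        condition: str = "",
        **options: Any,
    ) -> "PlasmidKineticsModel":
        data = GelDataset(table=table, axis=ExposureAxis(axis), condition=condition)
        return cls(data, **options)

    @classmethod
    def from_csv(cls, path: str | Path, **options: Any) -> "PlasmidKineticsModel":
        return cls(read_gel_table(path), **options)

    # ------------------------------------------------------------------ #
    # observations and parameters

    def _build_observations(self) -> pd.DataFrame:
        """Long table of (x, species, observed fraction, effective SD)."""
        floor = self.sd_floor_pct
        rows = []
        if self.mode == "means":
            summ = self.data.summarize_replicates()
            for _, rec in summ.iterrows():
                for sp in _SPECIES:
                    rows.append(
                        {
                            "x": rec["x"],
                            "species": sp,
                            "obs": rec[f"mean_{sp}"] / 100.0,
                            "sd": max(rec[f"sd_{sp}"], floor) / 100.0,
                        }
                    )
        else:
            fr = self.data.fractions()
            for _, rec in fr.iterrows():
                for sp in _SPECIES:
                    rows.append(
                        {"x": rec["x"], "species": sp, "obs": rec[sp], "sd": floor / 100.0}
                    )
        obs = pd.DataFrame(rows)
        if self.mask_linear_above is not None:
            drop = (obs["species"] == "linear") & (obs["x"] > self.mask_linear_above)
            obs = obs[~drop].reset_index(drop=True)
        return obs

    @property
    def param_names(self) -> list[str]:
        names = ["ksr", "krl"]
        if self.fit_s0:
            names.append("s0")
        if self.variant == "direct_break":
            names.append("ksl")
        return names

    def _unpack(self, theta: np.ndarray) -> KineticParams:
        d = dict(zip(self.param_names, theta))
        s0 = d.get("s0", self.init_state.s0)
        return KineticParams(
            ksr=d["ksr"],
            krl=d["krl"],
            s0=s0,
            r0=self.init_state.r0,
            l0=self.init_state.l0,
            ksl=d.get("ksl", 0.0),
            axis=self.axis,
        )

    def _residuals(self, theta: np.ndarray) -> np.ndarray:
        p = self._unpack(theta)
        x = self._obs["x"].to_numpy(float)
        s, r, lin = p.proportions(x)
        pred = np.where(
            self._obs["species"] == "supercoiled",
            s,
            np.where(self._obs["species"] == "relaxed", r, lin),
        )
        return (self._obs["obs"].to_numpy(float) - pred) / self._obs["sd"].to_numpy(float)

    # ------------------------------------------------------------------ #
    # starting values

    def initial_guess(self) -> np.ndarray:
        """Data-driven start: ksr from a log-linear regression of mean S on x.

        S(x) = S0 exp(-ksr x) is exactly log-linear, so on clean data the
        slope recovers ksr.  krl starts at ksr/50 (the second step is
        rate-limiting in this assay) and s0 at the mean supercoiled fraction
        at the smallest exposure.  Falls back to fixed defaults when the
        supercoiled signal is unusable.
        """
        summ = self.data.summarize_replicates()
        x = summ["x"].to_numpy(float)
        s_mean = summ["mean_supercoiled"].to_numpy(float) / 100.0
        keep = s_mean > 0
        if keep.sum() >= 2 and len(np.unique(x[keep])) >= 2:
            slope, _ = np.polyfit(x[keep], np.log(s_mean[keep]), 1)
            ksr0 = max(-slope, 1e-6)
            s00 = float(np.clip(s_mean[np.argmin(x)], 1e-3, 1.0))
        else:
            ksr0, s00 = 1.0, 1.0
        guess = {"ksr": ksr0, "krl": ksr0 / 50.0, "s0": s00, "ksl": ksr0 / 20.0}
        return np.array([guess[name] for name in self.param_names])

    # ------------------------------------------------------------------ #
    # fitting

    def fit(
        self,
        start: Sequence[float] | None = None,
        *,
        xtol: float = 1e-12,
        ftol: float = 1e-12,
        gtol: float = 1e-12,
        max_nfev: int = 10_000,
    ) -> "PlasmidKineticsResults":
        """Minimize the weighted residual sum of squares; never raises on
        non-convergence — inspect ``results.converged``."""
        names = self.param_names
        lower = np.zeros(len(names))
        upper = np.array([np.inf if n != "s0" else 1.0 for n in names])
        x0 = np.asarray(start, float) if start is not None else self.initial_guess()
        x0 = np.clip(x0, lower + 1e-12, np.where(np.isfinite(upper), upper, 1e12))

        sol = least_squares(
            self._residuals,
            x0,
            bounds=(lower, upper),
            method="trf",
            xtol=xtol,
            ftol=ftol,
            gtol=gtol,
            max_nfev=max_nfev,
            x_scale="jac",
        )

        wrss = float(2.0 * sol.cost)
        n_obs = len(self._obs)
        dof = n_obs - len(names)
        cov, bse = self._covariance(sol.jac, wrss, dof)
        at_bound = [
            n
            for n, v, lo, hi in zip(names, sol.x, lower, upper)
            if v - lo < 1e-8 or (np.isfinite(hi) and hi - v < 1e-8)
        ]
        return PlasmidKineticsResults(
            model=self,
            params=pd.Series(sol.x, index=names),
            bse=pd.Series(bse, index=names),
            cov=pd.DataFrame(cov, index=names, columns=names),
            wrss=wrss,
            dof=dof,
            n_obs=n_obs,
            converged=bool(sol.success),
            message=str(sol.message),
            nfev=int(sol.nfev),
            at_bound=at_bound,
        )

    def _covariance(
        self, jac: np.ndarray, wrss: float, dof: int
    ) -> tuple[np.ndarray, np.ndarray]:
        k = jac.shape[1]
        if dof <= 0:
            # no residual degrees of freedom: refuse to report uncertainties
            return np.full((k, k), np.nan), np.full(k, np.nan)
        jtj = jac.T @ jac
        # pseudo-inverse guards parameters pinned at a bound (singular J)
        cov = np.linalg.pinv(jtj)
        if self.scale_cov:
            cov = cov * (wrss / dof)
        bse = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        return cov, bse


@dataclass
class PlasmidKineticsResults:
    """Fit results: estimates, uncertainties, covariance and diagnostics."""

    model: PlasmidKineticsModel
    params: pd.Series
    bse: pd.Series
    cov: pd.DataFrame
    wrss: float
    dof: int
    n_obs: int
    converged: bool
    message: str
    nfev: int
    at_bound: list[str] = field(default_factory=list)

    # ------------------------------------------------------------------ #
    # accessors

    @property
    def axis(self) -> ExposureAxis:
        return self.model.axis

    @property
    def ksr(self) -> RateEstimate:
        return RateEstimate(self.params["ksr"], float(self.bse["ksr"]), self.axis)

    @property
    def krl(self) -> RateEstimate:
        return RateEstimate(self.params["krl"], float(self.bse["krl"]), self.axis)

    @property
    def s0(self) -> float:
        return float(self.params.get("s0", self.model.init_state.s0))

    @property
    def kinetic_params(self) -> KineticParams:
        return self.model._unpack(self.params.to_numpy())

    @property
    def redchi(self) -> float:
        return self.wrss / self.dof if self.dof > 0 else np.nan

    def cov_params(self) -> pd.DataFrame:
        return self.cov.copy()

    # ------------------------------------------------------------------ #
    # prediction / plotting

    def predict(self, grid: Sequence[float] | np.ndarray) -> pd.DataFrame:
        """Model species fractions on an exposure grid."""
        grid = np.asarray(grid, float)
        s, r, lin = self.kinetic_params.proportions(grid)
        return pd.DataFrame(
            {"x": grid, "supercoiled": s, "relaxed": r, "linear": lin}
        )

    def plot_fit(self, ax=None, n_curve: int = 200):
        """Data (means ± SD) with fitted curves; returns the axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        summ = self.model.data.summarize_replicates()
        xs = summ["x"].to_numpy(float)
        grid = np.linspace(0, xs.max() if xs.max() > 0 else 1.0, n_curve)
        curves = self.predict(grid)
        colors = {"supercoiled": "C0", "relaxed": "C1", "linear": "C2"}
        for sp in _SPECIES:
            ax.errorbar(
                xs,
                summ[f"mean_{sp}"],
                yerr=summ[f"sd_{sp}"],
                fmt="o",
                color=colors[sp],
                label=sp,
            )
            ax.plot(grid, 100 * curves[sp], color=colors[sp])
        ax.set_xlabel(f"exposure ({self.axis.units})")
        ax.set_ylabel("% of total DNA")
        ax.legend()
        return ax

    # ------------------------------------------------------------------ #
    # reporting

    def summary(self) -> str:
        lines = [
            "Plasmid topology-conversion kinetics — weighted least squares",
            "=" * 62,
            f"condition:        {self.model.data.condition or '(unlabelled)'}",
            f"exposure axis:    {self.axis.value} ({self.axis.units})",
            f"variant:          {self.model.variant}   mode: {self.model.mode}",
            f"observations:     {self.n_obs}   dof: {self.dof}",
            f"WRSS: {self.wrss:.6g}   reduced chi^2: {self.redchi:.4g}",
            f"converged: {self.converged}   nfev: {self.nfev}",
            "-" * 62,
            f"{'param':<8}{'estimate':>14}{'std err':>12}  units",
        ]
        for name in self.params.index:
            units = "" if name == "s0" else self.axis.rate_units
            lines.append(
                f"{name:<8}{self.params[name]:>14.6g}{self.bse[name]:>12.3g}  {units}"
            )
        if not self.model.fit_s0:
            lines.append(f"{'s0':<8}{self.s0:>14.6g}{'(fixed)':>12}")
        if self.at_bound:
            lines.append(f"at bound: {', '.join(self.at_bound)}")
        if self.dof <= 0:
            lines.append("standard errors withheld: no residual degrees of freedom")
        lines.append("=" * 62)
        return "\n".join(lines)

    def to_dict(self) -> dict[str, Any]:
        return {
            "package": {"name": "plasmidkinetics", "version": _pkg_version},
            "condition": self.model.data.condition,
            "axis": self.axis.value,
            "options": {
                "fit_s0": self.model.fit_s0,
                "variant": self.model.variant,
                "mode": self.model.mode,
                "sd_floor_pct": self.model.sd_floor_pct,
                "scale_cov": self.model.scale_cov,
                "mask_linear_above": self.model.mask_linear_above,
            },
            "params": {k: float(v) for k, v in self.params.items()},
            "bse": {k: float(v) for k, v in self.bse.items()},
            "s0": self.s0,
            "covariance": {
                "names": list(self.params.index),
                "matrix": self.cov.to_numpy().tolist(),
            },
            "diagnostics": {
                "wrss": self.wrss,
                "dof": self.dof,
                "n_obs": self.n_obs,
                "converged": self.converged,
                "message": self.message,
                "nfev": self.nfev,
                "at_bound": self.at_bound,
            },
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def read_fit_report(path: str | Path) -> dict[str, Any]:
    """Load a fit report written by :meth:`PlasmidKineticsResults.to_json`.

    Returns the raw dict augmented with ``ksr``/``krl`` as
    :class:`RateEstimate` and ``kinetic_params`` for downstream equivalence
    computations.
    """
    d = json.loads(Path(path).read_text())
    axis = ExposureAxis(d["axis"])
    d["ksr_estimate"] = RateEstimate(d["params"]["ksr"], d["bse"]["ksr"], axis)
    d["krl_estimate"] = RateEstimate(d["params"]["krl"], d["bse"]["krl"], axis)
    d["kinetic_params"] = KineticParams(
        ksr=d["params"]["ksr"],
        krl=d["params"]["krl"],
        s0=d["s0"],
        ksl=d["params"].get("ksl", 0.0),
        axis=axis,
    )
    return d
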