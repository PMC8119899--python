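"""Concentration-response and saturation-binding curve fitting.

Two models, exposed statsmodels-style (a model object built from data
whose ``fit()`` returns a results object with estimates, standard errors
and a ``summary()`` table):

* :class:`HillModel` — the four-parameter logistic

      y = a + (b - a) / (1 + 10^(nH (logEC50 - x))),

  with x = log10 of the agonist concentration in molar, a/b the minimum
  and maximum responses, EC50 the half-maximal concentration (reported as
  pEC50 = -log10 EC50) and nH the Hill slope.

* :class:`SaturationModel` — one-site specific binding

      B = Bmax L / (Kd + L),

  with L the free radioligand concentration in nM, Kd the equilibrium
  dissociation constant (nM) and Bmax the maximal binding (pmol/mg
  protein).

Fits are unweighted nonlinear least squares (scipy.optimize.curve_fit);
standard errors are asymptotic (square roots of the covariance diagonal).
When the table carries a ``replicate`` column, per-replicate fits supply
across-replicate SEMs alongside the pooled-fit asymptotic SEs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "AssayCurve",
    "HillParams",
    "BindingParams",
    "HillModel",
    "SaturationModel",
    "predict_hill",
    "fit_hill",
    "fit_saturation",
]


class FitConvergenceError(RuntimeError):
    """Nonlinear least squares failed to converge."""


@dataclass
class AssayCurve:
    """Tabular assay data plus (after fitting) the fitted parameters.

    ``data`` needs a response column and either concentration_M (dose
    response, molar) or ligand_nM (binding, nM); an optional replicate
    column groups repeated curves.  ``normalize`` divides responses by
    the maximum response before fitting (normalization to max ΔF).
    """

    data: pd.DataFrame
    normalize: bool = False
    fitted_params: object | None = None

    @classmethod
    def from_csv(cls, path, normalize: bool = False) -> "AssayCurve":
        return cls(pd.read_csv(path), normalize=normalize)

    def concentrations(self, column: str) -> np.ndarray:
        if column not in self.data.columns:
            raise ValueError(f"assay table lacks a {column!r} column")
        c = self.data[column].to_numpy(dtype=float)
        if np.any(c <= 0):
            raise ValueError("concentrations must be positive")
        return c

    def responses(self) -> np.ndarray:
        y = self.data["response"].to_numpy(dtype=float)
        if self.normalize:
            ymax = np.abs(y).max()
            if ymax == 0:
                raise ValueError("cannot normalize an all-zero response column")
            y = y / ymax
        return y


def predict_hill(params, x):
    """Logistic response at x = log10 concentration (M).

    ``params`` exposes a, b, pec50, nh (a :class:`HillParams` or any
    object with those attributes).
    """
    x = np.asarray(x, dtype=float)
    return params.a + (params.b - params.a) / (
        1.0 + 10.0 ** (params.nh * (-params.pec50 - x))
    )


@dataclass
class HillParams:
    """Fitted four-parameter-logistic parameters with standard errors."""

    a: float
    b: float
    pec50: float
    nh: float
    bse: dict[str, float] = field(default_factory=dict)
    replicate_sem: dict[str, float] | None = None
    n_obs: int = 0

    @property
    def ec50_m(self) -> float:
        return 10.0 ** (-self.pec50)

    def predict(self, x):
        return predict_hill(self, x)

    def summary(self) -> pd.DataFrame:
        rows = [
            ("a (min response)", self.a, self.bse.get("a")),
            ("b (max response)", self.b, self.bse.get("b")),
            ("pEC50 (-log10 M)", self.pec50, self.bse.get("pec50")),
            ("EC50 (uM)", self.ec50_m * 1e6, None),
            ("nH", self.nh, self.bse.get("nh")),
        ]
        df = pd.DataFrame(rows, columns=["parameter", "estimate", "se"])
        if self.replicate_sem:
            df["replicate_sem"] = df["parameter"].map(
                {
                    "a (min response)": self.replicate_sem.get("a"),
                    "b (max response)": self.replicate_sem.get("b"),
                    "pEC50 (-log10 M)": self.replicate_sem.get("pec50"),
                    "nH": self.replicate_sem.get("nh"),
                }
            )
        return df


@dataclass
class BindingParams:
    """Fitted one-site binding parameters with standard errors."""

    kd_nm: float
    bmax: float
    bse: dict[str, float] = field(default_factory=dict)
    replicate_sem: dict[str, float] | None = None
    n_obs: int = 0

    def predict(self, ligand_nm):
        L = np.asarray(ligand_nm, dtype=float)
        return self.bmax * L / (self.kd_nm + L)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                ("Kd (nM)", self.kd_nm, self.bse.get("kd_nm")),
                ("Bmax (pmol/mg)", self.bmax, self.bse.get("bmax")),
            ],
            columns=["parameter", "estimate", "se"],
        )


def _curve_fit(f, x, y, p0, param_names):
    if len(np.unique(x)) < len(p0):
        raise ValueError(
            f"need at least {len(p0)} distinct concentrations, got {len(np.unique(x))}"
        )
    if np.ptp(y) == 0:
        raise ValueError("degenerate flat response data: nothing to fit")
    try:
        popt, pcov = curve_fit(f, x, y, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise FitConvergenceError(f"curve fit did not converge: {exc}") from exc
    with np.errstate(invalid="ignore"):
        se = np.sqrt(np.diag(pcov))
    bse = {n: float(s) for n, s in zip(param_names, se)}
    return popt, bse


class HillModel:
    """Four-parameter logistic model of a concentration-response table."""

    param_names = ("a", "b", "pec50", "nh")

    def __init__(self, curve: AssayCurve):
        self.curve = curve
        self.x = np.log10(curve.concentrations("concentration_M"))
        self.y = curve.responses()

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, normalize: bool = False) -> "HillModel":
        return cls(AssayCurve(data, normalize=normalize))

    @staticmethod
    def _f(x, a, b, pec50, nh):
        return a + (b - a) / (1.0 + 10.0 ** (nh * (-pec50 - x)))

    def _start(self, x, y):
        # a = min response, b = max response, pEC50 = -x at half range, nH = 1
        a0, b0 = float(y.min()), float(y.max())
        half = (a0 + b0) / 2.0
        pec0 = -float(x[np.argmin(np.abs(y - half))])
        return [a0, b0, pec0, 1.0]

    def fit(self) -> HillParams:
        popt, bse = _curve_fit(self._f, self.x, self.y, self._start(self.x, self.y), self.param_names)
        rep_sem = self._replicate_sem()
        params = HillParams(
            a=float(popt[0]), b=float(popt[1]), pec50=float(popt[2]),
            nh=float(popt[3]), bse=bse, replicate_sem=rep_sem, n_obs=len(self.y),
        )
        self.curve.fitted_params = params
        return params

    def _replicate_sem(self):
        df = self.curve.data
        if "replicate" not in df.columns or df["replicate"].nunique() < 2:
            return None
        fits = []
        for _, g in df.groupby("replicate"):
            sub = AssayCurve(g.reset_index(drop=True), normalize=self.curve.normalize)
            try:
                p = HillModel(sub).fit_without_sem()
            except (ValueError, FitConvergenceError):
                continue
            fits.append([p.a, p.b, p.pec50, p.nh])
        if len(fits) < 2:
            return None
        arr = np.array(fits)
        sem = arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0])
        return dict(zip(self.param_names, sem.astype(float)))

    def fit_without_sem(self) -> HillParams:
        popt, bse = _curve_fit(self._f, self.x, self.y, self._start(self.x, self.y), self.param_names)
        return HillParams(
            a=float(popt[0]), b=float(popt[1]), pec50=float(popt[2]),
            nh=float(popt[3]), bse=bse, n_obs=len(self.y),
        )


class SaturationModel:
    """One-site saturation binding model B = Bmax L / (Kd + L)."""

    param_names = ("kd_nm", "bmax")

    def __init__(self, curve: AssayCurve):
        self.curve = curve
        self.L = curve.concentrations("ligand_nM")
        self.y = curve.responses()

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame) -> "SaturationModel":
        return cls(AssayCurve(data))

    @staticmethod
    def _f(L, kd, bmax):
        return bmax * L / (kd + L)

    def fit(self) -> BindingParams:
        if np.all(self.y == 0):
            raise ValueError("all-zero binding data: nothing to fit")
        bmax0 = float(self.y.max())
        half = bmax0 / 2.0
        kd0 = float(self.L[np.argmin(np.abs(self.y - half))])
        popt, bse = _curve_fit(self._f, self.L, self.y, [max(kd0, 1e-6), bmax0], self.param_names)
        rep_sem = self._replicate_sem()
        params = BindingParams(
            kd_nm=float(popt[0]), bmax=float(popt[1]), bse=bse,
            replicate_sem=rep_sem, n_obs=len(self.y),
        )
        if params.kd_nm <= 0 or params.bmax <= 0:
            raise FitConvergenceError(
                f"fit converged to non-physical parameters Kd={params.kd_nm}, Bmax={params.bmax}"
            )
        self.curve.fitted_params = params
        return params

    def _replicate_sem(self):
        df = self.curve.data
        if "replicate" not in df.columns or df["replicate"].nunique() < 2:
            return None
        fits = []
        for _, g in df.groupby("replicate"):
            sub = SaturationModel(AssayCurve(g.reset_index(drop=True)))
            try:
                popt, _ = _curve_fit(
                    sub._f, sub.L, sub.y, [max(float(sub.L.mean()), 1e-6), float(sub.y.max())],
                    self.param_names,
                )
            except (ValueError, FitConvergenceError):
                continue
            fits.append(popt)
        if len(fits) < 2:
            return None
        arr = np.array(fits)
        sem = arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0])
        return dict(zip(self.param_names, sem.astype(float)))


def fit_hill(curve: AssayCurve | pd.DataFrame, normalize: bool = False) -> HillParams:
    """Fit the four-parameter logistic to an assay table."""
    if isinstance(curve, pd.DataFrame):
        curve = AssayCurve(curve, normalize=normalize)
    return HillModel(curve).fit()


def fit_saturation(curve: AssayCurve | pd.DataFrame) -> BindingParams:
    """Fit the one-site saturation binding model to an assay table."""
    if isinstance(curve, pd.DataFrame):
        curve = AssayCurve(curve)
    return SaturationModel(curve).fit()
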