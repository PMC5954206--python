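"""Planar-biaxial datasets and GOH parameter estimation.

Material characterization follows the usual soft-tissue workflow: a specimen
is stretched along the circumferential and axial axes under several stretch-
ratio protocols, in-plane Cauchy stresses are recorded, and GOH parameters are
estimated by Nelder–Mead minimization of the squared stress residual

    SSE = sum_records (s_cc_model - s_cc_meas)^2 + (s_aa_model - s_aa_meas)^2 .

Plain Nelder–Mead is unconstrained, so parameter bounds (c10 > 0, k1 >= 0,
k2 > 0, alpha in [0, 90] deg, kappa in [0, 1/3]) are enforced by a smooth
reparameterization: log for the stiffness-like parameters, scaled logistic
for alpha and kappa.  Local minima are mitigated by seeded multi-start from
Latin-hypercube points plus one data-informed start, and the best minimum is
polished by repeated Nelder–Mead restarts.

Joint identifiability of (alpha, kappa) from two-axis data is known to be
weak; the contract of :func:`fit_goh` is recovery in stress space, not
parameter space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import qmc

from .constitutive import GOHParameters, biaxial_cauchy_stress

_CSV_COLS = ["protocol", "lambda_c", "lambda_a", "sigma_cc_pa", "sigma_aa_pa"]


class BiaxialDataError(ValueError):
    pass


class NonConvergenceError(RuntimeError):
    def __init__(self, msg, best=None):
        super().__init__(msg)
        self.best = best


@dataclass(frozen=True)
class BiaxialDataset:
    """Stretch pairs with measured in-plane Cauchy stresses, per protocol.

    ``records`` is a DataFrame with columns protocol, lambda_c, lambda_a,
    sigma_cc_pa, sigma_aa_pa.
    """

    records: pd.DataFrame
    specimen: str = ""
    region: str = ""

    def __post_init__(self):
        df = self.records
        missing = [c for c in _CSV_COLS if c not in df.columns]
        if missing:
            raise BiaxialDataError(f"dataset missing columns {missing}")
        if len(df) == 0:
            raise BiaxialDataError("empty biaxial dataset")
        lam = df[["lambda_c", "lambda_a"]].to_numpy(float)
        if np.any(lam < 1.0 - 1e-6):
            raise BiaxialDataError("stretches must be >= 1 - 1e-6")
        if not np.all(np.isfinite(df[_CSV_COLS[1:]].to_numpy(float))):
            raise BiaxialDataError("non-finite entries in dataset")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_protocols(self) -> int:
        return self.records["protocol"].nunique()

    @classmethod
    def from_csv(cls, path, specimen: str = "", region: str = "") -> "BiaxialDataset":
        return cls(pd.read_csv(path), specimen=specimen, region=region)

    def to_csv(self, path) -> None:
        self.records[_CSV_COLS].to_csv(path, index=False)


@dataclass
class FitResult:
    """Outcome of a GOH fit: parameters, objective, and restart diagnostics."""

    params: GOHParameters
    sse: float  # Pa^2
    n_restarts_used: int
    converged: bool
    trace: list = field(default_factory=list)  # best objective after each restart (Pa^2)


def _model_stresses(params: GOHParameters, df: pd.DataFrame):
    return biaxial_cauchy_stress(
        params, df["lambda_c"].to_numpy(float), df["lambda_a"].to_numpy(float)
    )


def residual_sse(params: GOHParameters, data: BiaxialDataset, weights=None) -> float:
    """Sum of squared stress residuals (Pa^2) over both components.

    ``weights`` may be ``None`` (unweighted), a per-record array, or
    ``"per_protocol"`` for equal total weight per protocol.
    """
    df = data.records
    scc, saa = _model_stresses(params, df)
    r2 = (scc - df["sigma_cc_pa"].to_numpy(float)) ** 2 + (
        saa - df["sigma_aa_pa"].to_numpy(float)
    ) ** 2
    if weights is None:
        w = 1.0
    elif isinstance(weights, str) and weights == "per_protocol":
        counts = df.groupby("protocol")["protocol"].transform("count").to_numpy(float)
        w = len(df) / (data.n_protocols * counts)
    else:
        w = np.asarray(weights, dtype=float)
    return float(np.sum(w * r2))


# --- bound-preserving reparameterization -----------------------------------

def _expit(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _logit(p):
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return np.log(p / (1 - p))


def _x_to_params(x, thickness_mm: float, label: str) -> GOHParameters:
    return GOHParameters(
        c10=float(np.exp(x[0])), k1=float(np.exp(x[1])), k2=float(np.exp(x[2])),
        alpha_deg=float(90.0 * _expit(x[3])), kappa=float(_expit(x[4]) / 3.0),
        thickness_mm=thickness_mm, label=label,
    )


def _params_to_x(p: GOHParameters):
    return np.array([
        np.log(p.c10), np.log(max(p.k1, 1e-8)), np.log(p.k2),
        _logit(p.alpha_deg / 90.0), _logit(min(p.kappa * 3.0, 1 - 1e-9)),
    ])


def _informed_start(data: BiaxialDataset) -> GOHParameters:
    """Heuristic start: c10 from the low-stretch secant stiffness, moderate fibers."""
    df = data.records
    lc = df["lambda_c"].to_numpy(float)
    la = df["lambda_a"].to_numpy(float)
    lr2 = 1.0 / (lc * la) ** 2
    denom = lc**2 - lr2
    mask = denom > 1e-6
    c10 = np.median(df["sigma_cc_pa"].to_numpy(float)[mask] / (2 * denom[mask]))
    c10 = float(np.clip(c10, 1e3, 1e6))
    return GOHParameters(c10=c10, k1=2.0 * c10, k2=5.0, alpha_deg=45.0, kappa=0.2,
                         thickness_mm=1.0, label="start")


_LHS_LO = np.array([np.log(5e3), np.log(5e3), np.log(0.2), _logit(10 / 90), _logit(0.1)])
_LHS_HI = np.array([np.log(5e5), np.log(3e6), np.log(40.0), _logit(80 / 90), _logit(0.95)])


def fit_goh(
    data: BiaxialDataset,
    n_restarts: int = 8,
    seed: int = 0,
    weights=None,
    thickness_mm: float | None = None,
    label: str | None = None,
    max_iter: int = 5000,
    tol: float = 1e-8,
    n_polish: int = 6,
) -> FitResult:
    """Estimate GOH parameters from a biaxial dataset by multi-start Nelder-Mead.

    Deterministic for a given ``seed``.  Raises :class:`NonConvergenceError`
    (with the best attempt attached) if no restart converges.
    """
    if len(data) < 10 or data.n_protocols < 2:
        raise BiaxialDataError(
            "fit requires >= 10 records over >= 2 distinct protocols "
            f"(got {len(data)} records, {data.n_protocols} protocols)"
        )
    df = data.records
    thickness = thickness_mm if thickness_mm is not None else 1.0
    lab = label if label is not None else (data.specimen or "fit")
    norm = float(np.sum(df[["sigma_cc_pa", "sigma_aa_pa"]].to_numpy(float) ** 2)) + 1.0

    def objective(x):
        try:
            p = _x_to_params(x, thickness, lab)
            return residual_sse(p, data, weights=weights) / norm
        except (ValueError, FloatingPointError, OverflowError):
            return 1e12

    sampler = qmc.LatinHypercube(d=5, seed=seed)
    starts = [_params_to_x(_informed_start(data))]
    if n_restarts > 1:
        u = sampler.random(n_restarts - 1)
        starts += list(_LHS_LO + u * (_LHS_HI - _LHS_LO))

    best_x, best_f, n_ok, trace = None, np.inf, 0, []
    opts = dict(maxiter=max_iter, maxfev=2 * max_iter, xatol=1e-10,
                fatol=tol * 1e-6, adaptive=True)
    for x0 in starts:
        res = minimize(objective, x0, method="Nelder-Mead", options=opts)
        if np.isfinite(res.fun):
            n_ok += 1
            if res.fun < best_f:
                best_f, best_x = res.fun, res.x
        trace.append(best_f * norm)

    if best_x is None:
        raise NonConvergenceError("all Nelder-Mead restarts failed", best=None)

    # polish: repeated NM restarts at the incumbent until stagnation
    for _ in range(n_polish):
        res = minimize(objective, best_x, method="Nelder-Mead", options=opts)
        if res.fun < best_f * (1.0 - 1e-12):
            best_f, best_x = res.fun, res.x
            trace.append(best_f * norm)
        else:
            break

    params = _x_to_params(best_x, thickness, lab)
    return FitResult(params=params, sse=best_f * norm, n_restarts_used=n_ok,
                     converged=n_ok > 0, trace=trace)
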