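"""Inverse Monte Carlo estimation of (mu_a, mu_sp) from Rd/Tt.

Given a diffuse-reflectance / total-transmittance pair measured on a
glass-sandwiched sample of known thickness, and fixed assumptions for
the anisotropy factor g and tissue refractive index n, the solver finds
the absorption and reduced scattering coefficients whose forward Monte
Carlo simulation reproduces the measurement.

Search strategy (two stages):

1. a log-spaced lookup table of forward simulations over the physiological
   (mu_a, mu_sp) range is interpolated bilinearly in log space to locate a
   starting point;
2. a Nelder-Mead simplex refines (log mu_a, log mu_sp) minimizing the
   combined relative misfit

       f = [(Rd_sim - Rd)/Rd]^2 + [(Tt_sim - Tt)/Tt]^2

   with every forward evaluation run on the same random seed (common
   random numbers), which makes f a deterministic, optimizable function
   despite Monte Carlo noise. Convergence: sqrt(f) <= tol (default 0.01)
   within max_iter forward evaluations.

Relative (not absolute) residuals keep Rd and Tt comparable despite
their different magnitudes. Solutions pinned at the search-range bounds
are flagged non-converged rather than silently clipped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from . import mc

__all__ = [
    "NonPhysicalMeasurementError",
    "MeasurementRecord",
    "OpticalProperties",
    "InversionResult",
    "LookupTable",
    "SolverConfig",
    "build_lookup",
    "DoubleSphereInversion",
    "invert_single",
    "invert_spectrum",
    "average_replicates",
]


class NonPhysicalMeasurementError(ValueError):
    """Rd + Tt >= 1 cannot come from an absorbing/lossy sample."""


@dataclass(frozen=True)
class MeasurementRecord:
    wavelength_nm: float
    Rd: float
    Tt: float
    thickness_mm: float
    replicate: str | int = 0

    def __post_init__(self):
        if self.Rd < 0 or self.Tt < 0:
            raise ValueError("Rd and Tt must be >= 0")
        if self.Rd + self.Tt >= 1:
            raise NonPhysicalMeasurementError(
                f"Rd + Tt = {self.Rd + self.Tt:.4f} >= 1"
            )
        if self.thickness_mm <= 0:
            raise ValueError("thickness_mm must be > 0")


@dataclass(frozen=True)
class OpticalProperties:
    mu_a: float
    mu_sp: float

    def __post_init__(self):
        if not (np.isfinite(self.mu_a) and np.isfinite(self.mu_sp)):
            raise ValueError("optical properties must be finite")
        if self.mu_a < 0 or self.mu_sp < 0:
            raise ValueError("optical properties must be >= 0")


@dataclass(frozen=True)
class InversionResult:
    props: OpticalProperties
    residual: float          # sqrt(f) at the accepted solution
    iterations: int          # forward evaluations spent in refinement
    converged: bool
    forward_se: tuple[float, float]  # (se_Rd, se_Tt) at the solution
    at_bound: bool = False
    Rd_fit: float = float("nan")
    Tt_fit: float = float("nan")


@dataclass(frozen=True)
class SolverConfig:
    tol: float = 0.01
    max_iter: int = 200
    n_photons_iter: int = 100_000
    n_photons_final: int = 1_000_000
    lut_shape: tuple[int, int] = (10, 10)
    lut_n_photons: int = 100_000
    mu_a_bounds: tuple[float, float] = (0.01, 5.0)
    mu_sp_bounds: tuple[float, float] = (0.1, 10.0)
    seed: int = 12345
    beam: mc.BeamGeometry = field(default_factory=mc.BeamGeometry)
    detector: mc.DetectorGeometry = field(default_factory=mc.DetectorGeometry)


@dataclass(frozen=True)
class LookupTable:
    """Forward (Rd, Tt) surfaces on a log-spaced (mu_a, mu_sp) grid."""

    mu_a_grid: np.ndarray
    mu_sp_grid: np.ndarray
    Rd: np.ndarray  # (n_mu_a, n_mu_sp)
    Tt: np.ndarray
    thickness_mm: float
    g: float
    n: float
    seed: int
    n_photons: int

    def interpolators(self):
        pts = (np.log(self.mu_a_grid), np.log(self.mu_sp_grid))
        f_rd = RegularGridInterpolator(pts, self.Rd, bounds_error=False,
                                       fill_value=None)
        f_tt = RegularGridInterpolator(pts, self.Tt, bounds_error=False,
                                       fill_value=None)
        return f_rd, f_tt


def _forward(mu_a, mu_sp, thickness, g, n, beam, detector, n_photons, seed):
    stack = mc.build_slab(mu_a=mu_a, mu_sp=mu_sp, sample_thickness=thickness,
                          g=g, n=n)
    return mc.simulate_rt(stack, beam=beam, detector=detector,
                          n_photons=n_photons, seed=seed)


def build_lookup(
    thickness_mm: float,
    g: float = 0.9,
    n: float = 1.4,
    cfg: SolverConfig | None = None,
) -> LookupTable:
    """One forward simulation per log-spaced grid node; reproducible."""
    cfg = cfg if cfg is not None else SolverConfig()
    n_a, n_s = cfg.lut_shape
    if n_a < 2 or n_s < 2:
        raise ValueError("lookup grid needs at least 2 nodes per axis")
    mu_a_grid = np.geomspace(*cfg.mu_a_bounds, n_a)
    mu_sp_grid = np.geomspace(*cfg.mu_sp_bounds, n_s)
    rd = np.empty((n_a, n_s))
    tt = np.empty((n_a, n_s))
    for i, mu_a in enumerate(mu_a_grid):
        for j, mu_sp in enumerate(mu_sp_grid):
            res = _forward(mu_a, mu_sp, thickness_mm, g, n,
                           cfg.beam, cfg.detector, cfg.lut_n_photons, cfg.seed)
            rd[i, j] = res.Rd
            tt[i, j] = res.Tt
    return LookupTable(mu_a_grid=mu_a_grid, mu_sp_grid=mu_sp_grid,
                       Rd=rd, Tt=tt, thickness_mm=thickness_mm,
                       g=g, n=n, seed=cfg.seed, n_photons=cfg.lut_n_photons)


class _Converged(Exception):
    pass


class DoubleSphereInversion(BaseEstimator):
    """Per-wavelength inverse Monte Carlo solver, sklearn-style.

    ``fit`` takes a measurement table (columns ``wavelength_nm``, ``Rd``,
    ``Tt``, ``thickness_mm`` and optionally ``sample_id``/``replicate``)
    and recovers one (mu_a, mu_sp) pair per row, independently per
    wavelength — no smoothing across the spectrum.

    Parameters mirror :class:`SolverConfig` plus the fixed optical
    assumptions ``g`` and ``n``. Lookup tables are cached per (thickness,
    g, n) within one estimator instance.

    Attributes (after fit)
    ----------------------
    results_ : DataFrame
        Per-record recovered mu_a, mu_sp, residual, iterations, converged.
    spectrum_ : DataFrame
        Per-wavelength mean and sample SD (ddof=1; NaN for one record)
        across records.
    """

    def __init__(self, g=0.9, n=1.4, tol=0.01, max_iter=200,
                 n_photons_iter=100_000, n_photons_final=1_000_000,
                 lut_shape=(10, 10), lut_n_photons=100_000,
                 mu_a_bounds=(0.01, 5.0), mu_sp_bounds=(0.1, 10.0),
                 seed=12345):
        self.g = g
        self.n = n
        self.tol = tol
        self.max_iter = max_iter
        self.n_photons_iter = n_photons_iter
        self.n_photons_final = n_photons_final
        self.lut_shape = lut_shape
        self.lut_n_photons = lut_n_photons
        self.mu_a_bounds = mu_a_bounds
        self.mu_sp_bounds = mu_sp_bounds
        self.seed = seed

    # -- internals ---------------------------------------------------

    def _cfg(self) -> SolverConfig:
        return SolverConfig(
            tol=self.tol, max_iter=self.max_iter,
            n_photons_iter=self.n_photons_iter,
            n_photons_final=self.n_photons_final,
            lut_shape=tuple(self.lut_shape),
            lut_n_photons=self.lut_n_photons,
            mu_a_bounds=tuple(self.mu_a_bounds),
            mu_sp_bounds=tuple(self.mu_sp_bounds),
            seed=self.seed,
        )

    def lookup_for(self, thickness_mm: float) -> LookupTable:
        if not hasattr(self, "_lut_cache"):
            self._lut_cache = {}
        key = (round(float(thickness_mm), 9), self.g, self.n)
        if key not in self._lut_cache:
            self._lut_cache[key] = build_lookup(thickness_mm, g=self.g,
                                                n=self.n, cfg=self._cfg())
        return self._lut_cache[key]

    def _invert_one(self, record: MeasurementRecord,
                    lut: LookupTable | None = None) -> InversionResult:
        cfg = self._cfg()
        lut = lut if lut is not None else self.lookup_for(record.thickness_mm)
        rd_meas = max(record.Rd, 1e-6)
        tt_meas = max(record.Tt, 1e-6)
        lo = np.log([cfg.mu_a_bounds[0], cfg.mu_sp_bounds[0]])
        hi = np.log([cfg.mu_a_bounds[1], cfg.mu_sp_bounds[1]])

        # stage 1: interpolated-lookup initialization
        f_rd, f_tt = lut.interpolators()

        def lut_objective(x):
            rd, tt = f_rd(x).item(), f_tt(x).item()
            return (((rd - rd_meas) / rd_meas) ** 2
                    + ((tt - tt_meas) / tt_meas) ** 2)

        la = np.linspace(lo[0], hi[0], 60)
        ls = np.linspace(lo[1], hi[1], 60)
        ga, gs = np.meshgrid(la, ls, indexing="ij")
        pts = np.column_stack([ga.ravel(), gs.ravel()])
        rd_i = f_rd(pts)
        tt_i = f_tt(pts)
        fgrid = (((rd_i - rd_meas) / rd_meas) ** 2
                 + ((tt_i - tt_meas) / tt_meas) ** 2)
        x0 = pts[int(np.argmin(fgrid))]
        pre = minimize(lut_objective, x0, method="Nelder-Mead",
                       options={"maxiter": 120, "xatol": 1e-3, "fatol": 1e-8})
        x0 = pre.x

        # stage 2: simplex on the true forward model, common random numbers
        state = {"best_f": np.inf, "best_x": x0, "nfev": 0}

        def objective(x):
            state["nfev"] += 1
            # soft penalty keeps the simplex inside the searched range
            pen = 0.0
            for k in range(2):
                if x[k] < lo[k]:
                    pen += 100.0 * (lo[k] - x[k]) ** 2
                elif x[k] > hi[k]:
                    pen += 100.0 * (x[k] - hi[k]) ** 2
            xc = np.clip(x, lo, hi)
            res = _forward(math.exp(xc[0]), math.exp(xc[1]),
                           record.thickness_mm, self.g, self.n,
                           cfg.beam, cfg.detector, cfg.n_photons_iter,
                           cfg.seed)
            f = (((res.Rd - rd_meas) / rd_meas) ** 2
                 + ((res.Tt - tt_meas) / tt_meas) ** 2) + pen
            if f < state["best_f"]:
                state["best_f"] = f
                state["best_x"] = np.clip(np.array(x), lo, hi)
            if f <= cfg.tol ** 2:
                raise _Converged
            if state["nfev"] >= cfg.max_iter:
                raise _Converged
            return f

        step = 0.15
        simplex = np.array([x0, x0 + [step, 0.0], x0 + [0.0, step]])
        try:
            minimize(objective, x0, method="Nelder-Mead",
                     options={"maxiter": cfg.max_iter,
                              "initial_simplex": simplex,
                              "xatol": 5e-4, "fatol": 1e-9})
        except _Converged:
            pass

        xb = state["best_x"]
        residual = math.sqrt(min(state["best_f"], np.inf))
        mu_a, mu_sp = math.exp(xb[0]), math.exp(xb[1])
        eps = 1e-9
        at_bound = bool(np.any(xb <= lo + eps) or np.any(xb >= hi - eps))
        converged = residual <= cfg.tol and not at_bound

        final = _forward(mu_a, mu_sp, record.thickness_mm, self.g, self.n,
                         cfg.beam, cfg.detector, cfg.n_photons_final,
                         cfg.seed + 1)
        return InversionResult(
            props=OpticalProperties(mu_a=mu_a, mu_sp=mu_sp),
            residual=residual,
            iterations=state["nfev"],
            converged=converged,
            forward_se=(final.se_Rd, final.se_Tt),
            at_bound=at_bound,
            Rd_fit=final.Rd,
            Tt_fit=final.Tt,
        )

    # -- sklearn surface ----------------------------------------------

    def fit(self, X: pd.DataFrame, y=None):
        """Invert every record of a measurement table independently."""
        required = {"wavelength_nm", "Rd", "Tt", "thickness_mm"}
        missing = required - set(X.columns)
        if missing:
            raise ValueError(f"measurement table lacks columns {sorted(missing)}")
        if len(X) == 0:
            raise ValueError("empty measurement table")
        rows = []
        for _, r in X.iterrows():
            rec = MeasurementRecord(
                wavelength_nm=float(r["wavelength_nm"]),
                Rd=float(r["Rd"]), Tt=float(r["Tt"]),
                thickness_mm=float(r["thickness_mm"]),
                replicate=r.get("replicate", 0),
            )
            try:
                res = self._invert_one(rec)
                failed = False
            except NonPhysicalMeasurementError:
                raise
            except Exception:  # pragma: no cover - defensive flagging
                res = None
                failed = True
            row = {
                "wavelength_nm": rec.wavelength_nm,
                "sample_id": r.get("sample_id", "sample_00"),
                "replicate": rec.replicate,
                "thickness_mm": rec.thickness_mm,
                "failed": failed,
            }
            if res is not None:
                row.update(
                    mu_a=res.props.mu_a, mu_sp=res.props.mu_sp,
                    residual=res.residual, iterations=res.iterations,
                    converged=res.converged, at_bound=res.at_bound,
                )
            else:
                row.update(mu_a=np.nan, mu_sp=np.nan, residual=np.nan,
                           iterations=0, converged=False, at_bound=False)
            rows.append(row)
        self.results_ = pd.DataFrame(rows)
        ok = self.results_
        grouped = ok.groupby("wavelength_nm")
        self.spectrum_ = pd.DataFrame(
            {
                "wavelength_nm": list(grouped.groups),
                "mu_a": grouped["mu_a"].mean().to_numpy(),
                "mu_a_sd": grouped["mu_a"].std(ddof=1).to_numpy(),
                "mu_sp": grouped["mu_sp"].mean().to_numpy(),
                "mu_sp_sd": grouped["mu_sp"].std(ddof=1).to_numpy(),
                "n_records": grouped.size().to_numpy(),
            }
        )
        return self


def invert_single(
    record: MeasurementRecord | dict,
    g: float = 0.9,
    n: float = 1.4,
    lut: LookupTable | None = None,
    cfg: SolverConfig | None = None,
) -> InversionResult:
    """Recover (mu_a, mu_sp) for one measurement record."""
    if isinstance(record, dict):
        record = MeasurementRecord(**record)
    cfg = cfg if cfg is not None else SolverConfig()
    est = DoubleSphereInversion(
        g=g, n=n, tol=cfg.tol, max_iter=cfg.max_iter,
        n_photons_iter=cfg.n_photons_iter,
        n_photons_final=cfg.n_photons_final, lut_shape=cfg.lut_shape,
        lut_n_photons=cfg.lut_n_photons, mu_a_bounds=cfg.mu_a_bounds,
        mu_sp_bounds=cfg.mu_sp_bounds, seed=cfg.seed,
    )
    return est._invert_one(record, lut=lut)


def invert_spectrum(
    records: pd.DataFrame,
    g: float = 0.9,
    n: float = 1.4,
    cfg: SolverConfig | None = None,
) -> DoubleSphereInversion:
    """Invert a spectrum of measurement records; returns the fitted solver."""
    cfg = cfg if cfg is not None else SolverConfig()
    est = DoubleSphereInversion(
        g=g, n=n, tol=cfg.tol, max_iter=cfg.max_iter,
        n_photons_iter=cfg.n_photons_iter,
        n_photons_final=cfg.n_photons_final, lut_shape=cfg.lut_shape,
        lut_n_photons=cfg.lut_n_photons, mu_a_bounds=cfg.mu_a_bounds,
        mu_sp_bounds=cfg.mu_sp_bounds, seed=cfg.seed,
    )
    return est.fit(records)


def average_replicates(records: pd.DataFrame) -> pd.DataFrame:
    """Mean Rd/Tt over replicates per (sample, wavelength) — the measured
    value convention for triplicate DIS scans."""
    keys = [k for k in ("sample_id", "wavelength_nm", "thickness_mm")
            if k in records.columns]
    out = records.groupby(keys, as_index=False)[["Rd", "Tt"]].mean()
    return out.sort_values(keys).reset_index(drop=True)
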