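"""Projected light penetration depth from tissue optical properties.

In the diffusion regime (mu_a << 3 mu_s') the fluence of a broad beam
decays as exp(-z/delta) with

    delta = 1 / sqrt(3 mu_a (mu_a + mu_s'))

delta is the projected light penetration depth (mm). The ratio
mu_a / (3 mu_s') gauges how well the diffusion condition holds; values
above ~0.1 mean delta is an extrapolation rather than a faithful depth,
which is flagged but not refused.

Cohort spectra are aggregated per-sample-first: delta is evaluated for
every sample at every wavelength and then averaged, which is not the
same as evaluating delta at the cohort-mean optical properties (delta is
convex in mu_a, so the mean of per-sample depths is slightly larger).
Both modes are available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "PenetrationDepth",
    "RatioSummary",
    "PenetrationDepthTransform",
    "penetration_depth",
    "depth_spectrum",
    "compare_depths",
]

VALIDITY_WARNING_RATIO = 0.1


@dataclass(frozen=True)
class PenetrationDepth:
    delta: float
    validity_ratio: float

    @property
    def diffusion_valid(self) -> bool:
        return self.validity_ratio <= VALIDITY_WARNING_RATIO


@dataclass(frozen=True)
class RatioSummary:
    """Per-wavelength comparison of two depth spectra over a band."""

    wavelengths: np.ndarray
    values: np.ndarray
    band: tuple[float, float]
    mode: str

    @property
    def band_min(self) -> float:
        return float(np.min(self.values))

    @property
    def band_max(self) -> float:
        return float(np.max(self.values))


class PenetrationDepthTransform(TransformerMixin, BaseEstimator):
    """Map (mu_a, mu_sp) pairs to (delta, validity_ratio).

    Stateless transformer; ``fit`` only validates input so the class
    composes with sklearn pipelines.

    Parameters
    ----------
    warn_ratio : float
        Diffusion-validity threshold on mu_a / (3 mu_sp).
    """

    def __init__(self, warn_ratio: float = VALIDITY_WARNING_RATIO):
        self.warn_ratio = warn_ratio

    def fit(self, X, y=None):
        self._validate(np.asarray(X, dtype=float))
        self.n_features_in_ = 2
        return self

    @staticmethod
    def _validate(X):
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n_samples, 2): columns mu_a, mu_sp")
        if not np.all(np.isfinite(X)):
            raise ValueError("optical properties must be finite")
        if np.any(X[:, 0] <= 0):
            raise ValueError("penetration depth is undefined for mu_a <= 0")
        if np.any(X[:, 1] < 0):
            raise ValueError("mu_sp must be >= 0")
        return X

    def transform(self, X):
        X = self._validate(np.asarray(X, dtype=float))
        mu_a, mu_sp = X[:, 0], X[:, 1]
        delta = 1.0 / np.sqrt(3.0 * mu_a * (mu_a + mu_sp))
        with np.errstate(divide="ignore", over="ignore"):
            ratio = np.where(mu_sp > 0, mu_a / (3.0 * mu_sp), np.inf)
        return np.column_stack([delta, ratio])


def penetration_depth(mu_a: float, mu_sp: float) -> PenetrationDepth:
    """delta = 1/sqrt(3 mu_a (mu_a + mu_sp)) for one wavelength (mm)."""
    out = PenetrationDepthTransform().fit_transform([[mu_a, mu_sp]])
    return PenetrationDepth(delta=float(out[0, 0]), validity_ratio=float(out[0, 1]))


def depth_spectrum(props: pd.DataFrame, aggregate: str = "per_sample") -> pd.DataFrame:
    """Depth spectrum with cohort mean and SD.

    Parameters
    ----------
    props : DataFrame
        Columns ``wavelength_nm``, ``mu_a``, ``mu_sp`` and optionally
        ``sample_id``. With a ``sample_id`` column and
        ``aggregate='per_sample'``, delta is computed per sample and then
        averaged across the cohort (sample SD, ddof=1); otherwise each
        row is treated as a single mean-property spectrum and the SD
        column is NaN.

    Returns
    -------
    DataFrame with columns wavelength_nm, delta, delta_sd, validity_ratio
    (validity at the cohort-mean properties).
    """
    if len(props) == 0:
        raise ValueError("empty optical-property spectrum")
    if aggregate not in ("per_sample", "mean_properties"):
        raise ValueError(f"unknown aggregate mode {aggregate!r}")
    props = props.copy()
    if "sample_id" not in props.columns or aggregate == "mean_properties":
        if aggregate == "mean_properties" and "sample_id" in props.columns:
            props = (
                props.groupby("wavelength_nm", as_index=False)[["mu_a", "mu_sp"]].mean()
            )
        tr = PenetrationDepthTransform().fit_transform(props[["mu_a", "mu_sp"]])
        return pd.DataFrame(
            {
                "wavelength_nm": props["wavelength_nm"].to_numpy(),
                "delta": tr[:, 0],
                "delta_sd": np.nan,
                "validity_ratio": tr[:, 1],
            }
        )

    tr = PenetrationDepthTransform().fit_transform(props[["mu_a", "mu_sp"]])
    props["delta"] = tr[:, 0]
    grouped = props.groupby("wavelength_nm")
    out = grouped["delta"].agg(["mean", "std"]).reset_index()
    mean_props = grouped[["mu_a", "mu_sp"]].mean()
    validity = mean_props["mu_a"] / (3.0 * mean_props["mu_sp"])
    return pd.DataFrame(
        {
            "wavelength_nm": out["wavelength_nm"].to_numpy(),
            "delta": out["mean"].to_numpy(),
            "delta_sd": out["std"].to_numpy(),  # NaN for single-sample cohorts
            "validity_ratio": validity.to_numpy(),
        }
    )


def compare_depths(
    a: pd.DataFrame,
    b: pd.DataFrame,
    band: tuple[float, float] = (400.0, 700.0),
    mode: str = "ratio",
) -> RatioSummary:
    """Per-wavelength comparison of two depth spectra over a band.

    ``ratio`` returns b/a (how much deeper b penetrates than a);
    ``fractional_difference`` returns (a - b)/a (the fractional reduction
    of b relative to a). Spectra must share the wavelength grid over the
    band.
    """
    if mode not in ("ratio", "fractional_difference"):
        raise ValueError(f"unknown comparison mode {mode!r}")
    lo, hi = band
    if lo > hi:
        raise ValueError("band_min must be <= band_max")
    a_band = a[(a["wavelength_nm"] >= lo) & (a["wavelength_nm"] <= hi)]
    b_band = b[(b["wavelength_nm"] >= lo) & (b["wavelength_nm"] <= hi)]
    common = np.intersect1d(
        a_band["wavelength_nm"].to_numpy(), b_band["wavelength_nm"].to_numpy()
    )
    if common.size == 0:
        raise ValueError("no shared wavelengths inside the band")
    da = a_band.set_index("wavelength_nm").loc[common, "delta"].to_numpy()
    db = b_band.set_index("wavelength_nm").loc[common, "delta"].to_numpy()
    if mode == "ratio":
        values = db / da
    else:
        values = (da - db) / da
    return RatioSummary(wavelengths=common, values=values, band=(lo, hi), mode=mode)
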