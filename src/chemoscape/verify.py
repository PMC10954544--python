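"""Composite origin-claim verification.

A claim "this sample was harvested in territory c" is rejected only if every
candidate location inside c is rejected.  At each grid cell x the variance-
normalized squared residual

    S(x) = sum_j (y*_j - mu_j(x))^2 / sigma_j^2(x)

follows a chi-squared distribution with m degrees of freedom under the
hypothesis that the sample comes from x (variables treated as independent
given location).  The claim's p-value is the maximum of the per-cell
p-values over the territory, and the claim is rejected when that maximum
falls strictly below the significance level alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .data_model import StudyGrid


@dataclass(frozen=True)
class VerificationResult:
    """Outcome of a single origin-claim test."""

    sample_id: str
    territory_id: str
    scale: str
    p_value: float
    s_at_argmax: float
    argmax_lon: float
    argmax_lat: float
    df: int
    alpha: float

    @property
    def reject(self) -> bool:
        """Strict inequality: reject iff p < alpha."""
        return decide(self.p_value, self.alpha) == "reject"

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "territory_id": self.territory_id,
            "scale": self.scale,
            "p_value": self.p_value,
            "S_at_argmax": self.s_at_argmax,
            "argmax_lon": self.argmax_lon,
            "argmax_lat": self.argmax_lat,
            "df": self.df,
            "decision": "reject" if self.reject else "not_reject",
        }


def residual_statistic(y_star: np.ndarray, mean: np.ndarray, variance: np.ndarray) -> tuple[float, int]:
    """Variance-normalized squared-residual statistic and its df.

    Missing entries of ``y_star`` (NaN) are skipped and the degrees of
    freedom reduced accordingly.  With unit variances S is the squared
    Euclidean distance between the observed and predicted vectors.
    """
    y = np.asarray(y_star, float)
    mu = np.asarray(mean, float)
    var = np.asarray(variance, float)
    ok = np.isfinite(y)
    if not ok.any():
        raise ValueError("all chemistry values are missing for this sample")
    if np.any(var[ok] <= 0):
        raise ValueError("non-positive predictive variance")
    resid = y[ok] - mu[ok]
    return float(np.sum(resid * resid / var[ok])), int(ok.sum())


def territory_pvalue(
    y_star: np.ndarray,
    ensemble,
    region_cells: np.ndarray,
    grid: StudyGrid,
    alpha: float = 0.05,
    sample_id: str = "",
    territory_id: str = "",
    scale: str = "custom",
    standardized: bool = False,
) -> VerificationResult:
    """Max-p composite test of a claim over the territory's grid cells.

    ``y_star`` is a raw chemistry vector aligned to the ensemble panel
    (standardized internally unless ``standardized=True``).  The per-cell
    p-value is the chi-squared survival function of S(x) at the df given by
    the number of non-missing variables; the reported p is the maximum over
    cells, attained at ``(argmax_lon, argmax_lat)`` (ties resolved to the
    lowest row-major cell index).
    """
    region_cells = np.asarray(region_cells, int)
    if len(region_cells) == 0:
        raise ValueError("empty territory: no grid cells to test")
    y = np.asarray(y_star, float)
    if not standardized:
        y = ensemble.transform(y)
    ok = np.isfinite(y)
    if not ok.any():
        raise ValueError("all chemistry values are missing for this sample")
    df = int(ok.sum())
    coords = grid.coords[region_cells]
    means, variances = ensemble.predict(coords)
    resid = y[None, ok] - means[:, ok]
    s_cells = np.sum(resid * resid / variances[:, ok], axis=1)
    # survival function directly for numerical stability at large S
    p_cells = chi2.sf(s_cells, df)
    best = int(np.argmax(p_cells))  # first max -> lowest row-major index
    return VerificationResult(
        sample_id=sample_id,
        territory_id=territory_id,
        scale=scale,
        p_value=float(p_cells[best]),
        s_at_argmax=float(s_cells[best]),
        argmax_lon=float(coords[best, 0]),
        argmax_lat=float(coords[best, 1]),
        df=df,
        alpha=alpha,
    )


def decide(p_value: float, alpha: float) -> str:
    """``"reject"`` iff p < alpha (strict), else ``"not_reject"``."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return "reject" if p_value < alpha else "not_reject"
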