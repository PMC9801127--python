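"""Downstream numerics: Michaelis-Menten fits, OLS with r², group tests.

The kinetic fit estimates (Km, Vmax) of v = Vmax*S/(Km + S) by bounded
nonlinear least squares; no Lineweaver-Burk linearization is used anywhere
(reciprocal transforms bias both parameters).  Linear regression reports
slope, intercept and r² for method-agreement plots; replicate group
comparisons use Welch's two-sample t-test (unequal variances, small n).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps


def michaelis_menten(s, vmax: float, km: float):
    """Initial velocity v = Vmax * S / (Km + S)."""
    s = np.asarray(s, dtype=float)
    return vmax * s / (km + s)


@dataclass(frozen=True)
class KineticDataset:
    """Substrate concentrations (μM) and initial velocities, with replicates."""

    concentrations: tuple[float, ...]
    velocities: tuple[float, ...]
    replicates: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.concentrations) != len(self.velocities):
            raise ValueError("concentrations and velocities differ in length")
        if self.replicates is not None and len(self.replicates) != len(self.velocities):
            raise ValueError("replicate ids differ in length")
        if any(s < 0 for s in self.concentrations):
            raise ValueError("negative substrate concentration")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "KineticDataset":
        df = pd.read_csv(path, sep="\t")
        reps = tuple(int(r) for r in df["replicate"]) if "replicate" in df.columns else None
        return cls(
            concentrations=tuple(float(s) for s in df["S"]),
            velocities=tuple(float(v) for v in df["v"]),
            replicates=reps,
        )


@dataclass(frozen=True)
class KineticFit:
    km: float
    vmax: float
    rss: float
    converged: bool
    km_stderr: float = float("nan")
    vmax_stderr: float = float("nan")

    @property
    def identifiable(self) -> bool:
        """False when the fit converged only formally (e.g. Km unconstrained
        because every concentration is saturating)."""
        return (
            self.converged
            and np.isfinite(self.km_stderr)
            and self.km_stderr < 0.5 * abs(self.km)
        )


def simulate_kinetic_dataset(
    km: float,
    vmax: float,
    concentrations: Sequence[float],
    *,
    noise_cv: float = 0.03,
    n_replicates: int = 3,
    seed: int = 0,
) -> KineticDataset:
    """Generate replicate initial-velocity data from known (Km, Vmax).

    Velocities carry multiplicative Gaussian noise with coefficient of
    variation ``noise_cv`` (0 for noiseless data); used for parameter
    recovery checks of the fitter.
    """
    rng = np.random.default_rng(seed)
    s_all, v_all, reps = [], [], []
    for rep in range(n_replicates):
        s = np.asarray(concentrations, dtype=float)
        v = michaelis_menten(s, vmax, km)
        if noise_cv > 0:
            v = v * (1.0 + noise_cv * rng.standard_normal(len(s)))
        s_all.extend(s)
        v_all.extend(v)
        reps.extend([rep] * len(s))
    return KineticDataset(
        concentrations=tuple(s_all), velocities=tuple(v_all), replicates=tuple(reps)
    )


def fit_michaelis_menten(data: KineticDataset) -> KineticFit:
    """Fit (Km, Vmax) by bounded nonlinear least squares.

    Initialization: Vmax0 = max(v), Km0 = the concentration whose velocity
    is closest to Vmax0/2; both parameters bounded positive.  Negative
    velocities are clipped to zero with a warning.  Non-convergence is
    reported in the ``converged`` flag rather than raised, and a fit whose
    Km standard error dwarfs the estimate is flagged non-identifiable.
    """
    s = np.asarray(data.concentrations, dtype=float)
    v = np.asarray(data.velocities, dtype=float)
    if len(set(s.tolist())) < 3:
        raise ValueError("need at least 3 distinct substrate concentrations")
    if np.any(v < 0):
        warnings.warn("negative velocities clipped to 0 before fitting", stacklevel=2)
        v = np.clip(v, 0.0, None)

    vmax0 = float(np.max(v))
    if vmax0 <= 0:
        return KineticFit(km=float("nan"), vmax=float("nan"), rss=float("nan"), converged=False)
    km0 = float(s[np.argmin(np.abs(v - vmax0 / 2.0))])
    km0 = max(km0, 1e-9)
    try:
        popt, pcov = optimize.curve_fit(
            michaelis_menten,
            s,
            v,
            p0=[vmax0, km0],
            bounds=([1e-12, 1e-12], [np.inf, np.inf]),
            # velocities can be orders of magnitude below 1; scale the
            # problem and tighten tolerances so the optimum is resolved
            # well past 4 significant digits
            x_scale=[vmax0, km0],
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
            maxfev=10000,
        )
    except RuntimeError:
        return KineticFit(km=float("nan"), vmax=float("nan"), rss=float("nan"), converged=False)
    vmax_hat, km_hat = float(popt[0]), float(popt[1])
    rss = float(np.sum((v - michaelis_menten(s, *popt)) ** 2))
    with np.errstate(invalid="ignore"):
        perr = np.sqrt(np.diag(pcov))
    return KineticFit(
        km=km_hat,
        vmax=vmax_hat,
        rss=rss,
        converged=True,
        km_stderr=float(perr[1]),
        vmax_stderr=float(perr[0]),
    )


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float


def linear_fit_r2(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Ordinary least squares with r² = 1 - SS_res/SS_tot."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("x and y must have equal length >= 2")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope undefined")
    res = sps.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def compare_groups(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Welch t-test p-value between replicate rate groups.

    Degenerate inputs (both groups constant) return p = 1 for equal means
    and p = 0 otherwise, by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 values per group")
    if np.var(a) == 0 and np.var(b) == 0:
        return 1.0 if np.mean(a) == np.mean(b) else 0.0
    return float(sps.ttest_ind(a, b, equal_var=False).pvalue)
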