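"""Inverse problem: fit the two-layer diffuse model to measured spectra.

Each cluster's mean reflectance spectrum over the working bands is fitted
by bounded trust-region nonlinear least squares, minimizing the sum of
squared residuals between modeled and measured reflectance.  The landscape
is non-convex and, with all four parameters free, under-determined, so the
fit is multi-started from a seeded Latin-hypercube of initial points and
the best incumbent is returned (flagged if not converged).  The blood
fraction spans six decades and is optimized in log10 space internally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .errors import FitError
from .optics import (
    B_BOUNDS,
    DE_BOUNDS_UM,
    M_BOUNDS,
    ChromophoreTable,
    SkinParams,
    forward_reflectance,
)
from .segmentation import ClusterResult

logger = logging.getLogger(__name__)

#: optimizer box per free parameter (B handled in log10 space internally)
PARAM_BOUNDS = {
    "B": B_BOUNDS,
    "SO2": (0.0, 1.0),
    "M": M_BOUNDS,
    "d_e_um": DE_BOUNDS_UM,
}
DEFAULT_FREE = ("B", "SO2", "M", "d_e_um")
_LOG_PARAMS = ("B",)


@dataclass
class FitConfig:
    """Configuration of the per-spectrum nonlinear fit.

    ``free`` lists the varied parameters; everything else is taken from
    ``base`` (which also supplies the fixed scattering constants).  Fixing
    M and/or d_e (the under-determination remedy) is done by removing them
    from ``free`` and setting their values in ``base``.
    """

    free: tuple = DEFAULT_FREE
    base: SkinParams = field(
        default_factory=lambda: SkinParams(B=1e-3, SO2=0.8, M=0.02, d_e_um=90.0)
    )
    initial: dict | None = None
    n_starts: int = 8
    seed: int = 0
    ftol: float = 1e-10
    xtol: float = 1e-8

    def validate(self) -> None:
        if not self.free:
            raise ValueError("free-parameter set is empty")
        for name in self.free:
            if name not in PARAM_BOUNDS:
                raise ValueError(f"unknown free parameter {name!r}")
        if self.initial:
            for name, v in self.initial.items():
                lo, hi = PARAM_BOUNDS[name]
                if not (lo <= v <= hi):
                    raise ValueError(f"initial {name}={v} outside bounds ({lo}, {hi})")


@dataclass
class FitResult:
    """Fitted skin parameters for one spectrum."""

    params: SkinParams
    residual_norm: float
    converged: bool
    n_evaluations: int
    residuals: np.ndarray
    message: str = ""

    @property
    def so2_pct(self) -> float:
        """Oxygen saturation in percent (interface convention)."""
        return 100.0 * self.params.SO2


def _encode(name: str, value: float) -> float:
    return np.log10(value) if name in _LOG_PARAMS else value


def _decode(name: str, value: float) -> float:
    return 10.0 ** value if name in _LOG_PARAMS else value


def _theta_to_params(theta, config: FitConfig) -> SkinParams:
    updates = {name: _decode(name, v) for name, v in zip(config.free, theta)}
    return replace(config.base, **updates)


def _start_points(config: FitConfig, rng_seed: int) -> np.ndarray:
    lo = np.array([_encode(n, PARAM_BOUNDS[n][0]) for n in config.free])
    hi = np.array([_encode(n, PARAM_BOUNDS[n][1]) for n in config.free])
    sampler = qmc.LatinHypercube(d=len(config.free), seed=rng_seed)
    # keep starts off the box faces
    unit = 0.05 + 0.9 * sampler.random(config.n_starts)
    starts = lo + unit * (hi - lo)
    if config.initial:
        guess = np.array([
            _encode(n, config.initial.get(n, getattr(config.base, n)))
            for n in config.free
        ])
        starts = np.vstack([guess, starts])
    return starts, lo, hi


def fit_spectrum(r_meas, bands_nm, config: FitConfig,
                 table: ChromophoreTable) -> FitResult:
    """Fit the two-layer model to one measured reflectance spectrum."""
    config.validate()
    r_meas = np.asarray(r_meas, dtype=float)
    bands = np.asarray(bands_nm, dtype=float)
    if r_meas.shape != bands.shape:
        raise ValueError("spectrum length does not match band list")
    if not np.all(np.isfinite(r_meas)):
        raise ValueError("measured spectrum contains non-finite values")
    degenerate = r_meas.max() <= 1e-6

    def residual_fn(theta):
        return forward_reflectance(_theta_to_params(theta, config),
                                   bands, table) - r_meas

    starts, lo, hi = _start_points(config, config.seed)
    best = None
    n_eval = 0
    for x0 in starts:
        try:
            res = least_squares(residual_fn, x0, bounds=(lo, hi),
                                method="trf", x_scale="jac",
                                ftol=config.ftol, xtol=config.xtol)
        except Exception as exc:  # model-evaluation failure on this start
            logger.debug("start %s failed: %s", x0, exc)
            continue
        n_eval += res.nfev
        if not np.isfinite(res.cost):
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise FitError("all multi-start fits failed to produce a finite loss")
    params = _theta_to_params(best.x, config)
    converged = bool(best.status > 0) and not degenerate
    message = best.message if not degenerate else \
        "degenerate (non-physical) measured spectrum"
    return FitResult(
        params=params,
        residual_norm=float(np.sqrt(2.0 * best.cost)),
        converged=converged,
        n_evaluations=n_eval,
        residuals=best.fun,
        message=message,
    )


def fit_all_clusters(clusters: ClusterResult, bands_nm, config: FitConfig,
                     table: ChromophoreTable) -> list:
    """Fit every non-empty cluster's centroid spectrum, in cluster order.

    Empty clusters (weight 0) yield ``None``.  Per-cluster failures are
    returned as flagged (non-converged) results, never raised.
    """
    results = []
    for k in range(clusters.K):
        if clusters.weights[k] == 0:
            results.append(None)
            continue
        sub = replace(config, seed=config.seed + k)
        try:
            results.append(fit_spectrum(clusters.centroids[k], bands_nm,
                                        sub, table))
        except FitError as exc:
            logger.warning("cluster %d fit failed: %s", k, exc)
            results.append(FitResult(
                params=sub.base, residual_norm=np.inf, converged=False,
                n_evaluations=0, residuals=np.full(len(bands_nm), np.nan),
                message=str(exc),
            ))
    return results
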