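"""Joint voxel-wise T1/T2/M0 estimation from multi-measurement images.

The estimation problem: a protocol acquires one magnitude image per
``(alpha, t_bs, t_sp)`` setting; for each voxel the per-measurement signal
vector is fitted with the semi-steady-state prepared-SPGR model (or, for
bias comparisons, the steady-state Ernst model, which has no T2) by bounded
nonlinear least squares under a Gaussian residual assumption.  Flip angles
are corrected per voxel with the smoothed B1+ actual-to-nominal ratio map,
``alpha_actual = ratio * alpha_nominal``.

The surface follows the statsmodels convention: build an
:class:`ISPGRModel` from data, call :meth:`~ISPGRModel.fit`, and read the
estimates, standard errors, diagnostics and :meth:`~ISPGRResults.summary`
off the returned :class:`ISPGRResults`.  ``fit_voxel`` and ``fit_volume``
are thin functional wrappers used by scripts and the CLI.

The joint (T1, T2) objective has local minima, particularly at short T2
where the blood-suppression attenuation trades off against M0.  The fit
therefore starts from a coarse log-spaced (T1, T2) grid on which M0 is
profiled out analytically (the model is linear in M0), refines the best few
grid nodes with bounded trust-region least squares, and keeps the lowest
cost — a deterministic multi-start with no random state.

Default bounds are T1 in [100, 3000] ms and T2 in [20, 300] ms; M0 is
bounded by 10x the largest observed signal.  Estimates that land on a bound
are reported as converged-at-bound with a distinct flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import least_squares

from .images import ImageStack
from .params import Protocol
from .signal_model import forward_signals

__all__ = [
    "FitBounds",
    "ISPGRModel",
    "ISPGRResults",
    "ParameterMaps",
    "actual_flip_angle",
    "smooth_b1_map",
    "fit_voxel",
    "fit_volume",
    "fit_regions",
    "FLAG_OK",
    "FLAG_AT_BOUND",
    "FLAG_FAILED",
    "FLAG_OUTSIDE",
]

T1_BOUNDS_MS = (100.0, 3000.0)
T2_BOUNDS_MS = (20.0, 300.0)

FLAG_OK = 0
FLAG_AT_BOUND = 1
FLAG_FAILED = 2
FLAG_OUTSIDE = -1


def actual_flip_angle(alpha_nominal, b1_ratio):
    """Actual flip angle (degrees): ``b1_ratio * alpha_nominal``.

    The B1+ map is an actual-to-nominal scaling field, so the correction is
    a per-voxel linear rescaling of the prescribed angle.
    """
    ratio = np.asarray(b1_ratio, dtype=float)
    if np.any(ratio <= 0):
        raise ValueError("b1_ratio must be positive")
    out = ratio * np.asarray(alpha_nominal, dtype=float)
    return float(out) if out.ndim == 0 else out


def smooth_b1_map(b1_ratio, sigma: float):
    """3D Gaussian smoothing of the B1+ ratio map; ``sigma`` in voxels.

    ``sigma = 0`` returns the input unchanged.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    b1_ratio = np.asarray(b1_ratio, dtype=float)
    if sigma == 0:
        return b1_ratio
    return ndimage.gaussian_filter(b1_ratio, sigma=sigma)


@dataclass(frozen=True)
class FitBounds:
    """Box bounds for the bounded least-squares fit (times in ms).

    ``m0 = None`` resolves the M0 box adaptively at fit time: the upper
    bound is 10x the largest analytically profiled M0 over the coarse
    (T1, T2) start grid.  A rule tied to the raw signal level (e.g. a fixed
    multiple of the maximum observed signal) fails for prepared shots,
    whose signals are only a few percent of M0.
    """

    t1: tuple[float, float] = T1_BOUNDS_MS
    t2: tuple[float, float] = T2_BOUNDS_MS
    m0: tuple[float, float] | None = None


class ISPGRModel:
    """Signal model for one voxel's multi-measurement signal vector.

    Parameters
    ----------
    signals : array-like
        Observed magnitude signal per measurement, same order as
        ``protocol.measurements``.
    protocol : Protocol
    alpha_scale : float
        Actual-to-nominal flip-angle ratio at this voxel.
    model : {"ispgr", "spgr"}
        ``"ispgr"`` fits (T1, T2, M0) with the prepared-shot model;
        ``"spgr"`` fits (T1, M0) with the Ernst equation, deliberately
        ignoring the preparation (bias comparison).
    bounds : FitBounds, optional
    n : int
        Readout index of the model evaluation; 1 (central k-space) unless
        the acquisition ordering says otherwise.
    """

    def __init__(self, signals, protocol: Protocol, alpha_scale: float = 1.0,
                 model: str = "ispgr", bounds: FitBounds | None = None,
                 n: int = 1):
        self.signals = np.asarray(signals, dtype=float)
        if self.signals.ndim != 1 or self.signals.shape[0] != len(protocol):
            raise ValueError("signals must be 1D with one value per measurement")
        if not np.all(np.isfinite(self.signals)):
            raise ValueError("signals must be finite")
        if model not in ("ispgr", "spgr"):
            raise ValueError(f"model must be 'ispgr' or 'spgr', got {model!r}")
        min_meas = 3 if model == "ispgr" else 2
        if len(protocol) < min_meas:
            raise ValueError(
                f"{model} fit needs at least {min_meas} measurements, "
                f"got {len(protocol)}"
            )
        if model == "ispgr":
            if len(set(protocol.t_bss)) < 2 or len(set(protocol.alphas)) < 2:
                warnings.warn(
                    "protocol has fewer than two distinct flip angles or "
                    "blood-suppression durations: joint T1/T2 fit may be "
                    "poorly identified",
                    stacklevel=2,
                )
        self.protocol = protocol
        self.alpha_scale = float(alpha_scale)
        self.model = model
        self.bounds = bounds or FitBounds()
        self.n = int(n)

    @property
    def nparams(self) -> int:
        return 3 if self.model == "ispgr" else 2

    def predict(self, t1: float, t2: float | None = None, m0: float = 1.0) -> np.ndarray:
        """Model signal vector at the given tissue parameters."""
        t2 = 100.0 if t2 is None else t2  # inert for the spgr model
        return forward_signals(t1, t2, m0, self.protocol,
                               alpha_scale=self.alpha_scale, n=self.n,
                               model=self.model)

    # -- fitting ----------------------------------------------------------
    def _grid_starts(self, n_starts: int, grid_shape: tuple[int, int]):
        """Coarse grid search with M0 profiled out analytically.

        Returns the top starts and the resolved M0 box."""
        lo1, hi1 = self.bounds.t1
        lo2, hi2 = self.bounds.t2
        t1g = np.geomspace(lo1, hi1, grid_shape[0])
        if self.model == "ispgr":
            t2g = np.geomspace(lo2, hi2, grid_shape[1])
            t1m, t2m = [a.ravel() for a in np.meshgrid(t1g, t2g, indexing="ij")]
        else:
            t1m = t1g
            t2m = np.full_like(t1g, 100.0)
        unit = forward_signals(t1m, t2m, 1.0, self.protocol,
                               alpha_scale=self.alpha_scale, n=self.n,
                               model=self.model)  # (G, m)
        denom = np.maximum(np.einsum("gm,gm->g", unit, unit), 1e-300)
        m0_hat = np.maximum(unit @ self.signals / denom, 0.0)
        if self.bounds.m0 is not None:
            m0_lo, m0_hi = self.bounds.m0
        else:
            m0_lo, m0_hi = 0.0, max(10.0 * float(m0_hat.max()), 1e-12)
        m0_hat = np.clip(m0_hat, max(m0_lo, 1e-12 * max(m0_hi, 1.0)), m0_hi)
        resid = unit * m0_hat[:, None] - self.signals
        sse = np.einsum("gm,gm->g", resid, resid)
        order = np.argsort(sse)[: max(1, n_starts)]
        starts = [(t1m[g], t2m[g], m0_hat[g]) for g in order]
        return starts, (m0_lo, m0_hi)

    def fit(self, n_starts: int = 3, grid_shape: tuple[int, int] = (12, 10),
            xtol: float = 1e-10) -> "ISPGRResults":
        """Bounded multi-start least-squares fit.

        Returns an :class:`ISPGRResults`; an all-zero signal vector yields a
        non-converged result with missing parameters rather than raising.
        """
        if not np.any(self.signals):
            return ISPGRResults(self, params=np.full(self.nparams, np.nan),
                                cost=np.nan, converged=False,
                                flag=FLAG_FAILED, nfev=0)
        lo1, hi1 = self.bounds.t1
        lo2, hi2 = self.bounds.t2
        starts, (m0_lo, m0_hi) = self._grid_starts(n_starts, grid_shape)
        eps = 1e-9

        if self.model == "ispgr":
            lower = np.array([lo1, lo2, m0_lo])
            upper = np.array([hi1, hi2, m0_hi])

            def resid(x):
                return forward_signals(x[0], x[1], x[2], self.protocol,
                                       alpha_scale=self.alpha_scale, n=self.n,
                                       model="ispgr") - self.signals
        else:
            lower = np.array([lo1, m0_lo])
            upper = np.array([hi1, m0_hi])

            def resid(x):
                return forward_signals(x[0], 100.0, x[1], self.protocol,
                                       alpha_scale=self.alpha_scale, n=self.n,
                                       model="spgr") - self.signals

        span = upper - lower
        best = None
        nfev = 0
        for t1_0, t2_0, m0_0 in starts:
            x0 = np.array([t1_0, t2_0, m0_0] if self.model == "ispgr"
                          else [t1_0, m0_0])
            x0 = np.clip(x0, lower + eps * span, upper - eps * span)
            sol = least_squares(resid, x0, bounds=(lower, upper), method="trf",
                                xtol=xtol, ftol=1e-12, gtol=1e-12,
                                x_scale=np.maximum(np.abs(x0), 1e-3))
            nfev += sol.nfev
            if best is None or sol.cost < best.cost:
                best = sol

        btol = 1e-6 * np.maximum(span, 1.0)
        at_bound = bool(np.any(best.x - lower <= btol) or np.any(upper - best.x <= btol))
        flag = FLAG_AT_BOUND if at_bound else FLAG_OK
        converged = bool(best.success)
        if not converged:
            flag = FLAG_FAILED
        return ISPGRResults(self, params=best.x, cost=float(best.cost),
                            converged=converged, flag=flag, nfev=nfev,
                            jac=best.jac)


@dataclass
class ISPGRResults:
    """Estimates and diagnostics of one voxel fit.

    ``params`` is ``(t1, t2, m0)`` for the prepared model and ``(t1, m0)``
    for the Ernst model; ``t2`` reads as NaN in the latter case.  ``flag``
    is one of the module-level ``FLAG_*`` codes.
    """

    model: ISPGRModel
    params: np.ndarray
    cost: float
    converged: bool
    flag: int
    nfev: int
    jac: np.ndarray | None = None

    @property
    def t1(self) -> float:
        return float(self.params[0])

    @property
    def t2(self) -> float:
        return float(self.params[1]) if self.model.model == "ispgr" else float("nan")

    @property
    def m0(self) -> float:
        return float(self.params[-1])

    @property
    def resid(self) -> np.ndarray:
        if not self.converged:
            return np.full_like(self.model.signals, np.nan)
        x = self.params
        if self.model.model == "ispgr":
            pred = self.model.predict(x[0], x[1], x[2])
        else:
            pred = self.model.predict(x[0], None, x[1])
        return self.model.signals - pred

    @property
    def resid_norm(self) -> float:
        return float(np.sqrt(np.nansum(self.resid ** 2)))

    @property
    def df_resid(self) -> int:
        return len(self.model.signals) - self.model.nparams

    @property
    def bse(self) -> np.ndarray:
        """Asymptotic standard errors from the Gauss-Newton approximation."""
        if self.jac is None or not self.converged or self.df_resid <= 0:
            return np.full(self.model.nparams, np.nan)
        jtj = self.jac.T @ self.jac
        try:
            cov = np.linalg.inv(jtj)
        except np.linalg.LinAlgError:
            return np.full(self.model.nparams, np.nan)
        s2 = 2.0 * self.cost / self.df_resid  # cost is 0.5 * SSR
        return np.sqrt(np.maximum(np.diag(cov) * s2, 0.0))

    def summary(self) -> str:
        names = ["T1 (ms)", "T2 (ms)", "M0 (a.u.)"] if self.model.model == "ispgr" \
            else ["T1 (ms)", "M0 (a.u.)"]
        bse = self.bse
        lines = [
            f"{'Prepared SPGR' if self.model.model == 'ispgr' else 'Ernst SPGR'}"
            " least-squares fit",
            f"measurements: {len(self.model.signals)}   "
            f"converged: {self.converged}   flag: {self.flag}",
            f"residual norm: {self.resid_norm:.6g}   nfev: {self.nfev}",
            f"{'param':<10}{'estimate':>14}{'std err':>14}",
        ]
        for name, v, se in zip(names, self.params, bse):
            lines.append(f"{name:<10}{v:>14.6g}{se:>14.3g}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Functional wrappers
# ---------------------------------------------------------------------------

def fit_voxel(signals, protocol: Protocol, alpha_scale: float = 1.0,
              model: str = "ispgr", bounds: FitBounds | None = None,
              n: int = 1, n_starts: int = 3) -> ISPGRResults:
    """Fit one voxel's signal vector; see :class:`ISPGRModel`."""
    return ISPGRModel(signals, protocol, alpha_scale=alpha_scale, model=model,
                      bounds=bounds, n=n).fit(n_starts=n_starts)


@dataclass
class ParameterMaps:
    """Fitted parameter volumes with per-voxel diagnostics.

    Voxels outside the mask carry NaN parameters and ``flag = -1``;
    non-converged voxels carry ``flag = 2`` and are excluded from summaries.
    """

    t1: np.ndarray
    t2: np.ndarray
    m0: np.ndarray
    resid_norm: np.ndarray
    flag: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def converged_mask(self) -> np.ndarray:
        """Voxels usable in summaries (converged, possibly at a bound)."""
        return (self.flag == FLAG_OK) | (self.flag == FLAG_AT_BOUND)

    def as_dict(self) -> dict:
        return {"t1": self.t1, "t2": self.t2, "m0": self.m0,
                "residual": self.resid_norm, "flag": self.flag}


def fit_volume(stack: ImageStack, protocol: Protocol, model: str = "ispgr",
               bounds: FitBounds | None = None, b1_sigma: float = 1.0,
               n: int = 1, n_starts: int = 3) -> ParameterMaps:
    """Voxel-wise fit of every masked voxel of an image stack.

    The B1+ ratio map is Gaussian-smoothed (``b1_sigma`` voxels) before the
    per-voxel flip-angle correction.  Deterministic: the multi-start grid is
    fixed, so repeated runs are bit-identical.
    """
    if not np.any(stack.mask > 0):
        raise ValueError("mask is empty")
    b1 = smooth_b1_map(stack.b1_ratio, b1_sigma)
    shape = stack.shape
    t1 = np.full(shape, np.nan)
    t2 = np.full(shape, np.nan)
    m0 = np.full(shape, np.nan)
    rn = np.full(shape, np.nan)
    flag = np.full(shape, FLAG_OUTSIDE, dtype=int)

    idx = np.argwhere(stack.mask > 0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # identifiability warning once is enough
        for ix, iy, iz in idx:
            res = fit_voxel(stack.volumes[:, ix, iy, iz], protocol,
                            alpha_scale=float(b1[ix, iy, iz]), model=model,
                            bounds=bounds, n=n, n_starts=n_starts)
            flag[ix, iy, iz] = res.flag
            if res.flag != FLAG_FAILED:
                t1[ix, iy, iz] = res.t1
                t2[ix, iy, iz] = res.t2
                m0[ix, iy, iz] = res.m0
                rn[ix, iy, iz] = res.resid_norm
    return ParameterMaps(t1=t1, t2=t2, m0=m0, resid_norm=rn, flag=flag,
                         meta={"model": model, "b1_sigma": b1_sigma, "n": n,
                               "protocol": protocol.to_dict()})


def fit_regions(stack: ImageStack, protocol: Protocol, model: str = "ispgr",
                bounds: FitBounds | None = None, b1_sigma: float = 0.0,
                n: int = 1) -> pd.DataFrame:
    """Fit the mean signal of each labelled region (one fit per region).

    Complements the per-voxel path: phantom vials are homogeneous, so
    fitting the vial-mean signal is a cheap, low-noise alternative to
    averaging voxel-wise fits.  Returns a DataFrame indexed by label with
    columns ``t1``, ``t2``, ``m0``, ``resid_norm``, ``flag``, ``n_voxels``.
    """
    b1 = smooth_b1_map(stack.b1_ratio, b1_sigma)
    rows = {}
    for label in np.unique(stack.mask[stack.mask > 0]):
        sel = stack.mask == label
        signals = stack.volumes[:, sel].mean(axis=1)
        res = fit_voxel(signals, protocol, alpha_scale=float(b1[sel].mean()),
                        model=model, bounds=bounds, n=n)
        rows[int(label)] = {"t1": res.t1, "t2": res.t2, "m0": res.m0,
                            "resid_norm": res.resid_norm, "flag": res.flag,
                            "n_voxels": int(sel.sum())}
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    df.index.name = "label"
    return df
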