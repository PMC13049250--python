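"""Quantitative evaluation: bias tables, Monte-Carlo precision maps,
repeatability statistics, ROI summaries and distribution-gated correlation.

These are the procedures used to judge the mapping method: accuracy against
per-region reference values (with and without the prepared-shot model, to
expose the bias of ignoring the preparation), precision under noise as a
function of ground-truth (T1, T2), test-retest agreement via Bland-Altman
limits and the within-subject coefficient of variation

    wCV = s_w / grand mean,     s_w = sqrt(mean(d^2) / 2),

where ``d`` are the paired differences, and correlation of ROI medians
against an external covariate with the test chosen by Shapiro-Wilk
normality of both variables (Pearson if both pass at p >= 0.05, Spearman
otherwise).

Percentile conventions matter for medians/IQRs: this module uses numpy's
linear-interpolation quantile rule throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .fitting import FitBounds, ISPGRModel, ParameterMaps
from .params import Protocol
from .signal_model import forward_signals

__all__ = [
    "bias_table",
    "SensitivityMap",
    "sensitivity_analysis",
    "RepeatabilityResult",
    "repeatability",
    "roi_summary",
    "CorrelationResult",
    "correlate_with_diameter",
]


# ---------------------------------------------------------------------------
# Accuracy / bias
# ---------------------------------------------------------------------------

def _coerce_reference(reference) -> pd.DataFrame:
    """Accept a DataFrame (label-indexed, t1/t2 columns), a dict, or a
    DigitalPhantom-like object with ``reference_table()``."""
    if hasattr(reference, "reference_table"):
        return reference.reference_table()
    if isinstance(reference, pd.DataFrame):
        return reference
    # dict: label -> (t1, t2)
    return pd.DataFrame(
        {"t1": {k: v[0] for k, v in reference.items()},
         "t2": {k: v[1] for k, v in reference.items()}}
    ).rename_axis("label")


def bias_table(param_maps_by_model, labels, reference) -> pd.DataFrame:
    """Per-region accuracy of fitted maps against reference values.

    Parameters
    ----------
    param_maps_by_model : mapping of str -> ParameterMaps
        e.g. ``{"ispgr": maps_a, "spgr": maps_b}``.
    labels : ndarray
        Integer region labels on the map grid (0 = background).
    reference : DataFrame, dict or DigitalPhantom
        Per-label reference ``t1``/``t2`` values, ms.

    Returns
    -------
    DataFrame
        One row per (model, region) with reference, fitted region mean and
        error = fitted - reference for T1 and T2, plus a ``mean`` row per
        model with the grand mean error.  Only converged voxels (including
        converged-at-bound) enter the region means; regions empty in a map
        are dropped with a warning.
    """
    import warnings

    ref = _coerce_reference(reference)
    labels = np.asarray(labels)
    rows = []
    for model_name, maps in param_maps_by_model.items():
        usable = maps.converged_mask
        errs_t1, errs_t2 = [], []
        for label, ref_row in ref.iterrows():
            sel = (labels == label) & usable
            if not sel.any():
                warnings.warn(f"region {label} empty in model {model_name!r}; excluded",
                              stacklevel=2)
                continue
            fit_t1 = float(np.mean(maps.t1[sel]))
            fit_t2 = float(np.nanmean(maps.t2[sel]))
            row = {
                "model": model_name, "region": label,
                "ref_t1": float(ref_row["t1"]), "fit_t1": fit_t1,
                "err_t1": fit_t1 - float(ref_row["t1"]),
                "ref_t2": float(ref_row["t2"]), "fit_t2": fit_t2,
                "err_t2": fit_t2 - float(ref_row["t2"]),
            }
            rows.append(row)
            errs_t1.append(row["err_t1"])
            errs_t2.append(row["err_t2"])
        if errs_t1:
            rows.append({
                "model": model_name, "region": "mean",
                "ref_t1": np.nan, "fit_t1": np.nan,
                "err_t1": float(np.mean(errs_t1)),
                "ref_t2": np.nan, "fit_t2": np.nan,
                "err_t2": float(np.nanmean(errs_t2)),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Monte-Carlo precision
# ---------------------------------------------------------------------------

@dataclass
class SensitivityMap:
    """Relative-error map over a (T1, T2) ground-truth grid.

    ``err_*`` arrays have shape ``(len(t1_grid), len(t2_grid))`` and hold
    the per-cell summary (default: median absolute relative error) in
    percent of ground truth.
    """

    t1_grid: np.ndarray
    t2_grid: np.ndarray
    err_t1: np.ndarray
    err_t2: np.ndarray
    err_m0: np.ndarray
    snr: float
    n_reps: int
    seed: int
    statistic: str = "median"

    def to_dataframe(self) -> pd.DataFrame:
        t1m, t2m = np.meshgrid(self.t1_grid, self.t2_grid, indexing="ij")
        return pd.DataFrame({
            "t1": t1m.ravel(), "t2": t2m.ravel(),
            "err_t1_pct": self.err_t1.ravel(),
            "err_t2_pct": self.err_t2.ravel(),
            "err_m0_pct": self.err_m0.ravel(),
        })

    def max_error(self, param: str = "t1", t2_below: float | None = None) -> float:
        """Maximum per-cell error, optionally restricted to T2 < ``t2_below``."""
        err = getattr(self, f"err_{param}")
        if t2_below is None:
            return float(np.nanmax(err))
        sel = self.t2_grid < t2_below
        if not sel.any():
            raise ValueError("no grid cells below the requested T2")
        return float(np.nanmax(err[:, sel]))

    def plot(self, ax=None):
        """Heatmaps of the per-cell T1/T2/M0 errors (requires matplotlib)."""
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 3, figsize=(12, 3.2)) if ax is None else (None, ax)
        for a, (name, err) in zip(
            axes, [("T1", self.err_t1), ("T2", self.err_t2), ("M0", self.err_m0)]
        ):
            im = a.imshow(err, origin="lower", aspect="auto",
                          extent=[self.t2_grid[0], self.t2_grid[-1],
                                  self.t1_grid[0], self.t1_grid[-1]])
            a.set_xlabel("T2 (ms)")
            a.set_ylabel("T1 (ms)")
            a.set_title(f"{name} error (%)")
            plt.colorbar(im, ax=a)
        return axes


def sensitivity_analysis(
    protocol: Protocol,
    t1_grid,
    t2_grid,
    snr: float = 30.0,
    n_reps: int = 100,
    seed: int = 0,
    bounds: FitBounds | None = None,
    statistic: str = "median",
    sigma_mode: str = "grid_mean",
    n_starts: int = 2,
) -> SensitivityMap:
    """Monte-Carlo precision of the joint fit over a ground-truth grid.

    For every (T1, T2) cell, the noiseless signal vector (M0 = 1) is
    computed, additive Gaussian noise is drawn at the requested SNR, and the
    noisy vector is fitted ``n_reps`` times with independent draws.  The
    per-cell error is the ``statistic`` ("median" or "mean") of the
    absolute relative parameter errors, in percent.

    The noise level follows the package-wide SNR convention: sigma equals
    the mean noiseless reference-measurement signal divided by ``snr``.
    With ``sigma_mode="grid_mean"`` (default) the mean runs over the whole
    ground-truth grid — one noise level for the map, as in an image
    containing all the tissues — so weak-signal cells see proportionally
    more noise; ``"per_cell"`` rescales sigma to each cell's own reference
    signal instead.

    Reps whose optimizer stops on the feasible boundary count as
    boundary-value estimates rather than being dropped — discarding them
    would flatter the precision.

    Deterministic for a given ``seed``.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    if statistic not in ("median", "mean"):
        raise ValueError("statistic must be 'median' or 'mean'")
    if sigma_mode not in ("grid_mean", "per_cell"):
        raise ValueError("sigma_mode must be 'grid_mean' or 'per_cell'")
    t1_grid = np.atleast_1d(np.asarray(t1_grid, dtype=float))
    t2_grid = np.atleast_1d(np.asarray(t2_grid, dtype=float))
    if t1_grid.size == 0 or t2_grid.size == 0:
        raise ValueError("grids must be non-empty")
    agg = np.nanmedian if statistic == "median" else np.nanmean
    rng = np.random.default_rng(seed)
    ref_idx = protocol.reference_index()
    bounds = bounds or FitBounds()

    sigma_shared = None
    if sigma_mode == "grid_mean":
        t1m, t2m = np.meshgrid(t1_grid, t2_grid, indexing="ij")
        ref_all = forward_signals(t1m.ravel(), t2m.ravel(), 1.0, protocol)[:, ref_idx]
        sigma_shared = float(ref_all.mean()) / snr

    shape = (t1_grid.size, t2_grid.size)
    err_t1 = np.empty(shape)
    err_t2 = np.empty(shape)
    err_m0 = np.empty(shape)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, t1 in enumerate(t1_grid):
            for j, t2 in enumerate(t2_grid):
                clean = forward_signals(t1, t2, 1.0, protocol)
                sigma = (sigma_shared if sigma_shared is not None
                         else float(clean[ref_idx]) / snr)
                noisy = clean + rng.normal(0.0, sigma, size=(n_reps, clean.size))
                rel = np.empty((n_reps, 3))
                for r in range(n_reps):
                    res = ISPGRModel(noisy[r], protocol, bounds=bounds).fit(
                        n_starts=n_starts, grid_shape=(10, 8))
                    rel[r] = [abs(res.t1 - t1) / t1,
                              abs(res.t2 - t2) / t2,
                              abs(res.m0 - 1.0)]
                err_t1[i, j], err_t2[i, j], err_m0[i, j] = 100.0 * agg(rel, axis=0)
    return SensitivityMap(t1_grid=t1_grid, t2_grid=t2_grid, err_t1=err_t1,
                          err_t2=err_t2, err_m0=err_m0, snr=snr,
                          n_reps=n_reps, seed=seed, statistic=statistic)


# ---------------------------------------------------------------------------
# Repeatability
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RepeatabilityResult:
    """Paired test-retest agreement: Bland-Altman components and wCV."""

    n_pairs: int
    mean_difference: float
    loa_lower: float
    loa_upper: float
    within_subject_sd: float
    grand_mean: float
    wcv: float

    def summary(self) -> str:
        return (
            f"n = {self.n_pairs} pairs\n"
            f"mean difference: {self.mean_difference:.6g}\n"
            f"95% limits of agreement: [{self.loa_lower:.6g}, {self.loa_upper:.6g}]\n"
            f"within-subject SD: {self.within_subject_sd:.6g}\n"
            f"wCV: {self.wcv:.4%}"
        )


def repeatability(pairs) -> RepeatabilityResult:
    """Bland-Altman statistics and wCV from paired repeat measurements.

    ``pairs`` is an (n, 2) array of paired values (e.g. per-region medians
    of two same-session scans).  Limits of agreement are mean difference
    +/- 1.96 SD of the differences; wCV = sqrt(mean(d^2)/2) / grand mean.
    """
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or pairs.shape[0] < 2:
        raise ValueError("pairs must be an (n >= 2, 2) array")
    d = pairs[:, 0] - pairs[:, 1]
    mean_diff = float(d.mean())
    sd = float(d.std(ddof=1))
    within_sd = float(np.sqrt(np.mean(d ** 2) / 2.0))
    grand = float(pairs.mean())
    if grand == 0:
        raise ZeroDivisionError("grand mean is zero; wCV undefined")
    return RepeatabilityResult(
        n_pairs=pairs.shape[0],
        mean_difference=mean_diff,
        loa_lower=mean_diff - 1.96 * sd,
        loa_upper=mean_diff + 1.96 * sd,
        within_subject_sd=within_sd,
        grand_mean=grand,
        wcv=within_sd / grand,
    )


# ---------------------------------------------------------------------------
# ROI summaries and correlation
# ---------------------------------------------------------------------------

def roi_summary(maps: ParameterMaps, mask=None) -> pd.DataFrame:
    """Median and IQR of T1/T2/M0 over a region of interest.

    Non-converged voxels are excluded.  ``mask`` may be a boolean array or
    an integer label array (one summary row per label); ``None`` summarizes
    every converged voxel.  Quantiles use linear interpolation.
    """
    usable = maps.converged_mask
    if mask is None:
        regions = {"all": usable}
    else:
        mask = np.asarray(mask)
        if mask.dtype == bool:
            regions = {"all": mask & usable}
        else:
            regions = {int(lb): (mask == lb) & usable
                       for lb in np.unique(mask[mask > 0])}
    rows = {}
    for name, sel in regions.items():
        if not sel.any():
            raise ValueError(f"region {name!r}: no converged voxels")
        row = {}
        for pname, arr in (("t1", maps.t1), ("t2", maps.t2), ("m0", maps.m0)):
            vals = arr[sel]
            vals = vals[np.isfinite(vals)]
            q25, q50, q75 = (np.percentile(vals, [25, 50, 75])
                             if vals.size else (np.nan,) * 3)
            row[f"{pname}_median"] = q50
            row[f"{pname}_q25"] = q25
            row[f"{pname}_q75"] = q75
        row["n_voxels"] = int(sel.sum())
        rows[name] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "region"
    return df


@dataclass(frozen=True)
class CorrelationResult:
    """Correlation with the method chosen by the normality gate."""

    coefficient: float
    pvalue: float
    method: str  # "pearson" or "spearman"
    shapiro_p: tuple[float, float]


def correlate_with_diameter(medians, diameters, alpha: float = 0.05) -> CorrelationResult:
    """Correlate ROI medians against a covariate (e.g. aneurysm diameter).

    Shapiro-Wilk is applied to both variables; Pearson is used only if both
    pass (p >= ``alpha``), otherwise Spearman.  The method used is returned
    alongside the coefficient and p-value.
    """
    x = np.asarray(medians, dtype=float)
    y = np.asarray(diameters, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    p_x = float(sps.shapiro(x).pvalue)
    p_y = float(sps.shapiro(y).pvalue)
    if p_x >= alpha and p_y >= alpha:
        r = sps.pearsonr(x, y)
        method = "pearson"
    else:
        r = sps.spearmanr(x, y)
        method = "spearman"
    return CorrelationResult(coefficient=float(r.statistic),
                             pvalue=float(r.pvalue), method=method,
                             shapiro_p=(p_x, p_y))
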