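"""Closed-form signal models for SPGR and prepared (interleaved) SPGR.

Steady-state SPGR
-----------------
With perfect spoiling the steady-state spoiled-gradient-echo signal follows
the Ernst equation

    S = M0 sin(a) (1 - E1) / (1 - cos(a) E1),        E1 = exp(-TR/T1),

maximized at the Ernst angle ``a = arccos(E1)``.

Semi-steady-state I-SPGR
------------------------
Interleaving the readout train with preparation modules breaks the steady
state.  After enough shots the magnetization reaches a *semi* steady state:
the longitudinal magnetization at the start of every shot is the same value
``M_1``, and within a shot it evolves along the readout index ``n``.  With
``C = E1 cos(a)`` and the per-interval relaxation factors

    E_FS = exp(-t_fs/T1),  E_BS = exp(-t_bs/T2),  E_Sp = exp(-t_sp/T1),

the longitudinal magnetization just before RF pulse ``n`` is

    M_n = M_1 C^(n-1) + M0 (1 - E1) (1 - C^(n-1)) / (1 - C),

and solving the shot-periodicity condition (readout train of ``k`` pulses,
then T1 relaxation over ``t_fs``, multiplication by ``E_BS`` while the
magnetization is transverse during blood suppression, and T1 relaxation over
``t_sp``) gives

    M_1/M0 = [ (1 - E_Sp) + (1 - E_FS) E_Sp E_BS
               + E_Sp E_BS E_FS (1 - E1)(1 - C^k)/(1 - C) ]
             / [ 1 - E_Sp E_BS E_FS C^k ].

The recorded signal after pulse ``n`` is ``S_n = sin(a) M_n``.  When all
three preparation durations are zero the bracket collapses algebraically to
the Ernst expression, for every ``n``.

Because the pseudo-spiral phase-encode ordering samples the center of
k-space with the first readout of each shot, image contrast is governed by
``S_1`` and downstream fitting uses ``n = 1`` by default.

All public functions accept the domain types from :mod:`ispgr.params`; the
private ``forward_signals`` kernel is fully vectorized over tissue-parameter
arrays and is what the fitting and phantom modules call in bulk.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import Measurement, Protocol, SequenceParams, TissueParams

__all__ = [
    "RelaxationFactors",
    "ernst_signal",
    "ernst_angle",
    "ispgr_signal",
    "end_prep_magnetization",
    "model_vector",
    "forward_signals",
]

# Floor for the 1 - E1 cos(a) style denominators.  They vanish only in the
# degenerate corner a -> 0 with TR/T1 -> 0, where the signal numerator
# vanishes at the same rate; flooring returns the analytic limit 0 instead
# of 0/0 while perturbing nothing at physical parameters.
_DENOM_EPS = 1e-12


@dataclass(frozen=True)
class RelaxationFactors:
    """Per-interval relaxation factors of one shot, each in (0, 1]."""

    e1: float
    e_fs: float
    e_bs: float
    e_sp: float

    @classmethod
    def from_params(cls, tissue: TissueParams, seq: SequenceParams) -> "RelaxationFactors":
        return cls(
            e1=float(np.exp(-seq.tr / tissue.t1)),
            e_fs=float(np.exp(-seq.t_fs / tissue.t1)),
            e_bs=float(np.exp(-seq.t_bs / tissue.t2)),
            e_sp=float(np.exp(-seq.t_sp / tissue.t1)),
        )


def _geom(c: np.ndarray, m) -> np.ndarray:
    """Partial geometric sum ``(1 - c**m) / (1 - c)`` with its ``c -> 1`` limit ``m``."""
    c = np.asarray(c, dtype=float)
    m = np.asarray(m, dtype=float)
    one_minus = 1.0 - c
    tiny = np.abs(one_minus) < _DENOM_EPS
    safe = np.where(tiny, 1.0, one_minus)
    return np.where(tiny, m, (1.0 - np.power(c, m)) / safe)


def _ernst_core(t1, m0, tr, alpha_rad):
    e1 = np.exp(-tr / np.asarray(t1, dtype=float))
    denom = np.maximum(1.0 - np.cos(alpha_rad) * e1, _DENOM_EPS)
    return m0 * np.sin(alpha_rad) * (1.0 - e1) / denom


def _end_prep_fraction(t1, t2, tr, alpha_rad, k, t_fs, t_bs, t_sp):
    """Semi-steady-state start-of-shot magnetization as a fraction of M0."""
    t1 = np.asarray(t1, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    e1 = np.exp(-tr / t1)
    e_fs = np.exp(-t_fs / t1)
    e_bs = np.exp(-t_bs / t2)
    e_sp = np.exp(-t_sp / t1)
    c = e1 * np.cos(alpha_rad)
    ck = np.power(c, k)
    gk = _geom(c, k)
    prep = e_sp * e_bs * e_fs
    num = (1.0 - e_sp) + (1.0 - e_fs) * e_sp * e_bs + prep * (1.0 - e1) * gk
    den = np.maximum(1.0 - prep * ck, _DENOM_EPS)
    return num / den


def _ispgr_core(t1, t2, m0, tr, alpha_rad, k, t_fs, t_bs, t_sp, n):
    """Signal after RF pulse ``n`` of the semi-steady-state prepared shot."""
    t1 = np.asarray(t1, dtype=float)
    e1 = np.exp(-tr / t1)
    c = e1 * np.cos(alpha_rad)
    frac = _end_prep_fraction(t1, t2, tr, alpha_rad, k, t_fs, t_bs, t_sp)
    n = np.asarray(n, dtype=float)
    transient = (1.0 - e1) * _geom(c, n - 1.0)
    return m0 * np.sin(alpha_rad) * (transient + frac * np.power(c, n - 1.0))


# ---------------------------------------------------------------------------
# Public, domain-typed API
# ---------------------------------------------------------------------------

def ernst_signal(tissue: TissueParams, tr: float, alpha: float) -> float:
    """Steady-state SPGR signal (Ernst equation).

    Parameters
    ----------
    tissue : TissueParams
    tr : float
        Repetition time, ms.
    alpha : float
        Flip angle, degrees.

    Returns
    -------
    float
        ``M0 sin(a)(1 - E1)/(1 - cos(a) E1)``, arbitrary units.
    """
    if not tr > 0:
        raise ValueError(f"tr must be positive, got {tr}")
    return float(_ernst_core(tissue.t1, tissue.m0, tr, np.deg2rad(alpha)))


def ernst_angle(t1: float, tr: float) -> float:
    """Flip angle (degrees) maximizing the steady-state SPGR signal."""
    return float(np.rad2deg(np.arccos(np.exp(-tr / t1))))


def ispgr_signal(tissue: TissueParams, seq: SequenceParams, n: int = 1) -> float:
    """Semi-steady-state prepared-SPGR signal after RF pulse ``n`` of a shot.

    ``n`` is 1-based; ``n = 1`` is the readout immediately after the
    preparation block (the one that samples central k-space).  With all
    preparation durations zero this equals :func:`ernst_signal` for every
    ``n``.
    """
    if not (1 <= n <= seq.k):
        raise IndexError(f"readout index n={n} outside [1, k={seq.k}]")
    return float(
        _ispgr_core(
            tissue.t1, tissue.t2, tissue.m0,
            seq.tr, np.deg2rad(seq.alpha), seq.k,
            seq.t_fs, seq.t_bs, seq.t_sp, n,
        )
    )


def end_prep_magnetization(tissue: TissueParams, seq: SequenceParams) -> float:
    """Longitudinal magnetization just before the first RF pulse of a shot.

    This is the semi-steady-state value ``M_1``; the first readout's signal
    is ``sin(a) * M_1``.
    """
    frac = _end_prep_fraction(
        tissue.t1, tissue.t2, seq.tr, np.deg2rad(seq.alpha),
        seq.k, seq.t_fs, seq.t_bs, seq.t_sp,
    )
    return float(tissue.m0 * frac)


def model_vector(
    tissue: TissueParams,
    protocol: Protocol,
    n: int = 1,
    alpha_scale: float = 1.0,
    model: str = "ispgr",
) -> np.ndarray:
    """Predicted signal for each measurement of a protocol.

    This is the forward model used by the joint fit: one value per
    ``(alpha, t_bs, t_sp)`` measurement, evaluated at readout index ``n``
    (default 1, the central-k-space readout).

    Parameters
    ----------
    tissue : TissueParams
    protocol : Protocol
    n : int
        1-based readout index within the shot.
    alpha_scale : float
        Actual-to-nominal flip-angle ratio from a B1+ map.
    model : {"ispgr", "spgr"}
        ``"spgr"`` ignores the preparation blocks and evaluates the Ernst
        equation per measurement (used for bias comparisons).
    """
    out = forward_signals(
        tissue.t1, tissue.t2, tissue.m0, protocol,
        alpha_scale=alpha_scale, n=n, model=model,
    )
    return np.atleast_1d(np.asarray(out, dtype=float))


def forward_signals(
    t1,
    t2,
    m0,
    protocol: Protocol,
    alpha_scale=1.0,
    n: int = 1,
    model: str = "ispgr",
) -> np.ndarray:
    """Vectorized forward model over arrays of tissue parameters.

    ``t1``, ``t2``, ``m0`` and ``alpha_scale`` may be scalars or arrays of a
    common broadcast shape ``S``; the result has shape ``S + (n_meas,)``.
    """
    if model not in ("ispgr", "spgr"):
        raise ValueError(f"model must be 'ispgr' or 'spgr', got {model!r}")
    t1 = np.asarray(t1, dtype=float)[..., None]
    t2 = np.asarray(t2, dtype=float)[..., None]
    m0 = np.asarray(m0, dtype=float)[..., None]
    scale = np.asarray(alpha_scale, dtype=float)[..., None]
    alpha_rad = np.deg2rad(protocol.alphas) * scale
    if not (1 <= n <= protocol.k):
        raise IndexError(f"readout index n={n} outside [1, k={protocol.k}]")
    if model == "spgr":
        return _ernst_core(t1, m0, protocol.tr, alpha_rad)
    return _ispgr_core(
        t1, t2, m0, protocol.tr, alpha_rad, protocol.k,
        protocol.t_fs, protocol.t_bss, protocol.t_sps, n,
    )
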