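"""Event-driven Bloch simulation of the prepared (I-SPGR) sequence.

This module is the independent oracle for the closed-form signal model.  It
never evaluates the analytical equations: it propagates magnetization event
by event, with relaxation applied in exact exponential form between
instantaneous RF pulses, so there is no time-discretization error.

Two spoiling modes are available:

``perfect``
    A single isochromat.  Each readout applies an instantaneous rotation by
    the flip angle, records ``|Mxy|`` right after the pulse, relaxes ``Mz``
    toward ``M0`` over TR with T1, and zeroes the transverse magnetization
    (perfect spoiling).  After ``k`` pulses the preparation is played:
    T1 relaxation over ``t_fs`` (the SPIR pulse only touches off-resonance
    fat spins), multiplication of ``Mz`` by ``exp(-t_bs/T2)`` for the iMSDE
    block (the magnetization spends ``t_bs`` in the transverse plane), and
    T1 relaxation over ``t_sp``.

``rf_gradient``
    An ensemble of isochromats with distinct intra-voxel spoiler-gradient
    phases and quadratic RF phase cycling, propagated with the full 3D Bloch
    rotations; the complex transverse signals are summed across the ensemble
    after receiver demodulation.  This mode exposes the residual transverse
    coherence pathways that the closed form neglects, and is used to map
    signal deviation versus the RF spoiling phase increment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .params import SequenceParams, TissueParams
from .signal_model import ernst_signal, ispgr_signal

__all__ = [
    "SpoilingConfig",
    "SignalTrain",
    "simulate_ispgr",
    "time_to_steady_state",
    "spoiling_deviation",
    "model_signal_train",
]


@dataclass(frozen=True)
class SpoilingConfig:
    """Spoiling model used by the simulator.

    Parameters
    ----------
    mode : {"perfect", "rf_gradient"}
    phase_increment : float
        Quadratic RF-spoiling phase step in degrees (``rf_gradient`` mode).
        The default of 117 deg is a common scanner choice; the increment is
        configuration, not a physical constant.
    n_isochromats : int
        Ensemble size for ``rf_gradient`` mode.  The default of 500 is
        convergence-checked: doubling it changes steady-state deviations by
        well under one percentage point.
    """

    mode: str = "perfect"
    phase_increment: float = 117.0
    n_isochromats: int = 500

    def __post_init__(self) -> None:
        if self.mode not in ("perfect", "rf_gradient"):
            raise ValueError(f"unknown spoiling mode {self.mode!r}")
        if not (0.0 <= self.phase_increment <= 180.0):
            raise ValueError("phase_increment must be in [0, 180] degrees")
        if self.n_isochromats < 1:
            raise ValueError("n_isochromats must be >= 1")


@dataclass
class SignalTrain:
    """Recorded transverse signal immediately after every RF pulse.

    Attributes
    ----------
    times : ndarray
        Sequence time of each pulse, ms, strictly increasing.
    signals : ndarray
        ``|Mxy|`` right after each pulse, arbitrary units.
    shot_index : ndarray
        0-based shot of each sample.
    readout_index : ndarray
        1-based readout position within the shot.
    """

    times: np.ndarray
    signals: np.ndarray
    shot_index: np.ndarray
    readout_index: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_shots(self) -> int:
        return int(self.shot_index[-1]) + 1

    @property
    def k(self) -> int:
        return int(self.readout_index.max())

    def shot(self, s: int) -> np.ndarray:
        """Signals of shot ``s`` ordered by readout index."""
        return self.signals[self.shot_index == s]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_ms": self.times,
                "shot": self.shot_index,
                "readout": self.readout_index,
                "signal": self.signals,
            }
        )


def model_signal_train(tissue: TissueParams, seq: SequenceParams) -> np.ndarray:
    """Closed-form semi-steady-state signal at each readout index 1..k."""
    return np.array([ispgr_signal(tissue, seq, n) for n in range(1, seq.k + 1)])


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def simulate_ispgr(
    tissue: TissueParams,
    seq: SequenceParams,
    n_shots: int,
    spoiling: SpoilingConfig | None = None,
) -> SignalTrain:
    """Simulate ``n_shots`` shots of the prepared sequence from equilibrium.

    The sequence starts with a readout block (pulse 1 at t = 0) and each
    shot ends with the preparation block, matching the event order used to
    derive the closed form.

    Returns a :class:`SignalTrain` with ``n_shots * k`` samples.
    """
    if n_shots < 1:
        raise ValueError(f"n_shots must be >= 1, got {n_shots}")
    spoiling = spoiling or SpoilingConfig()
    if spoiling.mode == "perfect":
        signals = _simulate_perfect(tissue, seq, n_shots)
    else:
        signals = _simulate_ensemble(tissue, seq, n_shots, spoiling)

    k = seq.k
    shot = np.repeat(np.arange(n_shots), k)
    readout = np.tile(np.arange(1, k + 1), n_shots)
    times = shot * seq.shot_duration + (readout - 1) * seq.tr
    return SignalTrain(times=times, signals=signals, shot_index=shot,
                       readout_index=readout)


def _simulate_perfect(tissue: TissueParams, seq: SequenceParams, n_shots: int) -> np.ndarray:
    t1, t2, m0 = tissue.t1, tissue.t2, tissue.m0
    cos_a = math.cos(math.radians(seq.alpha))
    sin_a = math.sin(math.radians(seq.alpha))
    e1 = math.exp(-seq.tr / t1)
    e_fs = math.exp(-seq.t_fs / t1)
    e_bs = math.exp(-seq.t_bs / t2)
    e_sp = math.exp(-seq.t_sp / t1)

    mz = m0
    out = np.empty(n_shots * seq.k)
    i = 0
    for _ in range(n_shots):
        for _ in range(seq.k):
            out[i] = abs(mz * sin_a)
            i += 1
            mz = m0 + (mz * cos_a - m0) * e1  # T1 recovery over TR, Mxy spoiled
        mz = m0 + (mz - m0) * e_fs            # gap + fat suppression: T1 only
        mz = mz * e_bs                        # iMSDE: T2 decay while transverse
        mz = m0 + (mz - m0) * e_sp            # spoiling interval: T1 only
    return out


def _rf_matrix(alpha_rad: float, phase_rad: float) -> np.ndarray:
    """Rotation by ``alpha`` about an axis at azimuth ``phase`` in the xy-plane."""
    ca, sa = math.cos(alpha_rad), math.sin(alpha_rad)
    cp, sp = math.cos(phase_rad), math.sin(phase_rad)
    rz_neg = np.array([[cp, sp, 0.0], [-sp, cp, 0.0], [0.0, 0.0, 1.0]])
    rx = np.array([[1.0, 0.0, 0.0], [0.0, ca, sa], [0.0, -sa, ca]])
    rz_pos = np.array([[cp, -sp, 0.0], [sp, cp, 0.0], [0.0, 0.0, 1.0]])
    return rz_pos @ rx @ rz_neg


def _simulate_ensemble(
    tissue: TissueParams,
    seq: SequenceParams,
    n_shots: int,
    spoiling: SpoilingConfig,
) -> np.ndarray:
    t1, t2, m0 = tissue.t1, tissue.t2, tissue.m0
    nz = spoiling.n_isochromats
    alpha_rad = math.radians(seq.alpha)
    inc_rad = math.radians(spoiling.phase_increment)
    e1 = math.exp(-seq.tr / t1)
    e2 = math.exp(-seq.tr / t2)
    e_fs1 = math.exp(-seq.t_fs / t1)
    e_fs2 = math.exp(-seq.t_fs / t2)
    e_bs = math.exp(-seq.t_bs / t2)
    e_sp = math.exp(-seq.t_sp / t1)

    # uniform intra-voxel spoiler-gradient phase spread: one cycle per TR
    theta = 2.0 * math.pi * np.arange(nz) / nz
    rot = np.exp(1j * theta)

    mxy = np.zeros(nz, dtype=complex)
    mz = np.full(nz, m0, dtype=float)
    out = np.empty(n_shots * seq.k)
    i = 0
    pulse = 0
    for _ in range(n_shots):
        for _ in range(seq.k):
            # quadratic phase cycling: phi_p - phi_{p-1} = p * increment
            phi = 0.5 * inc_rad * pulse * (pulse + 1)
            r = _rf_matrix(alpha_rad, phi)
            mx, my = mxy.real, mxy.imag
            mx2 = r[0, 0] * mx + r[0, 1] * my + r[0, 2] * mz
            my2 = r[1, 0] * mx + r[1, 1] * my + r[1, 2] * mz
            mz = r[2, 0] * mx + r[2, 1] * my + r[2, 2] * mz
            mxy = mx2 + 1j * my2
            # receiver demodulated with the RF phase
            out[i] = abs(np.mean(mxy * np.exp(-1j * phi)))
            i += 1
            pulse += 1
            # relaxation plus gradient dephasing over TR
            mxy = mxy * e2 * rot
            mz = m0 + (mz - m0) * e1
        # preparation: residual transverse decays during the gap, the iMSDE
        # block's own crushers then eliminate it entirely
        mxy = mxy * e_fs2
        mz = m0 + (mz - m0) * e_fs1
        mxy = np.zeros(nz, dtype=complex)
        mz = mz * e_bs
        mz = m0 + (mz - m0) * e_sp
    return out


# ---------------------------------------------------------------------------
# Convergence and spoiling analyses
# ---------------------------------------------------------------------------

def time_to_steady_state(
    train: SignalTrain,
    rel_tol: float = 1e-3,
    reference: np.ndarray | None = None,
) -> float:
    """Sequence time (ms) after which the train has converged.

    Each sample is compared against the same-readout-index signal of
    ``reference`` (an array of length ``k``; defaults to the train's final
    shot).  The result is the time of the first sample of the maximal
    suffix whose samples all deviate relatively by less than ``rel_tol`` —
    0.0 if the whole train complies, ``math.inf`` if even the last sample
    does not.
    """
    if train.n_shots < 2:
        raise ValueError("train must cover at least 2 shots")
    ref = train.shot(train.n_shots - 1) if reference is None else np.asarray(reference, float)
    if ref.shape != (train.k,):
        raise ValueError(f"reference must have length k={train.k}")
    per_sample_ref = ref[train.readout_index - 1]
    scale = np.maximum(np.abs(per_sample_ref), np.finfo(float).tiny)
    dev = np.abs(train.signals - per_sample_ref) / scale
    bad = np.nonzero(dev >= rel_tol)[0]
    if bad.size == 0:
        return 0.0
    first_good = bad[-1] + 1
    if first_good >= len(train.times):
        return math.inf
    return float(train.times[first_good])


def _steady_shots(t1: float, seq: SequenceParams, min_time: float = 3000.0) -> int:
    """Number of shots comfortably reaching steady state (~8 T1 of sequence time)."""
    return max(3, math.ceil(max(8.0 * t1, min_time) / seq.shot_duration))


def spoiling_deviation(
    tissue: TissueParams,
    seq: SequenceParams,
    phase_increments,
    n_isochromats: int = 500,
) -> pd.DataFrame:
    """Steady-state signal deviation caused by imperfect spoiling.

    For each RF phase increment, an isochromat ensemble with RF and gradient
    spoiling is run to steady state for both the prepared sequence and its
    unprepared SPGR counterpart (same TR and flip angle, no preparation).
    The reported deviation is the relative difference between the ensemble
    signal and the perfect-spoiling prediction — the closed-form
    semi-steady-state signal at readout index 1 for the prepared sequence
    and the Ernst signal for SPGR.

    Returns a DataFrame with columns ``phase_increment_deg``,
    ``ispgr_deviation`` and ``spgr_deviation`` (signed fractions).
    """
    increments = np.atleast_1d(np.asarray(phase_increments, dtype=float))
    seq_spgr = replace(seq, t_fs=0.0, t_bs=0.0, t_sp=0.0)
    ref_ispgr = ispgr_signal(tissue, seq, n=1)
    ref_spgr = ernst_signal(tissue, seq.tr, seq.alpha)
    shots_ispgr = _steady_shots(tissue.t1, seq)
    shots_spgr = _steady_shots(tissue.t1, seq_spgr)

    dev_i = np.empty(increments.size)
    dev_s = np.empty(increments.size)
    for j, inc in enumerate(increments):
        cfg = SpoilingConfig(mode="rf_gradient", phase_increment=float(inc),
                             n_isochromats=n_isochromats)
        tr_i = simulate_ispgr(tissue, seq, shots_ispgr, cfg)
        tr_s = simulate_ispgr(tissue, seq_spgr, shots_spgr, cfg)
        sig_i = tr_i.shot(tr_i.n_shots - 1)[0]        # central-k-space readout
        sig_s = tr_s.shot(tr_s.n_shots - 1)[-1]       # fully steady readout
        dev_i[j] = (sig_i - ref_ispgr) / ref_ispgr
        dev_s[j] = (sig_s - ref_spgr) / ref_spgr
    return pd.DataFrame(
        {
            "phase_increment_deg": increments,
            "ispgr_deviation": dev_i,
            "spgr_deviation": dev_s,
        }
    )
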