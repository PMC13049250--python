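"""Domain types: tissue parameters, sequence timing, and acquisition protocols.

The acquisition this package models is a 3D spoiled gradient echo (SPGR)
sequence whose readout blocks are interleaved with preparation modules
(I-SPGR): a temporal gap plus spectral fat suppression (duration ``t_fs``,
pure T1 relaxation for on-resonance spins), an improved motion-sensitized
driven-equilibrium (iMSDE) blood-suppression block that holds the
magnetization in the transverse plane for ``t_bs`` (pure T2 decay), and a
spoiling interval ``t_sp`` (T1 relaxation).  One *shot* is a preparation
block followed by ``k`` RF excitations/readouts at flip angle ``alpha`` and
repetition time ``tr``.

All times are milliseconds; flip angles are degrees at every interface and
converted to radians internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import yaml

__all__ = [
    "TissueParams",
    "SequenceParams",
    "Measurement",
    "Protocol",
    "get_protocol",
    "PROTOCOL_PRESETS",
]


@dataclass(frozen=True)
class TissueParams:
    """Relaxation parameters of one voxel or isochromat.

    Parameters
    ----------
    t1 : float
        Longitudinal relaxation time, ms.  Must be positive.
    t2 : float
        Transverse relaxation time, ms.  Must be positive.
    m0 : float
        Equilibrium magnetization, arbitrary units.  Must be non-negative.

    Notes
    -----
    ``t2 > t1`` is physically implausible for liquids/tissue but only raises
    a warning: joint-fit bounds permit such combinations and the optimizer
    must be free to traverse them.
    """

    t1: float
    t2: float
    m0: float = 1.0

    def __post_init__(self) -> None:
        if not (self.t1 > 0):
            raise ValueError(f"t1 must be positive, got {self.t1}")
        if not (self.t2 > 0):
            raise ValueError(f"t2 must be positive, got {self.t2}")
        if not (self.m0 >= 0):
            raise ValueError(f"m0 must be non-negative, got {self.m0}")
        if self.t2 > self.t1:
            warnings.warn(
                f"t2 ({self.t2} ms) exceeds t1 ({self.t1} ms): physically "
                "implausible but allowed",
                stacklevel=2,
            )


@dataclass(frozen=True)
class SequenceParams:
    """Timing and flip angle of one shot of the (I-)SPGR sequence.

    ``t_fs``, ``t_bs`` and ``t_sp`` are the fat-suppression-plus-gap,
    blood-suppression (transverse) and spoiling durations in ms; setting all
    three to zero recovers a conventional steady-state SPGR acquisition.
    """

    tr: float
    alpha: float  # degrees
    k: int = 1
    t_fs: float = 0.0
    t_bs: float = 0.0
    t_sp: float = 0.0

    def __post_init__(self) -> None:
        if not (self.tr > 0):
            raise ValueError(f"tr must be positive, got {self.tr}")
        if not (0.0 <= self.alpha <= 90.0):
            raise ValueError(f"alpha must be in [0, 90] degrees, got {self.alpha}")
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        for name in ("t_fs", "t_bs", "t_sp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def shot_duration(self) -> float:
        """Total duration of one shot (readout train plus preparation), ms."""
        return self.k * self.tr + self.t_fs + self.t_bs + self.t_sp


@dataclass(frozen=True)
class Measurement:
    """One acquired image: nominal flip angle (deg) with its preparation timings."""

    alpha: float
    t_bs: float = 0.0
    t_sp: float = 0.0


@dataclass(frozen=True)
class Protocol:
    """Ordered list of measurements sharing TR, shot length ``k`` and ``t_fs``.

    T1 sensitivity is generated by varying the flip angle, T2 sensitivity by
    varying the blood-suppression duration, so a protocol intended for a
    joint three-parameter fit should contain at least two distinct flip
    angles and two distinct ``t_bs`` values.
    """

    tr: float
    k: int
    t_fs: float
    measurements: tuple[Measurement, ...]
    name: str = ""
    te: float | None = None  # echo time, metadata only

    def __post_init__(self) -> None:
        if len(self.measurements) == 0:
            raise ValueError("protocol needs at least one measurement")
        object.__setattr__(self, "measurements", tuple(self.measurements))
        if len(self.measurements) < 3:
            warnings.warn(
                "fewer than 3 measurements: a joint T1/T2/M0 fit is "
                "under-determined",
                stacklevel=2,
            )
        # validate shared timing through SequenceParams invariants
        self.sequence_params(0)

    def __len__(self) -> int:
        return len(self.measurements)

    @property
    def alphas(self) -> np.ndarray:
        return np.array([m.alpha for m in self.measurements], dtype=float)

    @property
    def t_bss(self) -> np.ndarray:
        return np.array([m.t_bs for m in self.measurements], dtype=float)

    @property
    def t_sps(self) -> np.ndarray:
        return np.array([m.t_sp for m in self.measurements], dtype=float)

    def sequence_params(self, index: int) -> SequenceParams:
        """Full per-shot sequence parameters of measurement ``index``."""
        m = self.measurements[index]
        return SequenceParams(
            tr=self.tr, alpha=m.alpha, k=self.k,
            t_fs=self.t_fs, t_bs=m.t_bs, t_sp=m.t_sp,
        )

    def reference_index(self) -> int:
        """Index of the reference measurement used to define SNR.

        The measurement closest to the Ernst angle for mid-range T1 carries
        the most signal; here that is flip angle 10 deg at the shortest
        blood-suppression duration.  Falls back to the measurement with the
        smallest ``(|alpha - 10|, t_bs)`` pair.
        """
        keys = [(abs(m.alpha - 10.0), m.t_bs, i) for i, m in enumerate(self.measurements)]
        return min(keys)[2]

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "tr": self.tr,
            "k": self.k,
            "t_fs": self.t_fs,
            "te": self.te,
            "measurements": [
                {"alpha": m.alpha, "t_bs": m.t_bs, "t_sp": m.t_sp}
                for m in self.measurements
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Protocol":
        return cls(
            tr=float(d["tr"]),
            k=int(d["k"]),
            t_fs=float(d.get("t_fs", 0.0)),
            te=d.get("te"),
            name=d.get("name", ""),
            measurements=tuple(
                Measurement(float(m["alpha"]), float(m.get("t_bs", 0.0)),
                            float(m.get("t_sp", 0.0)))
                for m in d["measurements"]
            ),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "Protocol":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def _ispgr_measurements() -> tuple[Measurement, ...]:
    # Four flip angles at the shortest available blood-suppression duration
    # (13 ms), plus two longer durations at the near-Ernst flip angle of 10
    # deg; spoiling duration is paired with t_bs (10/14/21 ms for 13/20/35 ms).
    return (
        Measurement(25.0, 13.0, 10.0),
        Measurement(20.0, 13.0, 10.0),
        Measurement(10.0, 13.0, 10.0),
        Measurement(4.0, 13.0, 10.0),
        Measurement(10.0, 20.0, 14.0),
        Measurement(10.0, 35.0, 21.0),
    )


def _preset_phantom_spgr() -> Protocol:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return Protocol(
            tr=6.6, k=1, t_fs=0.0, te=1.2, name="phantom_spgr",
            measurements=tuple(Measurement(a) for a in (25.0, 20.0, 15.0, 10.0, 5.0, 2.0)),
        )


def _preset_phantom_ispgr() -> Protocol:
    return Protocol(
        tr=6.6, k=30, t_fs=110.0, te=1.2, name="phantom_ispgr",
        measurements=_ispgr_measurements(),
    )


def _preset_invivo_ispgr() -> Protocol:
    return Protocol(
        tr=3.5, k=30, t_fs=202.0, te=1.2, name="invivo_ispgr",
        measurements=_ispgr_measurements(),
    )


PROTOCOL_PRESETS = {
    "phantom_spgr": _preset_phantom_spgr,
    "phantom_ispgr": _preset_phantom_ispgr,
    "invivo_ispgr": _preset_invivo_ispgr,
}


def get_protocol(name: str, t_fs: float | None = None) -> Protocol:
    """Return a named protocol preset.

    Presets
    -------
    ``phantom_spgr``
        Conventional steady-state SPGR at TR 6.6 ms with flip angles
        25/20/15/10/5/2 deg and no preparation.
    ``phantom_ispgr``
        Blood- and fat-suppressed I-SPGR at TR 6.6 ms, 30 readouts per shot,
        ``t_fs`` 110 ms.
    ``invivo_ispgr``
        The in-vivo variant at TR 3.5 ms, 30 readouts per shot, ``t_fs``
        202 ms.

    The two reported fat-suppression durations (110 and 202 ms) are assigned
    by shot-length matching: the phantom scan's gap was shortened so the
    total shot length matches the in-vivo scan despite its longer TR
    (110 + 30 x 6.6 = 308 ms vs 202 + 30 x 3.5 = 307 ms).  Pass ``t_fs`` to
    override the assignment.

    Parameters
    ----------
    name : str
        Preset name.
    t_fs : float, optional
        Override the preset's fat-suppression-plus-gap duration, ms.
    """
    try:
        proto = PROTOCOL_PRESETS[name]()
    except KeyError:
        raise KeyError(
            f"unknown protocol preset {name!r}; available: "
            f"{sorted(PROTOCOL_PRESETS)}"
        ) from None
    if t_fs is not None:
        proto = replace(proto, t_fs=float(t_fs))
    return proto
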