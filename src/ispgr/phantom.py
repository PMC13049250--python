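"""Digital multi-vial phantom and forward acquisition simulation.

The standard preset emulates a cylindrical relaxometry phantom with eight
MnCl2-doped vials whose reference T1 values span 236-2013 ms and T2 values
span 15-328 ms.  Only the endpoints of those ranges are published; the
intermediate vials are log-spaced between them (MnCl2 concentration scales
both relaxation rates roughly geometrically), so per-vial ground truth is
synthetic by construction and should be read as "a phantom like the real
one", not the manufacturer's calibration sheet.

The forward simulator composes the closed-form semi-steady-state signal
model per voxel (flip angles scaled by the local B1+ ratio), then adds
noise.  The default noise model is additive Gaussian on the magnitude
images at a requested SNR, defined as

    snr = mean noiseless signal of the reference measurement over
          nonzero-M0 voxels  /  standard deviation of the added noise,

with the reference measurement defaulting to the near-Ernst acquisition
(flip angle 10 deg at the shortest blood-suppression duration).  A Rician
option is available for realism studies.

k-space effects (undersampling streaks, motion) are deliberately not
simulated; the stacks represent ideal reconstructions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .images import ImageStack
from .params import Protocol, TissueParams
from .signal_model import forward_signals

__all__ = [
    "Vial",
    "DigitalPhantom",
    "NoiseModel",
    "make_phantom",
    "simulate_stack",
    "paired_replicates",
]

T1_RANGE_MS = (236.0, 2013.0)
T2_RANGE_MS = (15.0, 328.0)


@dataclass(frozen=True)
class Vial:
    """A cylindrical vial: in-plane center and radius in voxels."""

    center: tuple[float, float]
    radius: float
    tissue: TissueParams


@dataclass(frozen=True)
class DigitalPhantom:
    """Voxelized phantom: vial geometry plus per-voxel ground-truth maps."""

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]  # mm
    vials: tuple[Vial, ...]
    background: TissueParams = field(
        default_factory=lambda: TissueParams(t1=1000.0, t2=100.0, m0=0.0)
    )

    def __post_init__(self) -> None:
        for i, a in enumerate(self.vials):
            for b in self.vials[i + 1:]:
                d = np.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1])
                if d < a.radius + b.radius:
                    raise ValueError("vials overlap")

    @property
    def labels(self) -> np.ndarray:
        """Integer label map: 0 background, 1..n_vials."""
        nx, ny, nz = self.shape
        xx, yy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
        plane = np.zeros((nx, ny), dtype=int)
        for i, v in enumerate(self.vials, start=1):
            inside = (xx - v.center[0]) ** 2 + (yy - v.center[1]) ** 2 <= v.radius ** 2
            plane[inside] = i
        return np.repeat(plane[:, :, None], nz, axis=2)

    def _param_map(self, attr: str) -> np.ndarray:
        lab = self.labels
        values = np.array(
            [getattr(self.background, attr)]
            + [getattr(v.tissue, attr) for v in self.vials]
        )
        return values[lab]

    @property
    def t1_map(self) -> np.ndarray:
        return self._param_map("t1")

    @property
    def t2_map(self) -> np.ndarray:
        return self._param_map("t2")

    @property
    def m0_map(self) -> np.ndarray:
        return self._param_map("m0")

    def reference_table(self):
        """Per-vial ground truth as a DataFrame (label, t1, t2, m0)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "label": np.arange(1, len(self.vials) + 1),
                "t1": [v.tissue.t1 for v in self.vials],
                "t2": [v.tissue.t2 for v in self.vials],
                "m0": [v.tissue.m0 for v in self.vials],
            }
        ).set_index("label")


@dataclass(frozen=True)
class NoiseModel:
    """Noise added to the simulated magnitude images.

    ``kind`` is ``"gaussian_magnitude"`` (additive Gaussian on the
    magnitude) or ``"rician"`` (Gaussian on both quadrature channels before
    the magnitude).  ``reference`` picks the measurement whose mean
    noiseless signal defines the SNR; ``None`` selects the near-Ernst
    measurement of the protocol.
    """

    kind: str = "gaussian_magnitude"
    snr: float = 30.0
    reference: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian_magnitude", "rician"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if not (self.snr > 0):
            raise ValueError("snr must be positive")


def make_phantom(
    preset: str = "standard_8vial",
    shape: tuple[int, int, int] = (48, 48, 3),
    voxel_size: tuple[float, float, float] = (0.98, 0.98, 4.0),
    vials: Sequence[Vial] | None = None,
) -> DigitalPhantom:
    """Build a digital phantom.

    ``preset="standard_8vial"`` places eight equal vials on a ring, with T1
    log-spaced over 236-2013 ms and T2 log-spaced over 15-328 ms, paired in
    increasing order (decreasing MnCl2 concentration raises both).  Pass
    ``vials`` explicitly (with ``preset="custom"``) for arbitrary layouts.
    """
    if vials is not None:
        return DigitalPhantom(shape=tuple(shape), voxel_size=tuple(voxel_size),
                              vials=tuple(vials))
    if preset != "standard_8vial":
        raise ValueError(f"unknown preset {preset!r}")
    nx, ny, _ = shape
    n_vials = 8
    ring_r = 0.32 * min(nx, ny)
    vial_r = 0.10 * min(nx, ny)
    t1s = np.geomspace(*T1_RANGE_MS, n_vials)
    t2s = np.geomspace(*T2_RANGE_MS, n_vials)
    built = []
    for i in range(n_vials):
        ang = 2.0 * np.pi * i / n_vials
        center = (nx / 2.0 + ring_r * np.cos(ang), ny / 2.0 + ring_r * np.sin(ang))
        built.append(Vial(center=center, radius=vial_r,
                          tissue=TissueParams(t1=float(t1s[i]), t2=float(t2s[i]), m0=1.0)))
    return DigitalPhantom(shape=tuple(shape), voxel_size=tuple(voxel_size),
                          vials=tuple(built))


def _noiseless_volumes(phantom: DigitalPhantom, protocol: Protocol, b1) -> np.ndarray:
    t1 = phantom.t1_map.ravel()
    t2 = phantom.t2_map.ravel()
    m0 = phantom.m0_map.ravel()
    scale = (np.broadcast_to(np.asarray(b1, dtype=float), phantom.shape)).ravel()
    sig = forward_signals(t1, t2, m0, protocol, alpha_scale=scale)  # (nvox, m)
    return np.moveaxis(sig.reshape(*phantom.shape, len(protocol)), -1, 0)


def simulate_stack(
    phantom: DigitalPhantom,
    protocol: Protocol,
    b1=1.0,
    noise: NoiseModel | None = None,
    rng: np.random.Generator | None = None,
) -> ImageStack:
    """Forward-simulate the multi-measurement image stack of a phantom.

    Parameters
    ----------
    phantom : DigitalPhantom
    protocol : Protocol
    b1 : float or ndarray
        B1+ actual-to-nominal ratio, scalar or a map broadcastable to the
        phantom grid.
    noise : NoiseModel, optional
        ``None`` produces a noiseless stack.
    rng : numpy Generator, optional
        Overrides the generator seeded from ``noise.seed``.
    """
    clean = _noiseless_volumes(phantom, protocol, b1)
    labels = phantom.labels
    volumes = clean
    meta = {"protocol": protocol.to_dict(), "noise": None}
    if noise is not None:
        rng = rng if rng is not None else np.random.default_rng(noise.seed)
        ref = noise.reference if noise.reference is not None else protocol.reference_index()
        inside = labels > 0
        mean_ref = float(clean[ref][inside].mean())
        sigma = mean_ref / noise.snr
        if noise.kind == "gaussian_magnitude":
            volumes = clean + rng.normal(0.0, sigma, size=clean.shape)
        else:  # rician
            volumes = np.abs(
                clean
                + rng.normal(0.0, sigma, size=clean.shape)
                + 1j * rng.normal(0.0, sigma, size=clean.shape)
            )
        meta["noise"] = {"kind": noise.kind, "snr": noise.snr,
                         "reference": ref, "sigma": sigma, "seed": noise.seed}
    b1_map = np.broadcast_to(np.asarray(b1, dtype=float), phantom.shape).copy()
    return ImageStack(volumes=volumes, b1_ratio=b1_map, mask=labels, meta=meta)


def paired_replicates(
    phantom: DigitalPhantom,
    protocol: Protocol,
    noise: NoiseModel,
    n_pairs: int,
    b1=1.0,
    seed: int | None = None,
) -> list[tuple[ImageStack, ImageStack]]:
    """Repeatability pairs: shared phantom, independent noise per replicate.

    Each pair mimics a scan repeated within one session.  Seeds are derived
    deterministically from ``seed`` (default: ``noise.seed``).
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    root = noise.seed if seed is None else seed
    ss = np.random.SeedSequence(root)
    children = ss.spawn(2 * n_pairs)
    pairs = []
    for i in range(n_pairs):
        a = simulate_stack(phantom, protocol, b1, noise,
                           rng=np.random.default_rng(children[2 * i]))
        b = simulate_stack(phantom, protocol, b1, noise,
                           rng=np.random.default_rng(children[2 * i + 1]))
        pairs.append((a, b))
    return pairs
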