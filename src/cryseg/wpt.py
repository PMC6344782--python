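"""Wavelet packet decomposition and sub-band energies.

A level-``j`` wavelet packet transform (WPT) runs the low-pass/high-pass
filter pair of an orthogonal wavelet down a *full* binary tree, splitting
the band [0, fs/2] into 2^j equal-width sub-bands.  The reference
configuration is level 5 (32 bands) over Daubechies filters db1, db10
and db20; at 44.1 kHz each band then spans 689.0625 Hz.

Terminal nodes are returned in natural frequency order (the Gray-code
reordering of the filter-bank paths), so band ``k`` covers
``[k, k+1] * fs / 2**(level+1)`` Hz.  Periodic ("wrap-around") boundary
extension is used, which makes the transform orthonormal: perfect
reconstruction and Parseval energy conservation hold exactly when the
frame length is a multiple of 2**level (otherwise PyWavelets pads
internally and reconstruction is still exact after truncation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

__all__ = ["WaveletSpec", "WPTree", "SubbandEnergies", "packet_tree",
           "subband_energies", "reconstruct"]

_FAMILIES = ("db1", "db10", "db20")


@dataclass(frozen=True)
class WaveletSpec:
    """Wavelet family and decomposition depth (reference: level 5)."""

    family: str = "db10"
    level: int = 5

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"family must be one of {_FAMILIES}")
        if self.level < 1:
            raise ValueError("level must be >= 1")

    @property
    def n_bands(self) -> int:
        return 2 ** self.level


@dataclass
class WPTree:
    """Terminal-node coefficients of one frame, in frequency order."""

    nodes: list[np.ndarray]
    paths: list[str]
    length: int
    spec: WaveletSpec


@dataclass
class SubbandEnergies:
    """Normalized (mean-square) energy per frequency band."""

    energies: np.ndarray
    band_edges_hz: np.ndarray = field(default=None)

    @property
    def n_bands(self) -> int:
        return self.energies.size


def band_edges_hz(spec: WaveletSpec, rate: float) -> np.ndarray:
    """The 2^level + 1 band edges in Hz spanning [0, rate/2]."""
    return np.linspace(0.0, rate / 2.0, spec.n_bands + 1)


def packet_tree(frame: np.ndarray, spec: WaveletSpec) -> WPTree:
    """Full wavelet packet decomposition of one frame."""
    frame = np.asarray(frame, dtype=np.float64)
    if frame.size < spec.n_bands:
        raise ValueError(
            f"frame of {frame.size} samples too short for level {spec.level} "
            f"(needs >= {spec.n_bands})"
        )
    wp = pywt.WaveletPacket(data=frame, wavelet=spec.family,
                            mode="periodization", maxlevel=spec.level)
    leaves = wp.get_level(spec.level, order="freq")
    return WPTree(
        nodes=[leaf.data.copy() for leaf in leaves],
        paths=[leaf.path for leaf in leaves],
        length=frame.size,
        spec=spec,
    )


def subband_energies(tree: WPTree, rate: float | None = None) -> SubbandEnergies:
    """E_j = (1/N_j) * sum_m coeff_j(m)^2 per band, frequency-ordered."""
    e = np.array([np.mean(node**2) for node in tree.nodes])
    edges = band_edges_hz(tree.spec, rate) if rate is not None else None
    return SubbandEnergies(energies=e, band_edges_hz=edges)


def reconstruct(tree: WPTree, spec: WaveletSpec | None = None) -> np.ndarray:
    """Invert the packet filter bank; exact for orthogonal families."""
    spec = spec or tree.spec
    if len(tree.nodes) != spec.n_bands:
        raise ValueError(
            f"need all {spec.n_bands} terminal nodes, got {len(tree.nodes)}"
        )
    wp = pywt.WaveletPacket(data=None, wavelet=spec.family,
                            mode="periodization", maxlevel=spec.level)
    for path, data in zip(tree.paths, tree.nodes):
        wp[path] = data
    out = wp.reconstruct(update=False)
    return np.asarray(out)[: tree.length]
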