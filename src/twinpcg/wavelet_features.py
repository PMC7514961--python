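"""Wavelet-packet features: subband two-norms and energy entropy.

A level-``j`` wavelet-packet decomposition splits a signal into ``2**j``
subbands by recursively applying the low- and high-pass halves of an
orthogonal filter bank to *both* branches (unlike the plain DWT, which only
refines the low-pass branch). For heart sounds we use the full 4-level db6
decomposition: its 16 terminal nodes (4,0)...(4,15), kept in natural (Paley)
order, tile the spectrum from approximation to finest detail.

Two feature families are derived here:

* the two-norm ``||S_k||_2`` of each node's coefficient sequence (16 values),
  a subband-energy profile of the record;
* the wavelet-packet energy entropy ``H = -sum_k eps_k ln(eps_k)`` where
  ``eps_k`` is the fraction of total energy in node k - low when energy
  concentrates in a single band, ``ln 16`` when spread uniformly.

Boundary handling is periodization, which keeps the transform orthogonal so
that Parseval holds exactly: the node energies sum to the signal energy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .signal_io import HeartSoundRecord

DEFAULT_WAVELET = "db6"
DEFAULT_LEVEL = 4


@dataclass(frozen=True)
class WaveletPacketTable:
    """Terminal-node coefficients of a full wavelet-packet decomposition."""

    level: int
    node_coeffs: tuple[np.ndarray, ...]  # natural (Paley) order
    wavelet_name: str
    boundary_mode: str

    def __post_init__(self):
        if len(self.node_coeffs) != 2 ** self.level:
            raise ValueError(
                f"expected {2 ** self.level} nodes, got {len(self.node_coeffs)}"
            )


@dataclass(frozen=True)
class NodeEnergySpectrum:
    """Per-node energies and their fractions of the total."""

    energies: np.ndarray
    total: float
    fractions: np.ndarray


def wpt_decompose(
    record: HeartSoundRecord,
    wavelet: str = DEFAULT_WAVELET,
    level: int = DEFAULT_LEVEL,
) -> WaveletPacketTable:
    """Full fixed-depth wavelet-packet decomposition of a record.

    Returns all ``2**level`` terminal-node coefficient sequences in natural
    order, computed with periodization boundaries (energy preserving for
    orthogonal wavelets).
    """
    if level < 1:
        raise ValueError("level must be >= 1")
    wav = pywt.Wavelet(wavelet)
    if not wav.orthogonal:
        raise ValueError(f"wavelet {wavelet!r} is not orthogonal")
    n = record.samples.size
    min_len = 2 ** level
    if n < min_len:
        raise ValueError(
            f"record of length {n} too short for level {level}: "
            f"minimum length is {min_len}"
        )
    wp = pywt.WaveletPacket(record.samples, wav, mode="periodization",
                            maxlevel=level)
    nodes = wp.get_level(level, order="natural")
    coeffs = tuple(np.asarray(node.data, dtype=float) for node in nodes)
    return WaveletPacketTable(level=level, node_coeffs=coeffs,
                              wavelet_name=wavelet,
                              boundary_mode="periodization")


def node_norms(table: WaveletPacketTable) -> np.ndarray:
    """Euclidean norm of each terminal node's coefficients, in node order."""
    return np.array([np.linalg.norm(c) for c in table.node_coeffs])


def energy_spectrum(table: WaveletPacketTable) -> NodeEnergySpectrum:
    """Node energies E_k = sum_i S_k(i)^2 and fractions eps_k = E_k / E."""
    energies = np.array([float(np.sum(c * c)) for c in table.node_coeffs])
    total = float(energies.sum())
    if total <= 0.0:
        raise ValueError("zero-energy signal has undefined entropy")
    return NodeEnergySpectrum(energies=energies, total=total,
                              fractions=energies / total)


def energy_entropy(spectrum: NodeEnergySpectrum) -> float:
    """Shannon entropy (natural log) of the subband energy distribution.

    ``0 * ln 0`` is taken as 0, so a spectrum with all energy in one node
    has entropy exactly 0; the uniform spectrum attains the maximum
    ``ln(n_nodes)``.
    """
    eps = spectrum.fractions
    nz = eps[eps > 0.0]
    return float(-np.sum(nz * np.log(nz)))
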