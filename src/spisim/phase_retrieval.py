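"""Iterative phase retrieval: Error Reduction and Hybrid Input-Output.

Given oversampled Fourier amplitudes and a real-space support, alternate
between the modulus constraint (replace the Fourier magnitude by the data)
and the support constraint.  ER projects onto the support (zero outside);
HIO applies the Fienup feedback g - beta g' outside the support, which
escapes the local minima ER stalls in.  The field-standard schedule is a
long HIO run polished by a few ER iterations.  Reconstructions from
oversampled amplitudes are defined only up to a global translation and a
conjugate point reflection (the "twin image"); ``align_and_score`` removes
both ambiguities plus an overall scale before computing the error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ReconstructionResult",
    "check_support",
    "reconstruct",
    "hio_er",
    "align_and_score",
]

logger = logging.getLogger(__name__)


@dataclass
class ReconstructionResult:
    """Support-constrained density with the per-iteration Fourier residual."""

    density: np.ndarray
    error_series: np.ndarray
    iterations: int
    algorithm: str
    beta: float | None = None
    seed: int | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.error_series) != self.iterations:
            raise ValueError("error series length must equal iteration count")


def check_support(support: np.ndarray) -> np.ndarray:
    support = np.asarray(support, dtype=bool)
    n_in = int(support.sum())
    if n_in == 0:
        raise ValueError("support is empty")
    if n_in >= support.size / 2:
        raise ValueError(
            f"support area {n_in} violates oversampling (needs < half of {support.size})"
        )
    return support


def _fourier_project(g: np.ndarray, amplitudes: np.ndarray):
    """Replace Fourier magnitudes with the data; return update and residual."""
    G = np.fft.fft2(g)
    mag = np.abs(G)
    residual = float(np.linalg.norm(mag - amplitudes) / np.linalg.norm(amplitudes))
    phase = np.where(mag > 1e-300, G / np.maximum(mag, 1e-300), 1.0)
    return np.fft.ifft2(amplitudes * phase), residual


def reconstruct(
    amplitudes: np.ndarray,
    support: np.ndarray,
    algorithm: str = "HIO",
    beta: float = 0.9,
    n_iter: int = 500,
    seed: int = 0,
    initial: np.ndarray | None = None,
    reality: bool = True,
    positivity: bool = False,
) -> ReconstructionResult:
    """Run ER or HIO from a seeded random-phase start.

    With ``reality`` (default) the object update keeps the real part,
    appropriate for amplitudes of a real density (Friedel-symmetric data);
    ``positivity`` additionally treats negative pixels as constraint
    violations (electron densities are nonnegative).  ``initial``
    warm-starts the iterate (used to chain HIO -> ER).
    """
    amplitudes = np.asarray(amplitudes, dtype=float)
    if np.any(amplitudes < 0):
        raise ValueError("amplitudes must be >= 0")
    support = check_support(support)
    if algorithm not in ("ER", "HIO"):
        raise ValueError(f"unknown algorithm {algorithm!r}")

    if initial is None:
        rng = np.random.default_rng(seed)
        phases = np.exp(2j * np.pi * rng.random(amplitudes.shape))
        g = np.fft.ifft2(amplitudes * phases)
        g = g.real if reality else g
        g = np.where(support, g, 0.0)  # start inside the support constraint
    else:
        g = initial.real if reality else initial.astype(complex)

    errors = np.empty(n_iter)
    for it in range(n_iter):
        g_prime, errors[it] = _fourier_project(g, amplitudes)
        if reality:
            g_prime = g_prime.real
        violation = ~support
        if positivity:
            violation = violation | (np.real(g_prime) < 0)
        if algorithm == "ER":
            g = np.where(violation, 0.0, g_prime)
        else:
            g = np.where(violation, g - beta * g_prime, g_prime)

    final = np.where(support, g_prime, 0.0)
    if not reality:
        total = final.sum()
        if np.abs(total) > 0:
            final = final * np.exp(-1j * np.angle(total))
    return ReconstructionResult(
        np.real(final), errors, n_iter, algorithm,
        beta if algorithm == "HIO" else None, seed,
        metadata={"complex_iterate": g, "reality": reality, "positivity": positivity},
    )


def hio_er(
    amplitudes: np.ndarray,
    support: np.ndarray,
    n_hio: int = 500,
    n_er: int = 100,
    beta: float = 0.9,
    seed: int = 0,
    reality: bool = True,
    positivity: bool = False,
) -> ReconstructionResult:
    """Field-standard schedule: HIO exploration then ER polishing."""
    first = reconstruct(
        amplitudes, support, "HIO", beta, n_hio, seed,
        reality=reality, positivity=positivity,
    )
    second = reconstruct(
        amplitudes, support, "ER", beta, n_er, seed,
        initial=first.metadata["complex_iterate"],
        reality=reality, positivity=positivity,
    )
    return ReconstructionResult(
        second.density,
        np.concatenate([first.error_series, second.error_series]),
        n_hio + n_er,
        "HIO+ER",
        beta,
        seed,
    )


def _point_reflect(a: np.ndarray) -> np.ndarray:
    """a[i, j] -> a[-i mod n, -j mod m] (twin-image partner for real data)."""
    return np.roll(a[::-1, ::-1], (1, 1), axis=(0, 1))


def align_and_score(reconstruction: np.ndarray, truth: np.ndarray) -> float:
    """Normalized L2 error after removing the phasing ambiguities.

    Minimizes over integer translations and the conjugate point reflection,
    then applies the optimal scalar rescale: ||alpha a - b|| / ||b||.
    """
    a = np.asarray(reconstruction, dtype=float)
    b = np.asarray(truth, dtype=float)
    if a.shape != b.shape:
        raise ValueError("shapes must match")
    norm_b = np.linalg.norm(b)
    if norm_b == 0:
        raise ValueError("truth is identically zero")

    B = np.fft.fft2(b)
    best = np.inf
    for cand in (a, _point_reflect(a)):
        corr = np.fft.ifft2(B * np.conj(np.fft.fft2(cand))).real
        # the optimal scalar may be negative (global sign ambiguity), so the
        # best translation maximizes |correlation|
        shift = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
        rolled = np.roll(cand, shift, axis=(0, 1))
        denom = float(np.sum(rolled * rolled))
        alpha = float(np.sum(rolled * b)) / denom if denom > 0 else 0.0
        err = np.linalg.norm(alpha * rolled - b) / norm_b
        best = min(best, float(err))
    return best
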