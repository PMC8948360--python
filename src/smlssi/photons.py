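"""Forward photon-count model: exposure probabilities and sampled counts.

For an emitter at r_E interrogated by K exposures with the minimum at r_i,
the expected counts are lambda_i ~ I^c(r_E - r_i) plus a uniform background.
Counts are Poisson; conditioning on the total detected photon budget N (the
fixed-N convention used throughout) makes the count vector multinomial with
probabilities

    p_i = (SBR / (SBR + 1)) * u_i / sum_j u_j  +  1 / (K * (SBR + 1)),

where u_i = I^c(r_E - r_i) and SBR is the signal-to-background ratio, defined
for an emitter at the pattern center with background spread uniformly over
the exposures.  Conditioning removes the nuisance brightness parameter and
leaves the position information untouched (the Fisher information for r_E is
identical under the Poisson and multinomial descriptions).

``SBR = inf`` gives the pure-signal model; ``SBR -> 0`` gives uniform counts
carrying no position information.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .beams import (
    BeamProfile,
    effective_excitation,
    effective_excitation_gradient,
)
from .exceptions import InvalidParameterError
from .sequences import ExcitationSequence

__all__ = [
    "Scenario",
    "CountRecord",
    "exposure_probabilities",
    "expected_counts",
    "sample_counts",
    "generate_fixture_dataset",
]


@dataclass(frozen=True)
class Scenario:
    """Full forward model for one localization configuration.

    Combines the beam, the excitation sequence, the excitation order ``c``,
    the photon budget ``N``, the signal-to-background ratio and the emitter
    position (nm).
    """

    beam: BeamProfile
    sequence: ExcitationSequence
    order: float = 1.0
    N: int = 500
    SBR: float = 4.0
    emitter_position: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self) -> None:
        if not np.isfinite(self.order) or self.order < 1.0:
            raise InvalidParameterError(
                f"excitation order must be a finite real >= 1, got {self.order}"
            )
        if int(self.N) != self.N or self.N < 1:
            raise InvalidParameterError(f"N must be a positive integer, got {self.N}")
        if not (self.SBR > 0):  # inf is allowed
            raise InvalidParameterError(f"SBR must be > 0 (or inf), got {self.SBR}")
        pos = np.asarray(self.emitter_position, dtype=float)
        if pos.shape != (2,) or not np.all(np.isfinite(pos)):
            raise InvalidParameterError("emitter_position must be a finite 2-vector")
        object.__setattr__(self, "emitter_position", pos)
        object.__setattr__(self, "N", int(self.N))

    @property
    def K(self) -> int:
        return self.sequence.K

    def at(self, position: np.ndarray) -> "Scenario":
        """Copy of this scenario with the emitter moved to ``position``."""
        return replace(self, emitter_position=np.asarray(position, dtype=float))


@dataclass(frozen=True)
class CountRecord:
    """Measured photon counts for one localization event."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 1 or np.any(counts < 0) or np.any(counts != np.round(counts)):
            raise InvalidParameterError("counts must be a 1-D vector of nonnegative integers")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def _signal_weights(
    positions: np.ndarray,
    centers: np.ndarray,
    beam: BeamProfile,
    order: float,
) -> tuple[np.ndarray, np.ndarray]:
    """u_i = I^c(r - r_i) and its position gradient for a batch of positions.

    ``positions``: (..., 2); ``centers``: (K, 2).
    Returns (u, grad_u) with shapes (..., K) and (..., K, 2); the gradient is
    taken with respect to the emitter position r.
    """
    disp = positions[..., np.newaxis, :] - centers  # (..., K, 2)
    u = effective_excitation(beam, disp, order)
    grad_u = effective_excitation_gradient(beam, disp, order)
    return u, grad_u


def _probabilities_batch(
    positions: np.ndarray,
    centers: np.ndarray,
    beam: BeamProfile,
    order: float,
    sbr: float,
    with_gradients: bool = False,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Exposure probabilities (and optionally their gradients) at many positions.

    Returns ``(p, grad_p)`` with shapes (..., K) and (..., K, 2); ``grad_p``
    is None unless requested.  Positions where all signal weights vanish
    (emitter exactly on every minimum at once; only possible for K = 1) fall
    back to uniform signal weights with zero gradient.
    """
    positions = np.asarray(positions, dtype=float)
    K = centers.shape[0]
    u, grad_u = _signal_weights(positions, centers, beam, order)
    U = u.sum(axis=-1, keepdims=True)
    degenerate = U <= 0.0
    safe_U = np.where(degenerate, 1.0, U)
    w = np.where(degenerate, 1.0 / K, u / safe_U)

    if np.isinf(sbr):
        signal_frac, background = 1.0, 0.0
    else:
        signal_frac = sbr / (sbr + 1.0)
        background = 1.0 / (K * (sbr + 1.0))
    p = signal_frac * w + background

    if not with_gradients:
        return p, None

    grad_U = grad_u.sum(axis=-2, keepdims=True)  # (..., 1, 2)
    grad_w = grad_u / safe_U[..., np.newaxis] - (
        u[..., np.newaxis] * grad_U / safe_U[..., np.newaxis] ** 2
    )
    grad_w = np.where(degenerate[..., np.newaxis], 0.0, grad_w)
    return p, signal_frac * grad_w


def exposure_probabilities(scenario: Scenario) -> np.ndarray:
    """Probability that a detected photon originates from each exposure.

    Length-K vector summing to 1, all entries nonnegative.
    """
    p, _ = _probabilities_batch(
        scenario.emitter_position,
        scenario.sequence.positions,
        scenario.beam,
        scenario.order,
        scenario.SBR,
    )
    return p


def expected_counts(scenario: Scenario) -> np.ndarray:
    """Expected photon counts lambda_i = N * p_i per exposure."""
    return scenario.N * exposure_probabilities(scenario)


def sample_counts(p: np.ndarray, N: int, seed) -> CountRecord:
    """One multinomial draw of ``N`` photons over the exposures.

    ``seed`` may be an integer or any ``numpy.random`` seed-like object
    (e.g. a ``SeedSequence`` or ``Generator``); draws are reproducible.
    """
    p = np.asarray(p, dtype=float)
    if int(N) != N or N < 1:
        raise InvalidParameterError(f"N must be a positive integer, got {N}")
    if abs(p.sum() - 1.0) > 1e-9 or np.any(p < 0):
        raise InvalidParameterError(
            f"p must be a probability vector (sum={p.sum()!r})"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = rng.multinomial(int(N), p / p.sum())
    return CountRecord(counts=counts)


def record_seed_sequence(master_seed: int, index: int) -> np.random.SeedSequence:
    """Independent, reproducible substream for record ``index``.

    Counter scheme: ``SeedSequence(master_seed, spawn_key=(index,))`` — every
    record can be regenerated in isolation from the master seed and its row
    index alone.
    """
    return np.random.SeedSequence(int(master_seed), spawn_key=(int(index),))


def generate_fixture_dataset(
    scenario: Scenario,
    true_positions: np.ndarray,
    repeats: int,
    seed: int,
) -> pd.DataFrame:
    """Synthetic count table for a grid of true emitter positions.

    One row per (position, repeat) with columns
    ``true_x_nm, true_y_nm, repeat, n_1 ... n_K, seed`` where ``seed`` is the
    per-record substream index.  Deterministic given ``seed``; per-exposure
    counts in each row sum to ``scenario.N``.
    """
    if repeats < 1:
        raise InvalidParameterError(f"repeats must be >= 1, got {repeats}")
    true_positions = np.atleast_2d(np.asarray(true_positions, dtype=float))
    rows = []
    index = 0
    for pos in true_positions:
        p = exposure_probabilities(scenario.at(pos))
        for rep in range(repeats):
            rng = np.random.default_rng(record_seed_sequence(seed, index))
            rec = sample_counts(p, scenario.N, rng)
            rows.append(
                {
                    "true_x_nm": pos[0],
                    "true_y_nm": pos[1],
                    "repeat": rep,
                    **{f"n_{i + 1}": int(c) for i, c in enumerate(rec.counts)},
                    "seed": index,
                }
            )
            index += 1
    return pd.DataFrame(rows)
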