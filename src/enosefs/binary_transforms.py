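"""Position-to-bit transforms: sigmoid baseline, Gaussian-CDF leader vote, min-max threshold.

A continuous optimizer position must be mapped to a {0,1} feature-inclusion
mask before the wrapper fitness can score it.  Three strategies are provided:

- ``sigmoid_binarize`` — the S-shaped transfer baseline used by binary GWO:
  each dimension is squashed through a steep sigmoid and compared to a uniform
  draw.
- ``approach1_binarize`` — leader vote: each of the three leaders casts a
  stochastic bit per dimension through the standard normal CDF of its
  attraction term; the output bit is the majority of the three votes.
- ``approach2_binarize`` — the agent's own position vector is min-max
  normalized across dimensions and thresholded against uniform draws, so the
  relative ordering of coordinates (not their absolute scale) decides bits.

All threshold comparisons use >= .
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .gwo_core import CoefficientDraw, Leader

SIGMOID_SLOPE = 10.0
SIGMOID_CENTER = 0.5


@dataclass
class LeaderVote:
    """Per-dimension leader vote record: CDF values and the derived bits."""

    gdt: np.ndarray   # (3, D) Gaussian CDF values in (0,1)
    bits: np.ndarray  # (3, D) individual leader votes in {0,1}


def gaussian_cdf(z) -> np.ndarray | float:
    """Standard normal CDF Phi(z); rejects non-finite input."""
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("gaussian_cdf requires finite input")
    out = norm.cdf(z)
    return float(out) if out.ndim == 0 else out


def approach1_binarize(
    leaders: list[Leader], coeffs: CoefficientDraw, rng: np.random.Generator
) -> tuple[np.ndarray, LeaderVote]:
    """Majority vote of three stochastic leader bits per dimension.

    For leader i and dimension d, GDT_i,d = Phi(x_leader_i,d - A_i,d * D_i,d)
    with the same A and D draws used in the continuous position update of this
    agent in this iteration; vote x_i,d = 1 iff GDT_i,d >= rand (independent
    uniforms per leader and dimension).  The output bit is 1 iff the mean of
    the three votes is >= 0.5, i.e. at least two leaders vote 1.
    """
    if coeffs.D_lead is None:
        raise ValueError("coefficient draw lacks leader distances; run the position update first")
    lead_pos = np.stack([ld.position for ld in leaders])
    gdt = norm.cdf(lead_pos - coeffs.A * coeffs.D_lead)
    votes = (gdt >= rng.random(gdt.shape)).astype(np.int8)
    mask = (votes.mean(axis=0) >= 0.5).astype(np.int8)
    return mask, LeaderVote(gdt=gdt, bits=votes)


def approach2_binarize(position: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Min-max normalize the agent's own position, then threshold against uniforms.

    NBT_d = (x_d - min(x)) / (max(x) - min(x)); bit_d = 1 iff NBT_d >= rand_d.
    The arg-max dimension always gets bit 1; the arg-min gets 0 whenever its
    draw is positive.  A constant position (max == min) is degenerate: NBT is
    set to 0.5 everywhere, i.e. a fair coin against each draw.
    """
    position = np.asarray(position, dtype=float)
    lo, hi = position.min(), position.max()
    if hi > lo:
        nbt = (position - lo) / (hi - lo)
    else:
        nbt = np.full_like(position, 0.5)
    return (nbt >= rng.random(position.shape)).astype(np.int8)


def sigmoid_binarize(position: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """S-shaped transfer baseline: s_d = 1/(1+exp(-10(x_d-0.5))), bit = s_d >= rand_d."""
    position = np.asarray(position, dtype=float)
    s = 1.0 / (1.0 + np.exp(-SIGMOID_SLOPE * (position - SIGMOID_CENTER)))
    return (s >= rng.random(position.shape)).astype(np.int8)
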