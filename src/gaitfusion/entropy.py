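"""Sample entropy of joint-angle sequences (movement complexity).

SampEn(m, r, N) = −ln(A/B), where B is the number of pairs of distinct
templates of length m whose Chebyshev distance is ≤ r, and A the same
count for length m + 1; self-matches are excluded.  Following the standard
formulation, both counts range over the N − m templates that admit an
(m+1)-length extension.  Higher values indicate a less regular, more
complex signal.

Defaults follow the usual biomechanical practice: embedding dimension
m = 2 and tolerance r = 0.1 × SD of the analyzed series, so the measure
adapts to the dynamic range of the data and is invariant under positive
rescaling.  An absolute-degrees tolerance mode is available.

Per subject, the entropy of each joint is computed once on the selected
normalized cycles concatenated in time order (a per-cycle-mean mode is
available as a configuration alternative).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .segmentation import GaitCycle

logger = logging.getLogger("gaitfusion.entropy")


@dataclass
class SampEnParams:
    """Embedding dimension, tolerance and tolerance mode."""

    m: int = 2
    r_frac: float = 0.1
    r_mode: str = "sd_relative"  # "sd_relative" | "absolute"

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("embedding dimension m must be >= 1")
        if self.r_frac <= 0:
            raise ValueError("tolerance must be > 0")
        if self.r_mode not in ("sd_relative", "absolute"):
            raise ValueError(f"unknown r_mode {self.r_mode!r}")


@dataclass
class EntropyFeatures:
    """Sample entropy of the hip, knee and ankle angle sequences, nats."""

    se_hip: float
    se_knee: float
    se_ankle: float

    def as_dict(self) -> dict[str, float]:
        return {"se_hip": self.se_hip, "se_knee": self.se_knee, "se_ankle": self.se_ankle}


def _match_count(x: np.ndarray, m: int, r: float, n_templates: int) -> int:
    """Number of ordered-distinct template pairs of length ``m`` within ``r``.

    Chebyshev distance; counts unordered pairs i < j over the first
    ``n_templates`` starting positions.
    """
    # embed: rows are templates x[i:i+m]
    emb = np.lib.stride_tricks.sliding_window_view(x, m)[:n_templates]
    count = 0
    for i in range(len(emb) - 1):
        d = np.max(np.abs(emb[i + 1 :] - emb[i]), axis=1)
        count += int(np.count_nonzero(d <= r))
    return count


def sample_entropy(series: np.ndarray, params: SampEnParams | None = None) -> float:
    """SampEn of one series; see the module docstring for conventions.

    Returns 0.0 (with a warning) for a zero-variance series, and +inf
    (with a warning stating the reason) when no template pair matches at
    length m + 1.
    """
    params = params or SampEnParams()
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    n = len(x)
    if n <= params.m + 1:
        raise ValueError(f"series length {n} must exceed m + 1 = {params.m + 1}")
    sd = float(np.std(x))
    if sd < 1e-15:
        warnings.warn("zero-variance series: sample entropy defined as 0")
        return 0.0
    r = params.r_frac * sd if params.r_mode == "sd_relative" else params.r_frac

    n_templates = n - params.m  # templates admitting an (m+1)-extension
    b = _match_count(x, params.m, r, n_templates)
    a = _match_count(x, params.m + 1, r, n_templates)
    if b == 0:
        warnings.warn("no template matches at length m: sample entropy undefined (+inf)")
        return float("inf")
    if a == 0:
        warnings.warn(
            "no template matches at length m+1: sample entropy undefined (+inf)"
        )
        return float("inf")
    return float(-np.log(a / b))


def joint_entropies(
    cycles: list[GaitCycle],
    params: SampEnParams | None = None,
    mode: str = "concatenated",
) -> EntropyFeatures:
    """Per-joint sample entropy of a subject's selected cycles.

    ``concatenated`` (default): cycles are concatenated in time order into
    one sequence per joint and SampEn computed once on it.
    ``per_cycle_mean``: SampEn per cycle, averaged.
    """
    if not cycles:
        raise ValueError("need at least one cycle")
    if mode not in ("concatenated", "per_cycle_mean"):
        raise ValueError(f"unknown entropy input mode {mode!r}")
    params = params or SampEnParams()
    ordered = sorted(cycles, key=lambda c: c.start_index)
    values: dict[str, float] = {}
    for joint, key in (("hip", "se_hip"), ("knee", "se_knee"), ("ankle", "se_ankle")):
        if mode == "concatenated":
            seq = np.concatenate([getattr(c, joint) for c in ordered])
            values[key] = sample_entropy(seq, params)
        else:
            values[key] = float(
                np.mean([sample_entropy(getattr(c, joint), params) for c in ordered])
            )
    return EntropyFeatures(**values)
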