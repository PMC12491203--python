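"""Gait-event detection and cycle segmentation from the ankle-angle trace.

The ankle trace is the primary event marker.  Under the package sign
convention (dorsiflexion positive), toe-off is the maximum plantarflexion
angle, i.e. the most-negative local extremum of the trace, detected with a
minimum peak separation of half the median inter-trough interval to
suppress double peaks.  Heel strike — the initiation point of ankle-angle
change after swing — is operationalized as the first +→− zero-crossing of
the smoothed first difference following each plantarflexion trough (the
first local maximum of the trace, i.e. the end-swing dorsiflexion peak
preceding the loading-response plantarflexion), subject to a prominence
floor of ``onset_prominence_frac`` of the trace's range of motion so that
noise wiggles on the flat swing plateau are ignored.  This onset rule is
a package convention: the
qualitative event description admits no unique numeric criterion, so the
rule is explicit and configurable.

A light moving average (default width 5) is applied only inside event
detection; exported angles are never smoothed.

A gait cycle runs heel strike to next heel strike and must contain exactly
one toe-off; the stance phase is heel strike → toe-off (physiologically
about 60% of the cycle) and the swing phase toe-off → next heel strike.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .io import JointAngleSeries, TrialRecording
from .preprocessing import resample_to_cycle

logger = logging.getLogger("gaitfusion.segmentation")

# Of trace RoM. The toe-off trough is the global per-cycle minimum and spans
# most of the ankle RoM; smaller dips (loading response) must not qualify.
TROUGH_PROMINENCE_FRAC = 0.4


class EventDetectionError(ValueError):
    """No usable gait events could be found in the trace."""


@dataclass(frozen=True)
class GaitEvent:
    kind: str  # "heel_strike" | "toe_off"
    sample_index: int
    time_s: float


@dataclass
class GaitCycle:
    """One heel-strike-to-heel-strike segment, time-normalized per joint."""

    start_index: int
    toe_off_index: int
    end_index: int
    stance_fraction: float
    hip: np.ndarray
    knee: np.ndarray
    ankle: np.ndarray

    def __post_init__(self) -> None:
        if not self.start_index < self.toe_off_index < self.end_index:
            raise ValueError("require start < toe_off < end")
        if not 0.0 < self.stance_fraction < 1.0:
            raise ValueError("stance_fraction must lie in (0, 1)")
        for name in ("hip", "knee", "ankle"):
            arr = getattr(self, name)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite normalized {name} array")

    @property
    def n_points(self) -> int:
        return len(self.hip)


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x.astype(float)
    pad = window // 2
    padded = np.pad(x.astype(float), pad, mode="edge")
    kernel = np.ones(window) / window
    return np.convolve(padded, kernel, mode="valid")[: len(x)]


def detect_events(
    ankle: JointAngleSeries | np.ndarray,
    sampling_rate: float = 100.0,
    onset_prominence_frac: float = 0.05,
    smooth_window: int = 5,
    min_cycle_separation_frac: float = 0.5,
) -> list[GaitEvent]:
    """Detect alternating toe-off / heel-strike events from the ankle trace."""
    x = ankle.angles_deg if isinstance(ankle, JointAngleSeries) else np.asarray(ankle, float)
    if not np.all(np.isfinite(x)):
        raise ValueError("ankle trace must be finite")
    rom = float(np.ptp(x))
    if rom < 1e-9:
        raise EventDetectionError("flat ankle trace: no gait events present")
    sm = _smooth(x, smooth_window)

    prominence = TROUGH_PROMINENCE_FRAC * rom
    troughs, _ = find_peaks(-sm, prominence=prominence)
    if len(troughs) == 0:
        raise EventDetectionError("no plantarflexion trough found")
    if len(troughs) >= 2:
        median_interval = float(np.median(np.diff(troughs)))
        distance = max(1, int(round(min_cycle_separation_frac * median_interval)))
        troughs, _ = find_peaks(-sm, prominence=prominence, distance=distance)

    # heel strike: first +→− zero-crossing of the smoothed difference after
    # each trough, i.e. the first local maximum, subject to a prominence
    # floor of onset_prominence_frac × RoM so flat-plateau noise wiggles
    # are ignored
    onset_prom = onset_prominence_frac * rom
    events: list[GaitEvent] = []
    bounds = list(troughs) + [len(x) - 1]
    for t, nxt in zip(troughs, bounds[1:]):
        events.append(GaitEvent("toe_off", int(t), t / sampling_rate))
        window = sm[t : nxt + 1]
        peaks, _ = find_peaks(window, prominence=onset_prom)
        if len(peaks):
            i = int(t + peaks[0])
            events.append(GaitEvent("heel_strike", i, i / sampling_rate))

    kinds = [e.kind for e in events]
    for a, b in zip(kinds, kinds[1:]):
        if a == b:
            logger.warning("non-alternating gait events detected (%s, %s)", a, b)
    heel_strikes = [e for e in events if e.kind == "heel_strike"]
    if len(heel_strikes) < 2:
        raise EventDetectionError(
            f"fewer than one complete gait cycle: {len(heel_strikes)} heel strike(s)"
        )
    return events


def segment_cycles(
    trial: TrialRecording,
    events: list[GaitEvent],
    n_cycle_points: int = 101,
) -> list[GaitCycle]:
    """Cut the trial into heel-strike-to-heel-strike cycles.

    Each cycle must contain exactly one toe-off; cycles violating this are
    skipped with a warning rather than aborting the subject.
    All three joints are resampled to ``n_cycle_points`` by cubic spline.
    """
    hs = [e.sample_index for e in events if e.kind == "heel_strike"]
    to = [e.sample_index for e in events if e.kind == "toe_off"]
    if len(hs) < 2:
        raise EventDetectionError("need at least two heel strikes to segment")
    cycles: list[GaitCycle] = []
    for start, end in zip(hs, hs[1:]):
        inside = [t for t in to if start < t < end]
        if len(inside) != 1:
            logger.warning(
                "cycle [%d, %d] of %s has %d toe-offs; skipped",
                start, end, trial.subject_id, len(inside),
            )
            continue
        toe = inside[0]
        arrays = {}
        for joint in ("hip", "knee", "ankle"):
            seg = trial.traces[joint].angles_deg[start : end + 1]
            arrays[joint] = resample_to_cycle(seg, n_cycle_points)
        cycles.append(
            GaitCycle(
                start_index=start,
                toe_off_index=toe,
                end_index=end,
                stance_fraction=(toe - start) / (end - start),
                hip=arrays["hip"],
                knee=arrays["knee"],
                ankle=arrays["ankle"],
            )
        )
    return cycles


def select_cycles(
    cycles: list[GaitCycle],
    k_min: int,
    k_max: int,
    rng_seed: int | np.random.Generator,
    subject_id: str = "?",
) -> list[GaitCycle]:
    """Uniformly sample ``min(k_max, available)`` cycles, reproducibly."""
    if len(cycles) < k_min:
        raise ValueError(
            f"subject {subject_id}: only {len(cycles)} cycle(s), need >= {k_min}"
        )
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    k = min(k_max, len(cycles))
    idx = rng.permutation(len(cycles))[:k]
    return [cycles[i] for i in idx]
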