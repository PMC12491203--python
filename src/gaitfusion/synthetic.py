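"""Seeded synthetic gait cohorts: Healthy / KOA / TKA walking emulation.

Each subject gets smooth periodic hip/knee/ankle angle templates built
from a fixed basis of period-wrapped Gaussian bumps plus a cosine
flexion–extension wave for the hip:

* hip — single flexion–extension cosine scaled to the subject's drawn hip
  range of motion, maximal flexion at heel strike;
* knee — the classical two-peak flexion wave (small loading-response peak
  in early stance, large swing peak), scaled to the drawn knee RoM;
* ankle — near-neutral at heel strike with a dorsiflexion plateau through
  mid-stance and a deep plantarflexion trough centred at the drawn stance
  fraction.  The trough is the toe-off landmark and the local dorsiflexion
  maximum at the cycle boundary is the heel-strike landmark, so event
  detection has exact ground truth.

Group profiles draw subject-level RoM means anchored to the magnitudes
typical of healthy, osteoarthritic and post-arthroplasty gait (healthy
knee RoM ≈ 61°, hip ≈ 37°; pathological compression to ≈ 45–51°), with
the osteoarthritis profile carrying a higher ``complexity_noise_sd`` —
smoothed additive noise proportional to each joint's RoM — so its traces
are more irregular and sample entropy rises, while arthroplasty traces
are slightly *more* regular than healthy, mirroring the
"decreased cyclogram features with increased sample entropy"
osteoarthritis signature.  Every drawn ground-truth parameter is recorded
in a manifest for recovery tests; cohorts are byte-identical under a
fixed master seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import (
    JointAngleSeries,
    SubjectMeta,
    TrialRecording,
    write_cohort_meta,
    write_trial,
)

logger = logging.getLogger("gaitfusion.synthetic")


def _wrapped_bump(phase: np.ndarray, center: float, width: float) -> np.ndarray:
    """Periodic Gaussian bump on the unit circle (exactly period-1)."""
    delta = np.mod(phase - center + 0.5, 1.0) - 0.5
    return np.exp(-0.5 * (delta / width) ** 2)


@dataclass
class GroupProfile:
    """Generating distribution of one clinical group."""

    name: str
    n_subjects: int
    hip_rom_mean: float
    hip_rom_sd: float
    knee_rom_mean: float
    knee_rom_sd: float
    hip_com_mean: float
    hip_com_sd: float
    knee_min_mean: float
    knee_min_sd: float
    knee_load_bump_mean: float  # loading-response peak, fraction of swing peak
    knee_load_bump_sd: float
    stance_fraction_mean: float
    stance_fraction_sd: float
    complexity_noise_sd: float  # fraction of each joint's RoM (group mean)
    complexity_noise_cv: float  # relative SD of the per-subject noise level
    cycle_jitter_sd: float      # s, SD of per-cycle duration
    cycle_duration_mean: float  # s
    age_mean: float
    age_sd: float
    bmi_mean: float
    bmi_sd: float
    spatiotemporal_mean: dict[str, float]
    spatiotemporal_sd: dict[str, float]
    side_category_probs: dict[str, float]

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for sd in (self.hip_rom_sd, self.knee_rom_sd, self.stance_fraction_sd,
                   self.complexity_noise_sd, self.cycle_jitter_sd):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")
        if not 0.4 < self.stance_fraction_mean < 0.8:
            raise ValueError("stance_fraction_mean must lie in (0.4, 0.8)")


@dataclass
class CohortSpec:
    """Three group profiles plus acquisition settings and the master seed."""

    profiles: list[GroupProfile]
    sampling_rate: float = 100.0
    k_min: int = 3
    k_max: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.k_min <= self.k_max:
            raise ValueError("need 1 <= k_min <= k_max")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        doc = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortSpec":
        import yaml

        doc = yaml.safe_load(Path(path).read_text())
        if not isinstance(doc, dict) or "profiles" not in doc:
            raise ValueError(f"cohort spec {path} must map fields incl. profiles")
        profiles = [GroupProfile(**p) for p in doc.pop("profiles")]
        known = {f.name for f in dataclasses.fields(cls)} - {"profiles"}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown cohort-spec keys: {sorted(unknown)}")
        return cls(profiles=profiles, **doc)


def default_profiles() -> list[GroupProfile]:
    """Default Healthy/KOA/TKA profiles (cohort of 21 + 24 + 25 subjects)."""
    return [
        GroupProfile(
            name="Healthy", n_subjects=21,
            hip_rom_mean=37.30, hip_rom_sd=4.8,
            knee_rom_mean=61.45, knee_rom_sd=7.5,
            hip_com_mean=15.92, hip_com_sd=8.0,
            knee_min_mean=3.0, knee_min_sd=5.0,
            knee_load_bump_mean=0.25, knee_load_bump_sd=0.05,
            stance_fraction_mean=0.60, stance_fraction_sd=0.012,
            complexity_noise_sd=0.009, complexity_noise_cv=0.3,
            cycle_jitter_sd=0.03,
            cycle_duration_mean=1.05,
            age_mean=56.6, age_sd=13.8, bmi_mean=25.1, bmi_sd=2.9,
            spatiotemporal_mean={
                "speed": 1.20, "stride_length": 1.26, "stride_width": 0.10,
                "step_length_left": 0.63, "step_length_right": 0.63,
            },
            spatiotemporal_sd={
                "speed": 0.10, "stride_length": 0.08, "stride_width": 0.02,
                "step_length_left": 0.05, "step_length_right": 0.05,
            },
            side_category_probs={"none": 1.0},
        ),
        GroupProfile(
            name="KOA", n_subjects=24,
            hip_rom_mean=33.55, hip_rom_sd=6.1,
            knee_rom_mean=50.59, knee_rom_sd=10.0,
            hip_com_mean=19.27, hip_com_sd=8.0,
            knee_min_mean=4.0, knee_min_sd=5.0,
            knee_load_bump_mean=0.25, knee_load_bump_sd=0.05,
            stance_fraction_mean=0.62, stance_fraction_sd=0.018,
            complexity_noise_sd=0.016, complexity_noise_cv=0.3,
            cycle_jitter_sd=0.05,
            cycle_duration_mean=1.18,
            age_mean=58.9, age_sd=11.4, bmi_mean=26.0, bmi_sd=0.3,
            spatiotemporal_mean={
                "speed": 0.90, "stride_length": 1.00, "stride_width": 0.11,
                "step_length_left": 0.49, "step_length_right": 0.51,
            },
            spatiotemporal_sd={
                "speed": 0.12, "stride_length": 0.10, "stride_width": 0.02,
                "step_length_left": 0.06, "step_length_right": 0.06,
            },
            side_category_probs={
                "bilateral": 14 / 24, "unilateral_left": 7 / 24,
                "unilateral_right": 3 / 24,
            },
        ),
        GroupProfile(
            name="TKA", n_subjects=25,
            hip_rom_mean=33.77, hip_rom_sd=6.7,
            knee_rom_mean=44.63, knee_rom_sd=10.0,
            hip_com_mean=18.95, hip_com_sd=8.0,
            knee_min_mean=5.0, knee_min_sd=5.0,
            knee_load_bump_mean=0.25, knee_load_bump_sd=0.05,
            stance_fraction_mean=0.61, stance_fraction_sd=0.015,
            complexity_noise_sd=0.0035, complexity_noise_cv=0.3,
            cycle_jitter_sd=0.03,
            cycle_duration_mean=1.12,
            age_mean=65.2, age_sd=10.1, bmi_mean=27.2, bmi_sd=3.5,
            spatiotemporal_mean={
                "speed": 0.95, "stride_length": 1.06, "stride_width": 0.10,
                "step_length_left": 0.52, "step_length_right": 0.53,
            },
            spatiotemporal_sd={
                "speed": 0.12, "stride_length": 0.10, "stride_width": 0.02,
                "step_length_left": 0.06, "step_length_right": 0.06,
            },
            side_category_probs={
                "bilateral": 5 / 25, "unilateral_left": 11 / 25,
                "unilateral_right": 9 / 25,
            },
        ),
    ]


def default_spec(seed: int = 0) -> CohortSpec:
    return CohortSpec(profiles=default_profiles(), seed=seed)


def generate_cycle_template(
    profile: GroupProfile, rng: np.random.Generator
) -> tuple[dict, dict]:
    """Draw one subject's angle templates over normalized phase [0, 1].

    Returns ``(templates, truth)`` where ``templates`` maps joint name to
    a callable phase → degrees and ``truth`` records the drawn RoMs and
    stance fraction.  All templates are exactly period-1 (f(0) = f(1)).
    """
    hip_rom = float(
        np.clip(rng.normal(profile.hip_rom_mean, profile.hip_rom_sd), 15.0, 60.0)
    )
    knee_rom = float(
        np.clip(rng.normal(profile.knee_rom_mean, profile.knee_rom_sd), 20.0, 85.0)
    )
    sf = float(
        np.clip(
            rng.normal(profile.stance_fraction_mean, profile.stance_fraction_sd),
            0.45, 0.75,
        )
    )
    hip_com = float(
        np.clip(rng.normal(profile.hip_com_mean, profile.hip_com_sd), -5.0, 40.0)
    )
    knee_min = float(
        np.clip(rng.normal(profile.knee_min_mean, profile.knee_min_sd), -5.0, 20.0)
    )

    def hip(phase: np.ndarray) -> np.ndarray:
        return hip_com + (hip_rom / 2.0) * np.cos(2 * np.pi * np.asarray(phase))

    # two-bump knee shape with a drawn loading-response amplitude,
    # rescaled to the drawn RoM
    load_bump = float(
        np.clip(
            rng.normal(profile.knee_load_bump_mean, profile.knee_load_bump_sd),
            0.02, 0.6,
        )
    )
    shape_grid = np.linspace(0, 1, 2001)

    def _knee_shape(phase: np.ndarray) -> np.ndarray:
        p = np.asarray(phase)
        return load_bump * _wrapped_bump(p, 0.12, 0.07) + _wrapped_bump(p, 0.72, 0.10)

    smin, smax = float(_knee_shape(shape_grid).min()), float(_knee_shape(shape_grid).max())

    def knee(phase: np.ndarray) -> np.ndarray:
        return knee_min + knee_rom * (_knee_shape(phase) - smin) / (smax - smin)

    def ankle(phase: np.ndarray) -> np.ndarray:
        p = np.asarray(phase)
        return (
            5.0 * _wrapped_bump(p, 0.0, 0.04)       # end-swing dorsiflexion peak (heel strike)
            + 10.0 * _wrapped_bump(p, 0.35, 0.12)   # mid-stance dorsiflexion plateau
            - 20.0 * _wrapped_bump(p, sf, 0.06)     # plantarflexion trough (toe-off)
            - 3.0 * _wrapped_bump(p, 0.08, 0.05)    # loading-response dip (first rocker)
        )

    templates = {"hip": hip, "knee": knee, "ankle": ankle}
    truth = {"hip_rom": hip_rom, "knee_rom": knee_rom, "stance_fraction": sf,
             "hip_com": hip_com, "knee_min": knee_min, "knee_load_bump": load_bump}
    return templates, truth


def _smooth3(x: np.ndarray) -> np.ndarray:
    padded = np.pad(x, 1, mode="edge")
    return np.convolve(padded, np.ones(3) / 3, mode="valid")


def _draw_covariates(profile: GroupProfile, rng: np.random.Generator) -> dict:
    age = float(np.clip(rng.normal(profile.age_mean, profile.age_sd), 25, 92))
    bmi = float(np.clip(rng.normal(profile.bmi_mean, profile.bmi_sd), 16, 45))
    sex = str(rng.choice(["F", "M"]))
    cats = sorted(profile.side_category_probs)
    probs = np.array([profile.side_category_probs[c] for c in cats])
    side = str(rng.choice(cats, p=probs / probs.sum()))
    spatio = {
        key: float(max(rng.normal(mu, profile.spatiotemporal_sd[key]), 1e-3))
        for key, mu in profile.spatiotemporal_mean.items()
    }
    return {"age": age, "bmi": bmi, "sex": sex, "side_category": side,
            "spatiotemporal": spatio}


def generate_subject(
    profile: GroupProfile,
    spec: CohortSpec,
    rng: np.random.Generator,
    subject_id: str,
) -> tuple[SubjectMeta, TrialRecording, dict]:
    """One subject: multi-cycle angle traces, metadata, ground truth.

    ``k`` complete heel-strike-to-heel-strike cycles (k uniform on
    [k_min, k_max]) are embedded in a trace of k+1 generated cycles plus a
    short tail, so that every cycle boundary needed by event detection is
    interior to the trace.  Per-cycle durations jitter independently;
    smoothed Gaussian noise with SD = complexity_noise_sd × RoM is added
    per joint.
    """
    templates, truth = generate_cycle_template(profile, rng)
    noise_sd = profile.complexity_noise_sd * float(
        np.clip(rng.normal(1.0, profile.complexity_noise_cv), 0.25, 2.0)
    )
    k = int(rng.integers(spec.k_min, spec.k_max + 1))
    n_gen = k + 1
    durations = rng.normal(profile.cycle_duration_mean, profile.cycle_jitter_sd, n_gen)
    durations = np.clip(durations, 0.6, 2.0)
    tail = 0.2 * profile.cycle_duration_mean
    starts = np.concatenate([[0.0], np.cumsum(durations)])
    total = starts[-1] + tail
    fs = spec.sampling_rate
    n_samples = int(np.floor(total * fs)) + 1
    t = np.arange(n_samples) / fs

    cycle_idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, n_gen - 1)
    in_tail = t >= starts[-1]
    phase = np.empty(n_samples)
    valid = ~in_tail
    phase[valid] = (t[valid] - starts[cycle_idx[valid]]) / durations[cycle_idx[valid]]
    # the tail continues the periodic motion at the last cycle's cadence
    phase[in_tail] = (t[in_tail] - starts[-1]) / durations[-1]
    phase = np.mod(phase, 1.0)

    traces: dict[str, JointAngleSeries] = {}
    roms = {"hip": truth["hip_rom"], "knee": truth["knee_rom"], "ankle": 33.0}
    for joint in ("hip", "knee", "ankle"):
        clean = templates[joint](phase)
        noise = rng.normal(0.0, noise_sd * roms[joint], n_samples)
        traces[joint] = JointAngleSeries(joint, clean + _smooth3(noise))

    cov = _draw_covariates(profile, rng)
    meta = SubjectMeta(
        subject_id=subject_id, group=profile.name, age=cov["age"], sex=cov["sex"],
        bmi=cov["bmi"], side_category=cov["side_category"],
        spatiotemporal=cov["spatiotemporal"],
    )
    side = "left" if cov["side_category"] != "unilateral_right" else "right"
    trial = TrialRecording(subject_id, side, fs, traces)

    boundary_samples = [int(round(s * fs)) for s in starts]
    trough_samples = [
        int(round((starts[i] + truth["stance_fraction"] * durations[i]) * fs))
        for i in range(n_gen)
    ]
    truth.update(
        {
            "subject_id": subject_id,
            "group": profile.name,
            "n_cycles": k,
            "cycle_boundaries": boundary_samples,
            "toe_off_samples": trough_samples,
            "durations_s": [float(d) for d in durations],
            "complexity_noise_sd": noise_sd,
        }
    )
    return meta, trial, truth


_PREFIX = {"Healthy": "H", "KOA": "K", "TKA": "T"}


def generate_cohort(
    spec: CohortSpec | None = None,
    out_dir: str | Path | None = None,
) -> tuple[list[tuple[SubjectMeta, TrialRecording]], dict]:
    """Generate the full cohort; optionally write it to disk.

    Returns ``(cohort, manifest)``; the manifest records every drawn
    ground-truth parameter per subject.  With ``out_dir`` set, writes
    ``meta.csv``, ``trials/<subject_id>.csv`` and ``manifest.json``.
    """
    spec = spec or default_spec()
    root_ss = np.random.SeedSequence(spec.seed)
    cohort: list[tuple[SubjectMeta, TrialRecording]] = []
    manifest: dict = {"seed": spec.seed, "sampling_rate": spec.sampling_rate,
                      "subjects": []}
    streams = root_ss.spawn(len(spec.profiles))
    for profile, stream in zip(spec.profiles, streams):
        subject_streams = stream.spawn(profile.n_subjects)
        prefix = _PREFIX.get(profile.name, profile.name[:1])
        for i, sub_ss in enumerate(subject_streams):
            sid = f"{prefix}{i + 1:02d}"
            rng = np.random.default_rng(sub_ss)
            meta, trial, truth = generate_subject(profile, spec, rng, sid)
            cohort.append((meta, trial))
            manifest["subjects"].append(truth)
    manifest["profiles"] = [dataclasses.asdict(p) for p in spec.profiles]

    if out_dir is not None:
        out_dir = Path(out_dir)
        trials_dir = out_dir / "trials"
        trials_dir.mkdir(parents=True, exist_ok=True)
        write_cohort_meta([m for m, _ in cohort], out_dir / "meta.csv")
        for _, trial in cohort:
            write_trial(trial, trials_dir / f"{trial.subject_id}.csv")
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return cohort, manifest
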