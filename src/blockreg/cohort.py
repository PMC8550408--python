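"""Synthetic subject-cohort simulator.

Generates telemetry sessions with the statistical structure the analysis
pipeline assumes, so every downstream stage can be exercised end-to-end
without human-subject data.  The generative model is deliberately the
simplest one exhibiting each measured phenomenon:

* completion time per task n (1-indexed across the whole session) follows an
  exponential-approach learning curve
  ``T(n) = T_inf + (T0 - T_inf) * exp(-(n - 1) / tau_T)``, scaled by a
  prompt multiplier (rho_speed < 1 <= rho_accuracy) and multiplicative
  lognormal noise exp(sigma_T * eps);
* the final tissue position is the target plus a fixed per-setup placement
  bias ``beta`` (in kidney-height units — the 2D Desktop default carries the
  characteristic negative-x bias) plus isotropic Gaussian noise sigma_p;
* the final orientation perturbs the target orientation about a uniformly
  random axis by |N(0, sigma_r(n))| degrees, with sigma_r(n) decaying from
  sigma_r0 to sigma_r_inf on its own learning timescale tau_r;
* within a task, 10 Hz pose samples interpolate linearly (slerp for
  rotation) from the start pose to the final pose — no human-motion realism
  is claimed.

Default profiles are calibrated so the simulated cohort reproduces the
qualitative setup orderings (2D Desktop slower and rotationally less
accurate than both VR setups, with a negative-x placement bias).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .geometry import Orientation, Pose, Vec3, slerp
from .schedule import Phase, Prompt, ProtocolConfig, TaskSpec, build_protocol
from .telemetry import Event, Setup, SubjectSession, TelemetryRecord

__all__ = [
    "SubjectProfile",
    "CohortConfig",
    "DEFAULT_PROFILES",
    "simulate_subject",
    "simulate_cohort",
]

SAMPLE_RATE_HZ = 10.0


@dataclass(frozen=True)
class SubjectProfile:
    """Generative parameters for one simulated subject."""

    setup: Setup
    t0_s: float  # initial per-task completion time
    t_inf_s: float  # asymptotic completion time
    tau_t: float  # completion-time learning timescale (tasks)
    sigma_t: float  # lognormal completion-time noise
    beta: tuple[float, float, float]  # placement bias, kidney-height units
    sigma_p: float  # isotropic position noise, kidney-height units
    sigma_r0_deg: float  # initial rotation-noise scale
    sigma_r_inf_deg: float  # asymptotic rotation-noise scale
    tau_r: float  # rotation learning timescale (tasks)
    rho_speed: float = 0.85
    rho_accuracy: float = 1.15
    satisfaction_probs: tuple[float, ...] = (0.2, 0.2, 0.2, 0.2, 0.2)

    def __post_init__(self) -> None:
        if min(self.t_inf_s, self.tau_t, self.tau_r) <= 0:
            raise ValueError("time constants and asymptote must be positive")
        if min(self.sigma_t, self.sigma_p, self.sigma_r0_deg, self.sigma_r_inf_deg) < 0:
            raise ValueError("noise scales must be nonnegative")
        if not 0 < self.rho_speed <= 1 <= self.rho_accuracy:
            raise ValueError("require 0 < rho_speed <= 1 <= rho_accuracy")
        if abs(sum(self.satisfaction_probs) - 1.0) > 1e-9:
            raise ValueError("satisfaction_probs must sum to 1")

    def rho(self, prompt: Prompt) -> float:
        if prompt is Prompt.SPEED:
            return self.rho_speed
        if prompt is Prompt.ACCURACY:
            return self.rho_accuracy
        return 1.0

    def expected_time(self, n: int, prompt: Prompt = Prompt.NONE) -> float:
        """Noise-free completion time of overall task n (1-indexed)."""
        curve = self.t_inf_s + (self.t0_s - self.t_inf_s) * np.exp(
            -(n - 1) / self.tau_t
        )
        return float(curve * self.rho(prompt))

    def sigma_r(self, n: int) -> float:
        return float(
            self.sigma_r_inf_deg
            + (self.sigma_r0_deg - self.sigma_r_inf_deg) * np.exp(-(n - 1) / self.tau_r)
        )


# Per-setup defaults: the 2D Desktop profile is slower, carries the
# negative-x placement bias, and has coarser rotation control; both VR
# profiles are ~3x faster with small symmetric biases.
DEFAULT_PROFILES: dict[Setup, SubjectProfile] = {
    Setup.DESKTOP_2D: SubjectProfile(
        setup=Setup.DESKTOP_2D,
        t0_s=70.0,
        t_inf_s=22.6,
        tau_t=6.0,
        sigma_t=0.25,
        beta=(-0.0114, 0.0, 0.0),
        sigma_p=0.004,
        sigma_r0_deg=24.0,
        sigma_r_inf_deg=8.7,
        tau_r=8.0,
        satisfaction_probs=(0.15, 0.25, 0.30, 0.26, 0.04),  # mean 2.79
    ),
    Setup.VR_TABLETOP: SubjectProfile(
        setup=Setup.VR_TABLETOP,
        t0_s=25.0,
        t_inf_s=7.1,
        tau_t=3.0,
        sigma_t=0.25,
        beta=(0.0021, 0.0021, 0.0021),
        sigma_p=0.004,
        sigma_r0_deg=7.5,
        sigma_r_inf_deg=5.8,
        tau_r=4.0,
        satisfaction_probs=(0.02, 0.05, 0.15, 0.47, 0.31),  # mean 4.00
    ),
    Setup.VR_STANDUP: SubjectProfile(
        setup=Setup.VR_STANDUP,
        t0_s=25.0,
        t_inf_s=7.39,
        tau_t=2.0,
        sigma_t=0.25,
        beta=(0.00085, 0.00085, 0.00085),
        sigma_p=0.004,
        sigma_r0_deg=7.5,
        sigma_r_inf_deg=6.9,
        tau_r=4.0,
        satisfaction_probs=(0.02, 0.06, 0.16, 0.49, 0.27),  # mean 3.93
    ),
}

#: Kidney display height per setup (mm): on-screen vs room-scale VR.
SETUP_HEIGHTS_MM: dict[Setup, float] = {
    Setup.DESKTOP_2D: 113.0,
    Setup.VR_TABLETOP: 590.0,
    Setup.VR_STANDUP: 590.0,
}


@dataclass(frozen=True)
class CohortConfig:
    """Cohort composition: subjects per setup, profiles, protocol, master seed."""

    subjects_per_setup: dict[Setup, int] = field(
        default_factory=lambda: {s: 14 for s in Setup}
    )
    profiles: dict[Setup, SubjectProfile] = field(
        default_factory=lambda: dict(DEFAULT_PROFILES)
    )
    protocol_config: ProtocolConfig = field(default_factory=ProtocolConfig)
    master_seed: int = 0

    def __post_init__(self) -> None:
        clean = {Setup(k): int(v) for k, v in self.subjects_per_setup.items()}
        if not clean or min(clean.values()) < 1:
            raise ValueError("need at least one subject per requested setup")
        object.__setattr__(self, "subjects_per_setup", clean)

    @classmethod
    def from_json(cls, source: str | Path) -> "CohortConfig":
        raw = json.loads(Path(source).read_text())
        kwargs: dict = {}
        if "subjects_per_setup" in raw:
            kwargs["subjects_per_setup"] = {
                Setup(k): v for k, v in raw["subjects_per_setup"].items()
            }
        if "master_seed" in raw:
            kwargs["master_seed"] = raw["master_seed"]
        if "profiles" in raw:
            kwargs["profiles"] = {
                Setup(k): replace(DEFAULT_PROFILES[Setup(k)], **v)
                for k, v in raw["profiles"].items()
            }
        return cls(**kwargs)


def _random_axis(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def simulate_subject(
    profile: SubjectProfile,
    protocol: list[TaskSpec],
    subject_id: str = "s000",
    seed: int | np.random.SeedSequence = 0,
    include_samples: bool = True,
) -> SubjectSession:
    """Simulate one subject's telemetry session over a protocol.

    Fully reproducible from ``seed``.  With ``include_samples`` the session
    carries 10 Hz within-task pose samples interpolating start -> final pose;
    otherwise only the submit rows (which is all the analyses consume).
    """
    rng = np.random.default_rng(seed)
    height = protocol[0].kidney_height_mm
    beta = np.asarray(profile.beta, dtype=float)
    records: list[TelemetryRecord] = []
    now = 0.0
    if not include_samples:
        # keep a session-start row so the first task's completion time is
        # still measured from the phase start
        records.append(
            TelemetryRecord(
                timestamp_s=0.0,
                phase=protocol[0].phase,
                task_index=protocol[0].index,
                tissue_pose=protocol[0].start_pose,
                target_pose=protocol[0].target_pose,
                event=Event.SAMPLE,
            )
        )
    for n, spec in enumerate(protocol, start=1):
        duration = profile.expected_time(n, spec.prompt) * float(
            np.exp(profile.sigma_t * rng.standard_normal())
        )
        target = spec.target_pose
        eta = rng.standard_normal(3)
        final_pos = Vec3.from_array(
            target.position.as_array() + (beta + profile.sigma_p * eta) * height
        )
        angle = abs(rng.normal(0.0, profile.sigma_r(n)))
        perturb = Orientation.from_axis_angle(_random_axis(rng), angle)
        final_ori = perturb.compose(target.orientation)
        start = spec.start_pose
        if include_samples:
            n_samples = int(duration * SAMPLE_RATE_HZ)
            for k in range(n_samples):
                frac = (k / SAMPLE_RATE_HZ) / duration
                pos = Vec3.from_array(
                    (1 - frac) * start.position.as_array()
                    + frac * final_pos.as_array()
                )
                ori = slerp(start.orientation, final_ori, frac)
                records.append(
                    TelemetryRecord(
                        timestamp_s=now + k / SAMPLE_RATE_HZ,
                        phase=spec.phase,
                        task_index=spec.index,
                        tissue_pose=Pose(pos, ori),
                        target_pose=target,
                        event=Event.SAMPLE,
                    )
                )
        now += duration
        records.append(
            TelemetryRecord(
                timestamp_s=now,
                phase=spec.phase,
                task_index=spec.index,
                tissue_pose=Pose(final_pos, final_ori),
                target_pose=target,
                event=Event.SUBMIT,
            )
        )
    satisfaction = int(rng.choice(np.arange(1, 6), p=profile.satisfaction_probs))
    return SubjectSession(
        subject_id=subject_id,
        setup=profile.setup,
        kidney_height_mm=height,
        records=records,
        satisfaction=satisfaction,
    )


def simulate_cohort(
    config: CohortConfig | None = None, include_samples: bool = True
) -> list[SubjectSession]:
    """Simulate a full cohort: independent per-subject seed streams derived
    from the master seed, one protocol per setup (kidney height differs,
    normalized difficulty does not)."""
    config = config or CohortConfig()
    root = np.random.SeedSequence(config.master_seed)
    sessions: list[SubjectSession] = []
    protocols = {
        setup: build_protocol(
            replace_height(config.protocol_config, SETUP_HEIGHTS_MM[setup])
        )
        for setup in config.subjects_per_setup
    }
    counter = 0
    for setup, n_subjects in sorted(
        config.subjects_per_setup.items(), key=lambda kv: kv[0].value
    ):
        profile = config.profiles[setup]
        for _ in range(n_subjects):
            child = root.spawn(1)[0]
            sessions.append(
                simulate_subject(
                    profile,
                    protocols[setup],
                    subject_id=f"s{counter:03d}",
                    seed=child,
                    include_samples=include_samples,
                )
            )
            counter += 1
    return sessions


def replace_height(config: ProtocolConfig, height_mm: float) -> ProtocolConfig:
    return replace(config, kidney_height_mm=height_mm)
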