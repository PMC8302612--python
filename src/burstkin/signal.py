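"""Synthesis of MS2/MCP-like fluorescence traces from initiation events.

Each initiating polymerase contributes a deterministic trapezoid of
fluorescence as it transcribes the reporter: nothing until it reaches the
stem-loop cassette, a linear ramp while the loops are being transcribed,
a plateau of one polymerase unit until the polymerase (and transcript)
leaves the gene, and zero afterwards (no retention at the 3' end).  A
trace is the sum of these kernels sampled on the camera frame grid, plus
noise and a detection floor mimicking spot-detection limits.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .models import InitiationEventTrain, PromoterModel, simulate_event_train

__all__ = [
    "SignalKernel",
    "FluorescenceTrace",
    "CohortConfig",
    "Cohort",
    "kernel_intensity",
    "convolve_events",
    "degrade_trace",
    "calibrate_intensity",
    "generate_cohort",
    "DEFAULT_FRAME_INTERVAL",
]

#: camera frame spacing of the live-imaging movies, seconds
DEFAULT_FRAME_INTERVAL = 3.86


@dataclass(frozen=True)
class SignalKernel:
    """Single-polymerase fluorescence kernel of the reporter construct.

    Defaults describe a transgene with a 41 bp pre-MS2 fragment, 24xMS2
    loops (1292 bp) and a 4526 bp post-MS2 fragment, transcribed at
    45 bp/s with zero retention of the finished transcript.
    """

    pre_len: float = 41.0
    ms2_len: float = 1292.0
    post_len: float = 4526.0
    elongation_speed: float = 45.0
    retention_time: float = 0.0

    def __post_init__(self) -> None:
        for name in ("pre_len", "ms2_len", "post_len", "elongation_speed"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.retention_time < 0:
            raise ValueError("retention_time must be nonnegative")

    @property
    def ramp_start(self) -> float:
        return self.pre_len / self.elongation_speed

    @property
    def ramp_end(self) -> float:
        return (self.pre_len + self.ms2_len) / self.elongation_speed

    @property
    def dwell_end(self) -> float:
        total = self.pre_len + self.ms2_len + self.post_len
        return total / self.elongation_speed + self.retention_time

    @property
    def integral(self) -> float:
        """Area under the kernel (polymerase-units x s): a trapezoid."""
        return self.dwell_end - 0.5 * (self.ramp_start + self.ramp_end)

    def intensity(self, tau) -> np.ndarray:
        """Fluorescence of one polymerase ``tau`` seconds after initiation
        (fraction of MS2 loops transcribed, saturating at 1)."""
        tau = np.asarray(tau, dtype=float)
        if np.any(tau < 0):
            raise ValueError("tau must be nonnegative")
        ramp = (tau - self.ramp_start) / (self.ramp_end - self.ramp_start)
        out = np.clip(ramp, 0.0, 1.0)
        out = np.where(tau >= self.dwell_end, 0.0, out)
        return out

    def to_dict(self) -> dict:
        return {
            "pre_len": self.pre_len,
            "ms2_len": self.ms2_len,
            "post_len": self.post_len,
            "elongation_speed": self.elongation_speed,
            "retention_time": self.retention_time,
        }


def kernel_intensity(kernel: SignalKernel, tau) -> np.ndarray:
    """Functional alias of :meth:`SignalKernel.intensity`."""
    return kernel.intensity(tau)


@dataclass(frozen=True)
class FluorescenceTrace:
    """Frame-sampled transcription-site intensity of one nucleus.

    ``unit`` is "pol" once calibrated to polymerase counts, "au" for raw
    arbitrary units.  Frame times must be uniformly spaced.
    """

    nucleus_id: object
    frame_times: np.ndarray
    intensities: np.ndarray
    unit: str = "pol"
    genotype: str = ""
    movie: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.frame_times, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if t.shape != y.shape or t.ndim != 1:
            raise ValueError("frame_times and intensities must be 1-d and of equal length")
        if t.size > 1:
            dt = np.diff(t)
            if np.any(np.abs(dt - dt[0]) > 1e-6):
                raise ValueError("frame times must be uniformly spaced")
        object.__setattr__(self, "frame_times", t)
        object.__setattr__(self, "intensities", y)

    @property
    def frame_interval(self) -> float:
        t = self.frame_times
        return float(t[1] - t[0]) if t.size > 1 else 0.0

    @property
    def calibrated(self) -> bool:
        return self.unit == "pol"


@dataclass(frozen=True)
class CohortConfig:
    """Settings of a synthetic cohort of nuclei.

    ``noise_sd`` is the additive Gaussian noise level in polymerase
    units; ``detection_floor`` zeroes frames below that many polymerases
    (spot detection cannot see dim sites).  ``gap_params`` draws a
    postmitotic activation delay per nucleus.
    """

    n_nuclei: int = 200
    movie_duration: float = 1800.0
    frame_interval: float = DEFAULT_FRAME_INTERVAL
    noise_sd: float = 0.5
    detection_floor: float = 3.0
    gap_params: Optional[object] = None  # GapParams, see burstkin.gaps
    calibration_factor: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be nonnegative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass(frozen=True)
class Cohort:
    """Synthetic traces paired with their ground-truth event trains."""

    traces: Tuple[FluorescenceTrace, ...]
    trains: Tuple[InitiationEventTrain, ...]
    config: CohortConfig


def convolve_events(
    train: InitiationEventTrain,
    kernel: SignalKernel,
    frame_times: Optional[np.ndarray] = None,
    frame_interval: float = DEFAULT_FRAME_INTERVAL,
    **trace_tags,
) -> FluorescenceTrace:
    """Noiseless trace: sum of one kernel per initiation event, sampled on
    the frame grid (grid spans the train's window unless given)."""
    if frame_times is None:
        t0, t1 = train.window
        frame_times = t0 + frame_interval * np.arange(int(np.floor((t1 - t0) / frame_interval)) + 1)
    frame_times = np.asarray(frame_times, dtype=float)
    y = np.zeros_like(frame_times)
    for ev in train.event_times:
        tau = frame_times - ev
        mask = tau >= 0
        if mask.any():
            y[mask] += kernel.intensity(tau[mask])
    return FluorescenceTrace(train.nucleus_id, frame_times, y, unit="pol", **trace_tags)


def degrade_trace(
    trace: FluorescenceTrace,
    noise_sd: float,
    detection_floor: float = 0.0,
    seed=0,
) -> FluorescenceTrace:
    """Add zero-mean Gaussian noise (polymerase units), clip negatives to
    zero, and zero every frame below the detection floor."""
    if not trace.calibrated:
        raise ValueError("degrade_trace expects a calibrated trace (polymerase units)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y = trace.intensities.copy()
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    y = np.clip(y, 0.0, None)
    y[y < detection_floor] = 0.0
    return replace(trace, intensities=y)


def calibrate_intensity(trace: FluorescenceTrace, single_molecule_intensity: float) -> FluorescenceTrace:
    """Convert a raw trace to polymerase units by dividing by the median
    single-molecule intensity (a.u. per transcript, from smFISH-style
    calibration)."""
    if single_molecule_intensity <= 0:
        raise ValueError("single_molecule_intensity must be positive")
    return replace(
        trace,
        intensities=trace.intensities / single_molecule_intensity,
        unit="pol",
    )


def generate_cohort(
    model: PromoterModel,
    config: CohortConfig,
    kernel: Optional[SignalKernel] = None,
    genotype: str = "synthetic",
) -> Cohort:
    """Simulate a cohort of nuclei: per nucleus, draw a postmitotic onset
    delay, run the Gillespie promoter simulation from that onset to the
    movie end, convolve with the kernel, then degrade (noise + floor).

    Returns the degraded traces together with the ground-truth event
    trains (both on the movie time axis, t=0 at mitosis).
    """
    kernel = kernel or SignalKernel()
    rng = np.random.default_rng(config.seed)
    n_frames = int(np.floor(config.movie_duration / config.frame_interval)) + 1
    frame_times = config.frame_interval * np.arange(n_frames)
    traces: List[FluorescenceTrace] = []
    trains: List[InitiationEventTrain] = []
    for i in range(config.n_nuclei):
        if config.gap_params is not None:
            onset = float(config.gap_params.sample(1, rng)[0])
        else:
            onset = 0.0
        onset = min(onset, config.movie_duration)
        train = simulate_event_train(
            model,
            duration=config.movie_duration - onset,
            seed=rng,
            nucleus_id=i,
            t_start=onset,
        )
        # full-movie window so traces share the common time origin
        train = InitiationEventTrain(i, train.event_times, (0.0, config.movie_duration))
        clean = convolve_events(train, kernel, frame_times=frame_times, genotype=genotype)
        noisy = degrade_trace(clean, config.noise_sd, config.detection_floor, seed=rng)
        traces.append(noisy)
        trains.append(train)
    return Cohort(tuple(traces), tuple(trains), config)
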