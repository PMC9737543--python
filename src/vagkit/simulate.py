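"""Synthetic vibroarthrogram (VAG) signals and cohorts.

Two layers of simulation are provided:

1. **Signal level** — :func:`simulate_recording` builds a 20-s accelerometer
   trace for one temporomandibular joint: cyclic jaw open/close motion shows
   up as an amplitude envelope on baseline noise, and symptomatic joints
   additionally emit short damped-sinusoid "click" bursts whose energy sits
   below 300 Hz. Per-subject and per-session random effects act
   multiplicatively on amplitude (log-normal), which induces the
   between-subject / between-session variance structure that the reliability
   analysis estimates.

2. **Feature level** — :func:`simulate_feature_matrix` draws directly from
   the two-way crossed ANOVA model ``X[i,j] = mu + r_i + c_j + e_ij`` so that
   the theoretical ICC(A,1) = sigma_r^2 / (sigma_r^2 + sigma_c^2 + sigma_e^2)
   is known exactly. This is the ground-truth generator used to validate the
   ICC estimator and its confidence intervals.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Literal

import numpy as np
import pandas as pd

GroupLabel = Literal["symptomatic", "asymptomatic", "unknown"]

#: Allowed group labels for recordings and manifests.
GROUPS = ("symptomatic", "asymptomatic", "unknown")

MANIFEST_COLUMNS = ["subject_id", "group", "side", "session", "path"]


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of the VAG signal simulator.

    Defaults mirror the recording protocol the simulator emulates: 5 kHz
    sampling, 20-s sessions, 10 jaw open/close cycles per session, and joint
    clicks concentrated below 300 Hz.

    Parameters
    ----------
    sampling_rate : float
        Sampling frequency in Hz.
    duration : float
        Recording length in seconds.
    n_cycles : int
        Jaw open/close cycles per recording; sets the envelope period.
    baseline_noise_sd : float
        SD of the Gaussian baseline noise (signal units) before the envelope
        and amplitude effects are applied.
    click_rate : float
        Expected number of click bursts per cycle (Poisson) for symptomatic
        recordings.
    click_amplitude_mean : float
        Mean peak amplitude of a click burst, in signal units.
    click_center_freq : float
        Carrier frequency of the damped-sinusoid click, in Hz (kept below
        300 Hz so clicks dominate the IB3 integral).
    click_duration : float
        Effective burst length in seconds; the exponential decay constant is
        chosen so the burst has decayed to ~1% at this point.
    subject_sd, session_sd : float
        Log-scale SDs of the multiplicative per-subject and per-session
        amplitude effects.
    """

    sampling_rate: float = 5000.0
    duration: float = 20.0
    n_cycles: int = 10
    baseline_noise_sd: float = 0.05
    click_rate: float = 2.0
    click_amplitude_mean: float = 1.0
    click_center_freq: float = 150.0
    click_duration: float = 0.02
    subject_sd: float = 0.3
    session_sd: float = 0.1

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        for name in ("baseline_noise_sd", "click_rate", "click_amplitude_mean",
                     "subject_sd", "session_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 < self.click_duration < self.duration / self.n_cycles:
            raise ValueError("click_duration must lie in (0, duration/n_cycles)")

    @property
    def n_samples(self) -> int:
        return int(round(self.sampling_rate * self.duration))


@dataclass(frozen=True)
class VagRecording:
    """One VAG acceleration time series with its acquisition metadata."""

    samples: np.ndarray
    sampling_rate: float
    subject_id: str = "S000"
    group: str = "unknown"
    side: str = "left"
    session: int = 1

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sampling_rate


@dataclass(frozen=True)
class TwoWayModelParams:
    """Two-way crossed random-effects model for an n-subject, k-session design.

    The model is ``X[i,j] = mu + r_i + c_j + e_ij`` with independent zero-mean
    normal effects; its theoretical ICC(A,1) is
    ``sigma_r**2 / (sigma_r**2 + sigma_c**2 + sigma_e**2)``.
    """

    n: int
    k: int = 2
    mu: float = 0.0
    sigma_r: float = 1.0
    sigma_c: float = 0.0
    sigma_e: float = 1.0

    def __post_init__(self) -> None:
        if self.n < 2 or self.k < 2:
            raise ValueError("need n >= 2 subjects and k >= 2 sessions")
        if min(self.sigma_r, self.sigma_c, self.sigma_e) < 0:
            raise ValueError("all SDs must be >= 0")

    @property
    def theoretical_icc(self) -> float:
        total = self.sigma_r**2 + self.sigma_c**2 + self.sigma_e**2
        if total == 0:
            return float("nan")
        return self.sigma_r**2 / total


def _cycle_envelope(t: np.ndarray, duration: float, n_cycles: int) -> np.ndarray:
    """Amplitude envelope of jaw motion: n_cycles maxima over the recording.

    A raised cosine per cycle with a 0.3 floor — the joint is never perfectly
    silent, and the floor keeps short-time RMS strictly positive.
    """
    phase = 2.0 * np.pi * n_cycles * t / duration
    return 0.3 + 0.7 * 0.5 * (1.0 - np.cos(phase))


def _click_burst(n: int, fs: float, center_freq: float, duration: float,
                 amplitude: float, phase: float) -> np.ndarray:
    """Damped sinusoid a*exp(-t/tau)*sin(2*pi*f*t + phi), ~1% residual at `duration`."""
    tau = duration / np.log(100.0)
    t = np.arange(n) / fs
    return amplitude * np.exp(-t / tau) * np.sin(2.0 * np.pi * center_freq * t + phase)


def simulate_recording(
    params: SimulationParams,
    group: str = "asymptomatic",
    subject_effect: float = 0.0,
    session_effect: float = 0.0,
    seed: int = 0,
    *,
    subject_id: str = "S000",
    side: str = "left",
    session: int = 1,
) -> VagRecording:
    """Simulate one VAG recording.

    Asymptomatic joints produce envelope-modulated baseline noise only;
    symptomatic joints additionally emit Poisson(click_rate)-per-cycle damped
    sinusoid bursts. The whole trace is scaled by
    ``exp(subject_effect + session_effect)``.

    The output is a deterministic function of all arguments.
    """
    if group not in GROUPS:
        raise ValueError(f"group must be one of {GROUPS}, got {group!r}")
    rng = np.random.default_rng(seed)
    n = params.n_samples
    fs = params.sampling_rate
    t = np.arange(n) / fs
    env = _cycle_envelope(t, params.duration, params.n_cycles)

    x = rng.standard_normal(n) * params.baseline_noise_sd * env

    if group == "symptomatic":
        cycle_len = params.duration / params.n_cycles
        burst_len = min(int(round(params.click_duration * fs)) * 3, n)
        for c in range(params.n_cycles):
            n_clicks = rng.poisson(params.click_rate)
            for _ in range(n_clicks):
                t0 = (c + rng.uniform(0.0, 1.0)) * cycle_len
                i0 = int(t0 * fs)
                amp = params.click_amplitude_mean * rng.lognormal(0.0, 0.25)
                phase = rng.uniform(0.0, 2.0 * np.pi)
                burst = _click_burst(min(burst_len, n - i0), fs,
                                     params.click_center_freq,
                                     params.click_duration, amp, phase)
                x[i0:i0 + len(burst)] += burst

    x *= np.exp(subject_effect + session_effect)
    return VagRecording(samples=x, sampling_rate=fs, subject_id=subject_id,
                        group=group, side=side, session=session)


def count_bursts(params: SimulationParams, seed: int) -> int:
    """Number of click bursts a symptomatic recording with this seed contains.

    Replays the generator's random stream, so it is exact, and exists so that
    the Poisson burst-count behaviour can be tested without signal-level
    burst detection.
    """
    rng = np.random.default_rng(seed)
    rng.standard_normal(params.n_samples)  # consume the noise draw
    total = 0
    for _ in range(params.n_cycles):
        n_clicks = rng.poisson(params.click_rate)
        total += int(n_clicks)
        for _ in range(n_clicks):
            rng.uniform(0.0, 1.0)
            rng.lognormal(0.0, 0.25)
            rng.uniform(0.0, 2.0 * np.pi)
    return total


def _iter_cohort(n_symptomatic: int, n_control: int) -> Iterator[tuple[str, str]]:
    for i in range(n_symptomatic):
        yield f"S{i + 1:03d}", "symptomatic"
    for i in range(n_control):
        yield f"C{i + 1:03d}", "asymptomatic"


def simulate_cohort(
    n_symptomatic: int = 47,
    n_control: int = 47,
    sessions: int = 2,
    params: SimulationParams | None = None,
    seed: int = 0,
    side: str = "left",
) -> tuple[pd.DataFrame, list[VagRecording]]:
    """Simulate a two-group cohort with repeated recording sessions.

    Each subject's amplitude effect is drawn once (it persists across
    sessions); a fresh session effect is drawn per recording. Defaults give
    the two-group, 47+47-subject, two-session design.

    Returns
    -------
    manifest : pandas.DataFrame
        Columns ``subject_id, group, side, session, path`` (path empty until
        recordings are written to disk).
    recordings : list of VagRecording
        In manifest row order.
    """
    if n_symptomatic < 1 or n_control < 1 or sessions < 1:
        raise ValueError("subject and session counts must be >= 1")
    params = params or SimulationParams()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(1 + (n_symptomatic + n_control) * sessions)
    effect_rng = np.random.default_rng(children[0])
    # Independent child seeds per recording keep output invariant to order.
    rec_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in children[1:]]

    rows = []
    recordings: list[VagRecording] = []
    idx = 0
    for subject_id, group in _iter_cohort(n_symptomatic, n_control):
        subj_eff = effect_rng.normal(0.0, params.subject_sd)
        for sess in range(1, sessions + 1):
            sess_eff = effect_rng.normal(0.0, params.session_sd)
            rec = simulate_recording(
                params, group, subj_eff, sess_eff, seed=rec_seeds[idx],
                subject_id=subject_id, side=side, session=sess,
            )
            recordings.append(rec)
            rows.append({"subject_id": subject_id, "group": group,
                         "side": side, "session": sess, "path": ""})
            idx += 1
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    return manifest, recordings


def simulate_feature_matrix(model: TwoWayModelParams, seed: int = 0) -> np.ndarray:
    """Draw an n x k subjects-by-sessions matrix from the two-way model.

    ``X[i,j] = mu + r_i + c_j + e_ij`` with r ~ N(0, sigma_r^2),
    c ~ N(0, sigma_c^2), e ~ N(0, sigma_e^2), all independent.
    """
    rng = np.random.default_rng(seed)
    r = rng.normal(0.0, model.sigma_r, size=(model.n, 1))
    c = rng.normal(0.0, model.sigma_c, size=(1, model.k))
    e = rng.normal(0.0, model.sigma_e, size=(model.n, model.k))
    return model.mu + r + c + e
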