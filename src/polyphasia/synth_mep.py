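"""Synthetic motor-evoked-potential (MEP) traces with controllable polyphasia.

The study's raw EMG recordings are not deposited, so the scoring pipeline is
exercised on simulated traces. A trace is a train of alternating-sign
Gaussian lobes anchored at a configurable peak latency: a waveform built
from ``k + 1`` lobes changes sign exactly ``k`` times, which makes the
zero-crossing count of the noiseless waveform an exact, plantable ground
truth. White measurement noise and a noise-only pre-stimulus segment are
added on top.

Two calibration presets target the patient-group summary statistics
independently (they are not jointly satisfiable under a single
"polyphasic ⇔ crossings > 2" rule):

* ``patient-mean`` — crossing-count pmf with expectation 1.49
  (the patients' mean number of zero crossings);
* ``patient-ratio`` — pmf with P(crossings > 2) = 0.77
  (the patients' mean fraction of polyphasic MEPs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .formats_io import GROUPS, MEPTrace

# Default acquisition geometry: 20 kHz sampling (Nyquist-safe for the
# 20 Hz–10 kHz recording bandwidth), 10 ms of pre-stimulus baseline and
# 60 ms of post-stimulus signal.
DEFAULT_SAMPLING_RATE = 20_000.0
DEFAULT_PRE_MS = 10.0
DEFAULT_POST_MS = 60.0
# crossings are counted in [peak − 9 ms, peak + 36 ms]
WINDOW_POST_MS = 36.0


@dataclass(frozen=True)
class MEPGenSpec:
    """Parameters of one synthetic MEP."""

    target_crossings: int = 1
    peak_amplitude: float = 2.0        # mV, first-lobe height
    peak_latency_ms: float = 20.0      # typical cortical ADM latency
    phase_width_ms: float = 3.0        # lobe-to-lobe spacing
    # 1% of amplitude: the level the 5%-hysteresis counter rejects reliably
    # (band = 5 noise SDs; see docs/methods.md)
    noise_sd: float = 0.02             # mV
    sampling_rate: float = DEFAULT_SAMPLING_RATE
    pre_ms: float = DEFAULT_PRE_MS
    post_ms: float = DEFAULT_POST_MS

    def __post_init__(self) -> None:
        if self.target_crossings < 0:
            raise ValueError("target_crossings must be ≥ 0")
        if self.peak_amplitude <= 0:
            raise ValueError("peak_amplitude must be positive")
        if self.phase_width_ms <= 0:
            raise ValueError("phase_width_ms must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be ≥ 0")
        span = self.target_crossings * self.phase_width_ms
        if span > WINDOW_POST_MS - 2 * self.phase_width_ms:
            raise ValueError(
                f"{self.target_crossings} crossings at {self.phase_width_ms} ms "
                f"per lobe do not fit the +{WINDOW_POST_MS} ms analysis window")
        if self.peak_latency_ms + span + 2 * self.phase_width_ms > self.post_ms:
            raise ValueError("waveform does not fit the simulated sweep")


def synth_mep_trace(spec: MEPGenSpec, seed: int, *,
                    subject_id: str = "S1", group: str = "patient",
                    site: str = "cortex", muscle: str = "ADM",
                    side: str = "right", trace_id: str = "T1") -> MEPTrace:
    """Generate one MEP trace; deterministic given ``(spec, seed)``.

    The noiseless waveform is a sum of ``target_crossings + 1``
    alternating-sign Gaussian lobes spaced ``phase_width_ms`` apart, the
    first peaking at ``peak_latency_ms``; amplitudes decay geometrically
    (factor 0.8) so the first lobe is the first and largest extremum.
    """
    rng = np.random.default_rng(seed)
    n_pre = int(round(spec.pre_ms * 1e-3 * spec.sampling_rate))
    n_post = int(round(spec.post_ms * 1e-3 * spec.sampling_rate))
    t_ms = (np.arange(n_pre + n_post + 1) - n_pre) / spec.sampling_rate * 1e3

    sigma = spec.phase_width_ms / 4.0  # lobes well separated at this width
    clean = np.zeros_like(t_ms)
    for k in range(spec.target_crossings + 1):
        center = spec.peak_latency_ms + k * spec.phase_width_ms
        amp = spec.peak_amplitude * (0.8 ** k) * (-1.0 if k % 2 else 1.0)
        clean += amp * np.exp(-0.5 * ((t_ms - center) / sigma) ** 2)
    clean[t_ms < 0] = 0.0  # pre-stimulus segment is noise only

    noise = rng.normal(0.0, spec.noise_sd, size=t_ms.size) if spec.noise_sd else 0.0
    return MEPTrace(
        subject_id=subject_id, group=group, site=site, muscle=muscle,
        side=side, trace_id=trace_id, sampling_rate=spec.sampling_rate,
        stimulus_index=n_pre, samples=clean + noise,
    )


def noiseless_waveform(spec: MEPGenSpec) -> np.ndarray:
    """The underlying deterministic waveform (oracle for crossing counts)."""
    return synth_mep_trace(
        MEPGenSpec(**{**spec.__dict__, "noise_sd": 0.0}), seed=0).samples


@dataclass(frozen=True)
class GroupPreset:
    """Per-group generating distribution for a cohort simulation."""

    name: str
    crossing_pmf: dict[int, float]
    n_meps_range: tuple[int, int] = (10, 15)   # pulses recorded per subject
    peak_amplitude: float = 2.0
    amplitude_jitter: float = 0.3              # lognormal-ish scatter, mV sd
    peak_latency_ms: float = 20.0
    latency_jitter_ms: float = 1.5
    noise_frac: float = 0.01   # noise SD as a fraction of the drawn amplitude
    phase_width_ms: float = 3.0

    def __post_init__(self) -> None:
        if self.name not in GROUPS and self.name != "custom":
            raise ValueError(f"unknown group preset name {self.name!r}")
        total = sum(self.crossing_pmf.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"crossing_pmf sums to {total}, not 1")
        if any(k < 0 or p < 0 for k, p in self.crossing_pmf.items()):
            raise ValueError("crossing_pmf support and masses must be ≥ 0")
        if not 1 <= self.n_meps_range[0] <= self.n_meps_range[1]:
            raise ValueError("bad n_meps_range")

    def pmf_mean(self) -> float:
        return sum(k * p for k, p in self.crossing_pmf.items())


# Group presets calibrated so the pmf expectation matches each group's
# reported mean zero-crossing count (patients 1.49, relatives 1.46,
# controls 1.22).
PRESETS: dict[str, GroupPreset] = {
    "patient-mean": GroupPreset(
        name="patient", crossing_pmf={1: 0.62, 2: 0.27, 3: 0.11}),
    "relative-mean": GroupPreset(
        name="relative", crossing_pmf={1: 0.65, 2: 0.24, 3: 0.11}),
    "control-mean": GroupPreset(
        name="control", crossing_pmf={1: 0.82, 2: 0.14, 3: 0.04}),
    # fraction of polyphasic (> 2 crossings) MEPs = the patients' mean
    # polyphasia ratio 0.77
    "patient-ratio": GroupPreset(
        name="patient", crossing_pmf={1: 0.23, 3: 0.77}),
}

#: sites/muscles are cycled deterministically across a subject's pulses
_SITE_CYCLE = ("cortex", "cortex", "spinal_cervical", "spinal_lumbar")
_MUSCLE_FOR_SITE = {"cortex": ("ADM", "TA"), "spinal_cervical": ("ADM",),
                    "spinal_lumbar": ("TA",)}


def synth_subject(preset: GroupPreset, subject_id: str, seed: int,
                  n_meps: int | None = None) -> list[MEPTrace]:
    """Simulate one subject's block of 10–15 stimulations."""
    rng = np.random.default_rng(seed)
    if n_meps is None:
        lo, hi = preset.n_meps_range
        n_meps = int(rng.integers(lo, hi + 1))
    support = sorted(preset.crossing_pmf)
    probs = np.array([preset.crossing_pmf[k] for k in support])
    probs = probs / probs.sum()
    targets = rng.choice(support, size=n_meps, p=probs)

    # "custom" presets still need a valid trace group label
    group = preset.name if preset.name in GROUPS else "patient"
    traces = []
    for i, target in enumerate(targets):
        amp = max(0.5, preset.peak_amplitude + rng.normal(0.0, preset.amplitude_jitter))
        lat = max(10.0, preset.peak_latency_ms + rng.normal(0.0, preset.latency_jitter_ms))
        spec = MEPGenSpec(
            target_crossings=int(target), peak_amplitude=amp,
            peak_latency_ms=lat, phase_width_ms=preset.phase_width_ms,
            noise_sd=preset.noise_frac * amp)
        site = _SITE_CYCLE[i % len(_SITE_CYCLE)]
        muscles = _MUSCLE_FOR_SITE[site]
        traces.append(synth_mep_trace(
            spec, seed=int(rng.integers(0, 2**31 - 1)),
            subject_id=subject_id, group=group, site=site,
            muscle=muscles[i % len(muscles)],
            side=("right" if i % 2 == 0 else "left"),
            trace_id=f"{subject_id}_M{i:02d}",
        ))
    return traces


@dataclass(frozen=True)
class CohortConfig:
    """Per-group subject counts and presets; defaults mirror the study
    design of 20 patients, 23 first-degree relatives and 30 controls."""

    groups: tuple[tuple[str, int, GroupPreset], ...] = (
        ("patient", 20, PRESETS["patient-mean"]),
        ("relative", 23, PRESETS["relative-mean"]),
        ("control", 30, PRESETS["control-mean"]),
    )
    n_meps: int | None = None   # fix pulses per subject; None → draw 10–15

    def __post_init__(self) -> None:
        for name, n, _preset in self.groups:
            if name not in GROUPS:
                raise ValueError(f"unknown group {name!r}")
            if n < 0:
                raise ValueError("subject count must be ≥ 0")


def synth_cohort(config: CohortConfig | None = None, seed: int = 0) -> list[MEPTrace]:
    """Simulate a full cohort; reproducible from ``seed`` alone."""
    config = config or CohortConfig()
    rng = np.random.default_rng(seed)
    traces: list[MEPTrace] = []
    for group, n_subjects, preset in config.groups:
        for i in range(n_subjects):
            subject_id = f"{group[:3]}{i + 1:03d}"
            traces.extend(synth_subject(
                preset, subject_id, seed=int(rng.integers(0, 2**31 - 1)),
                n_meps=config.n_meps))
    return traces
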