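"""Zero-crossing polyphasia scoring of motor evoked potentials.

The scorer follows the operational definition used in TMS polyphasia
studies: an MEP is polyphasic when the baseline-corrected response crosses
zero more than twice. Crossings are counted inside a window anchored at the
first MEP peak, from 9 ms before to 36 ms after it. Because real EMG is
noisy, a crossing is only counted when the signal reaches at least
``hysteresis_frac`` of the window's maximum absolute amplitude on *both*
sides of the sign change (a Schmitt-trigger rule), which makes the count
invariant to amplitude scaling and to baseline offset.

Per subject, the mean crossing count over all recorded pulses and the
polyphasia ratio (polyphasic MEPs / total MEPs) are reported, plus a binary
subject label and the stimulation-site / muscle attribution of polyphasia.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .formats_io import DEFAULT_CONFIG, MEPTrace

logger = logging.getLogger(__name__)


class NoResponseError(ValueError):
    """No post-stimulus sample exceeds the response-onset threshold."""


@dataclass(frozen=True)
class PhaseCount:
    """Zero-crossing result for one MEP."""

    trace_id: str
    n_crossings: int
    window_start_ms: float
    window_end_ms: float
    polyphasic: bool
    baseline_mv: float
    peak_latency_ms: float
    subject_id: str = ""
    group: str = ""
    site: str = ""
    muscle: str = ""

    def __post_init__(self) -> None:
        if self.n_crossings < 0:
            raise ValueError("n_crossings must be ≥ 0")
        if not self.window_end_ms > self.window_start_ms:
            raise ValueError("window_end_ms must exceed window_start_ms")


@dataclass(frozen=True)
class SubjectSummary:
    subject_id: str
    group: str
    n_meps: int
    mean_crossings: float
    polyphasia_ratio: float
    subject_polyphasic: bool
    site_attribution: str    # cortex | spinal | both | none
    muscle_attribution: str  # ADM | TA | both | none

    def __post_init__(self) -> None:
        if self.n_meps < 1:
            raise ValueError("n_meps must be ≥ 1")
        if not 0.0 <= self.polyphasia_ratio <= 1.0:
            raise ValueError("polyphasia_ratio outside [0, 1]")
        if self.mean_crossings < 0:
            raise ValueError("mean_crossings must be ≥ 0")


def estimate_baseline(trace: MEPTrace) -> tuple[float, float]:
    """Mean and SD of the pre-stimulus segment (≥ 5 ms required)."""
    n_pre = trace.stimulus_index
    if n_pre / trace.sampling_rate * 1e3 < 5.0:
        raise ValueError("need ≥ 5 ms of pre-stimulus signal to estimate baseline")
    pre = trace.samples[:n_pre]
    return float(np.mean(pre)), float(np.std(pre))


def detect_first_peak(trace: MEPTrace, baseline: float, noise_sd: float,
                      k: float = 3.0, floor_mv: float = 0.1) -> float:
    """Latency (ms after stimulus) of the first local extremum after onset.

    Onset is the first post-stimulus sample whose absolute deviation from
    baseline exceeds ``k * noise_sd`` (or ``floor_mv`` when the recording is
    noiseless). The *first* extremum is returned even when a later lobe is
    larger — the analysis window is anchored at response onset, not at the
    global maximum.
    """
    threshold = k * noise_sd if noise_sd > 0 else floor_mv
    s = trace.samples[trace.stimulus_index:] - baseline
    above = np.flatnonzero(np.abs(s) > threshold)
    if above.size == 0:
        raise NoResponseError(
            f"trace {trace.trace_id}: no sample exceeds onset threshold "
            f"{threshold:.3g} mV")
    onset = int(above[0])
    d = np.diff(s)
    # local extremum: derivative sign change (plateaus break at their start)
    for i in range(max(onset, 1), s.size - 1):
        if d[i - 1] != 0 and np.sign(d[i]) != np.sign(d[i - 1]):
            return i / trace.sampling_rate * 1e3
    # monotone to the end: take the last sample as the extremum
    return (s.size - 1) / trace.sampling_rate * 1e3


def count_zero_crossings(trace: MEPTrace, peak_latency_ms: float | None = None,
                         pre_ms: float = 9.0, post_ms: float = 36.0,
                         hysteresis_frac: float = 0.05,
                         polyphasia_threshold: int = 2,
                         baseline: float | None = None,
                         noise_sd: float | None = None,
                         onset_k: float = 3.0,
                         onset_floor_mv: float = 0.1) -> PhaseCount:
    """Count baseline crossings in the peak-anchored analysis window.

    The window is ``[peak − pre_ms, peak + post_ms]`` clipped to the trace
    (the usable window length varies with the recording; clipping is logged).
    Hysteresis: samples are classified +1 / −1 only beyond
    ``hysteresis_frac × max |amplitude − baseline|`` of the window; the
    crossing count is the number of state changes in that thresholded
    sequence, so excursions that do not clear the band on both sides of a
    sign change are ignored.
    """
    if baseline is None or noise_sd is None:
        baseline, noise_sd = estimate_baseline(trace)
    if peak_latency_ms is None:
        peak_latency_ms = detect_first_peak(trace, baseline, noise_sd,
                                            k=onset_k, floor_mv=onset_floor_mv)

    fs = trace.sampling_rate
    start = trace.stimulus_index + int(round((peak_latency_ms - pre_ms) * 1e-3 * fs))
    end = trace.stimulus_index + int(round((peak_latency_ms + post_ms) * 1e-3 * fs))
    if start < 0:
        start = 0
    if end >= trace.samples.size:
        logger.warning("trace %s: analysis window clipped to trace end",
                       trace.trace_id)
        end = trace.samples.size - 1
    if end <= start:
        raise ValueError(f"trace {trace.trace_id}: empty analysis window")

    s = trace.samples[start:end + 1] - baseline
    peak_abs = float(np.max(np.abs(s)))
    band = hysteresis_frac * peak_abs
    states = np.where(s >= band, 1, np.where(s <= -band, -1, 0))
    nz = states[states != 0]
    n_crossings = int(np.count_nonzero(np.diff(nz))) if nz.size else 0

    t0 = (start - trace.stimulus_index) / fs * 1e3
    t1 = (end - trace.stimulus_index) / fs * 1e3
    return PhaseCount(
        trace_id=trace.trace_id, n_crossings=n_crossings,
        window_start_ms=t0, window_end_ms=t1,
        polyphasic=n_crossings > polyphasia_threshold,
        baseline_mv=baseline, peak_latency_ms=peak_latency_ms,
        subject_id=trace.subject_id, group=trace.group,
        site=trace.site, muscle=trace.muscle,
    )


def score_trace(trace: MEPTrace, config: dict | None = None) -> PhaseCount:
    """Full per-MEP pipeline: baseline → first peak → windowed crossings."""
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    return count_zero_crossings(
        trace,
        pre_ms=cfg["window_pre_ms"], post_ms=cfg["window_post_ms"],
        hysteresis_frac=cfg["hysteresis_frac"],
        polyphasia_threshold=cfg["polyphasia_threshold"],
        onset_k=cfg["onset_k"], onset_floor_mv=cfg["onset_floor_mv"],
    )


def attribute_site_muscle(phase_counts: list[PhaseCount]) -> tuple[str, str]:
    """Where (stimulation level) and in which muscle polyphasia appeared.

    Cervical and lumbar stimulation both count as *spinal*.
    """
    poly = [p for p in phase_counts if p.polyphasic]
    if not poly:
        return "none", "none"
    sites = {("cortex" if p.site == "cortex" else "spinal") for p in poly}
    muscles = {p.muscle for p in poly}
    site = "both" if len(sites) == 2 else sites.pop()
    muscle = "both" if len(muscles) == 2 else muscles.pop()
    return site, muscle


def summarize_subject(phase_counts: list[PhaseCount],
                      min_polyphasic_fraction: float = 0.0) -> SubjectSummary:
    """Per-subject summary over all analyzable MEPs.

    ``subject_polyphasic`` defaults to the "any polyphasic MEP" rule
    (``min_polyphasic_fraction = 0``); a stricter minimum fraction of
    polyphasic pulses can be required instead.
    """
    if not phase_counts:
        raise ValueError("no analyzable MEPs for subject")
    n = len(phase_counts)
    n_poly = sum(p.polyphasic for p in phase_counts)
    ratio = n_poly / n
    if min_polyphasic_fraction > 0:
        subject_poly = ratio >= min_polyphasic_fraction
    else:
        subject_poly = n_poly >= 1
    site, muscle = attribute_site_muscle(phase_counts)
    return SubjectSummary(
        subject_id=phase_counts[0].subject_id,
        group=phase_counts[0].group,
        n_meps=n,
        mean_crossings=float(np.mean([p.n_crossings for p in phase_counts])),
        polyphasia_ratio=ratio,
        subject_polyphasic=subject_poly,
        site_attribution=site,
        muscle_attribution=muscle,
    )


def score_cohort(traces: list[MEPTrace], config: dict | None = None
                 ) -> tuple[list[PhaseCount], list[SubjectSummary]]:
    """Score every trace and summarize every subject.

    Traces with no detectable response and subjects with zero analyzable
    MEPs are dropped with a logged note.
    """
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    per_subject: dict[str, list[PhaseCount]] = {}
    all_counts: list[PhaseCount] = []
    for trace in traces:
        try:
            pc = score_trace(trace, cfg)
        except NoResponseError as exc:
            logger.info("trace unanalyzable: %s", exc)
            continue
        all_counts.append(pc)
        per_subject.setdefault(trace.subject_id, []).append(pc)

    summaries = []
    for subject_id, counts in per_subject.items():
        if not counts:
            logger.info("subject %s: zero analyzable MEPs, excluded", subject_id)
            continue
        summaries.append(summarize_subject(
            counts, min_polyphasic_fraction=cfg["min_polyphasic_fraction"]))
    return all_counts, summaries
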