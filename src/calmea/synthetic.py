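"""Synthetic Ca2+-imaging fields and MEA recordings with known ground truth.

The calcium generator emulates the statistical structure of a
fluorescence-imaging stimulus experiment on a mixed neuronal culture:
a field of ~50-60 cells (configurable) is imaged at ~1 frame/s for 45 s,
the agonist is added at 10 s, and a fraction ``p_react`` of cells are
true responders.  Responders follow one of two kinetic templates that
contrast the observed response classes:

* ``transient`` — fast rise (3 frames to peak) followed by a slow
  exponential decline (tau = 15 s), the NMDA/glutamate-like shape;
* ``plateau``  — slower rise (8 frames) and a sustained maximum for the
  rest of the recording, the shape produced by e.g. quinolinic, ibotenic
  and domoic acid.

Non-responders are resting baseline plus additive Gaussian frame noise.
An optional contamination fraction of null cells receives a sustained
supra-threshold excursion, used to emulate an assay with a known false
positive rate.

The MEA generator draws homogeneous-Poisson background spikes per
electrode and injects scheduled burst packets on a configurable fraction
of electrodes; a companion renderer turns spike lists into noisy sampled
voltage traces for testing the adaptive-threshold spike detector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .core import ConfigurationError, FieldRecording, GenerationError
from .mea import SpikeTrain

KINETICS = ("transient", "plateau", "null")


@dataclass
class CaFieldConfig:
    """Configuration of one synthetic Ca2+-imaging field.

    Fluorescence values are in arbitrary camera units throughout.

    Parameters
    ----------
    n_cells : int
        Cells in the field (a real image field holds ~45-60).
    p_react : float
        Probability that a cell is a true responder.
    kinetics : {"transient", "plateau", "null"}
        Responder kinetic template; ``"null"`` forbids responders and is
        used for negative-control (buffer-only) fields.
    baseline_mean, baseline_sd : float
        Cell-to-cell heterogeneity of the resting fluorescence F0.
    noise_sd : float
        Additive per-frame Gaussian noise SD.  The default of 3.0 makes
        the mean + 3 SD noise band of null delta-F values land at the
        assay's working threshold of ~9.
    amp_mean, amp_sd, amp_min : float
        Responder peak-amplitude distribution: normal, truncated below at
        ``amp_min`` so true responders stay separable from noise.
    fpr_contamination : float
        Probability that a null cell nevertheless receives a sustained
        supra-threshold excursion (drawn uniformly on
        ``(contamination_threshold, 3 * contamination_threshold)``).
    n_frames, frame_interval, stimulus_frame :
        Acquisition geometry: 45 frames at 1 s with the stimulus at
        frame 10 by default.
    seed : int
        Seed for the generator; identical seeds give identical fields.
    """

    n_cells: int = 55
    p_react: float = 0.0
    kinetics: str = "null"
    baseline_mean: float = 50.0
    baseline_sd: float = 10.0
    noise_sd: float = 3.0
    amp_mean: float = 40.0
    amp_sd: float = 10.0
    amp_min: float = 15.0
    fpr_contamination: float = 0.0
    contamination_threshold: float = 9.0
    n_frames: int = 45
    frame_interval: float = 1.0
    stimulus_frame: int = 10
    transient_rise_frames: int = 3
    transient_decay_tau: float = 15.0
    plateau_rise_frames: int = 8
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.p_react <= 1.0:
            raise ConfigurationError("p_react must be in [0, 1]")
        if not 0.0 <= self.fpr_contamination <= 1.0:
            raise ConfigurationError("fpr_contamination must be in [0, 1]")
        if self.kinetics not in KINETICS:
            raise ConfigurationError(f"kinetics must be one of {KINETICS}")
        if self.kinetics == "null" and self.p_react > 0:
            raise ConfigurationError("kinetics='null' requires p_react = 0")
        if self.n_cells < 0 or self.n_frames <= 0:
            raise ConfigurationError("n_cells and n_frames must be positive")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        if self.amp_min <= 0:
            raise ConfigurationError("amp_min must be > 0")
        if not 0 <= self.stimulus_frame < self.n_frames:
            raise ConfigurationError("stimulus_frame must lie inside the recording")
        if self.frame_interval <= 0:
            raise ConfigurationError("frame_interval must be > 0")


@dataclass
class CaGroundTruth:
    """Per-cell ground truth aligned one-to-one with the generated traces."""

    responder: np.ndarray  # bool, true responder flags
    amplitude: np.ndarray  # peak amplitude; 0 for non-responders
    contaminated: np.ndarray  # bool, null cells given a supra-threshold excursion


def kinetic_template(
    kind: str,
    n_frames: int,
    stimulus_frame: int,
    rise_frames: int,
    decay_tau: float = 15.0,
    frame_interval: float = 1.0,
) -> np.ndarray:
    """Unit-amplitude response template, zero before the stimulus.

    The signal starts at the stimulus frame, rises linearly over
    ``rise_frames`` frames to 1, then either decays exponentially with
    time constant ``decay_tau`` seconds (transient) or stays at 1
    (plateau).
    """
    template = np.zeros(n_frames)
    if kind == "null":
        return template
    peak = stimulus_frame + rise_frames
    for f in range(stimulus_frame, n_frames):
        if f <= peak:
            template[f] = (f - stimulus_frame) / rise_frames
        elif kind == "transient":
            template[f] = math.exp(-(f - peak) * frame_interval / decay_tau)
        else:  # plateau
            template[f] = 1.0
    return template


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lower: float, size: int
) -> np.ndarray:
    a = (lower - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cell_traces(config: CaFieldConfig) -> Tuple[FieldRecording, CaGroundTruth]:
    """Generate one field of per-cell fluorescence traces.

    Returns the :class:`~calmea.core.FieldRecording` and the aligned
    :class:`CaGroundTruth`.  Identical configs (including ``seed``)
    produce bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, F = config.n_cells, config.n_frames

    baselines = np.clip(
        rng.normal(config.baseline_mean, config.baseline_sd, n), 1.0, None
    )
    responder = (
        rng.random(n) < config.p_react
        if config.kinetics != "null"
        else np.zeros(n, dtype=bool)
    )
    amps = np.zeros(n)
    if responder.any():
        amps[responder] = _truncated_normal(
            rng, config.amp_mean, config.amp_sd, config.amp_min, int(responder.sum())
        )
    contaminated = (~responder) & (rng.random(n) < config.fpr_contamination)
    thr = config.contamination_threshold
    excursions = np.zeros(n)
    if contaminated.any():
        excursions[contaminated] = rng.uniform(thr, 3 * thr, int(contaminated.sum()))

    resp_template = kinetic_template(
        config.kinetics,
        F,
        config.stimulus_frame,
        config.transient_rise_frames
        if config.kinetics == "transient"
        else config.plateau_rise_frames,
        config.transient_decay_tau,
        config.frame_interval,
    )
    # contaminated cells always get the sustained (plateau) shape
    contam_template = kinetic_template(
        "plateau", F, config.stimulus_frame, config.plateau_rise_frames
    )

    traces = (
        baselines[:, None]
        + (responder * amps)[:, None] * resp_template[None, :]
        + (contaminated * excursions)[:, None] * contam_template[None, :]
        + rng.normal(0.0, config.noise_sd, (n, F))
    )
    recording = FieldRecording(
        traces=traces,
        stimulus_frame=config.stimulus_frame,
        frame_times=np.arange(F) * config.frame_interval,
    )
    truth = CaGroundTruth(responder=responder, amplitude=amps, contaminated=contaminated)
    return recording, truth


# ---------------------------------------------------------------------------
# image rendering


@dataclass
class FieldRender:
    """A rendered field: image stack, nuclear channel and cell centroids."""

    stack: np.ndarray  # (n_frames, size, size) float32
    nuclear: np.ndarray  # (size, size) float32
    centroids: np.ndarray  # (n_cells, 2) int (row, col)


def _disk_offsets(radius: int) -> Tuple[np.ndarray, np.ndarray]:
    """Pixel offsets (dy, dx) with dy^2 + dx^2 <= radius^2."""
    r = int(radius)
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    keep = dy**2 + dx**2 <= r**2
    return dy[keep], dx[keep]


def _place_centroids(
    rng: np.random.Generator,
    n_cells: int,
    image_size: int,
    cell_radius: int,
    min_distance: float,
    max_tries: int,
) -> np.ndarray:
    lo, hi = cell_radius, image_size - cell_radius - 1
    if hi < lo:
        raise GenerationError("image too small for the requested cell radius")
    placed: List[Tuple[int, int]] = []
    tries = 0
    while len(placed) < n_cells:
        if tries >= max_tries:
            raise GenerationError(
                f"could not place {n_cells} cells after {max_tries} tries"
            )
        tries += 1
        cand = (int(rng.integers(lo, hi + 1)), int(rng.integers(lo, hi + 1)))
        if all(
            (cand[0] - p[0]) ** 2 + (cand[1] - p[1]) ** 2 >= min_distance**2
            for p in placed
        ):
            placed.append(cand)
    return np.asarray(placed, dtype=int).reshape(-1, 2)


def render_field_video(
    recording: FieldRecording,
    cell_radius: int = 4,
    image_size: int = 128,
    seed: int = 0,
    min_distance: Optional[float] = None,
    max_tries_per_cell: int = 5000,
) -> FieldRender:
    """Render a field recording as a multi-frame image stack.

    Each cell is a 2-D Gaussian blob (sigma = radius / 2) at a random
    integer-pixel centroid; blob intensity is normalised so that the mean
    pixel value inside the extraction disk of ``cell_radius`` equals the
    cell's trace value for that frame, making the noise-free
    render -> extract round trip scale-true.  The nuclear channel marks
    each centroid with a sharp Gaussian dot (a stand-in for a nuclear
    stain image).

    Centroid placement uses rejection sampling with a minimum centre
    distance of ``2 * cell_radius`` (configurable); exhausting the retry
    budget raises :class:`~calmea.core.GenerationError`.
    """
    n = recording.n_cells
    rng = np.random.default_rng(seed)
    if min_distance is None:
        min_distance = 2.0 * cell_radius
    if recording.centroids is not None:
        centroids = recording.centroids.astype(int)
    else:
        centroids = _place_centroids(
            rng, n, image_size, cell_radius, min_distance, max_tries_per_cell * max(n, 1)
        )
        recording.centroids = centroids.astype(float)

    sigma = cell_radius / 2.0
    half = int(math.ceil(3 * sigma))
    dy, dx = np.mgrid[-half : half + 1, -half : half + 1]
    kernel = np.exp(-(dy**2 + dx**2) / (2 * sigma**2))
    disk_dy, disk_dx = _disk_offsets(cell_radius)
    disk_mean = kernel[disk_dy + half, disk_dx + half].mean()
    kernel = kernel / disk_mean  # disk-mean of the blob == trace value

    stack = np.zeros((recording.n_frames, image_size, image_size), dtype=np.float64)
    nuclear = np.zeros((image_size, image_size), dtype=np.float64)
    n_sigma = max(1.0, cell_radius / 3.0)
    n_kernel = np.exp(-(dy**2 + dx**2) / (2 * n_sigma**2))
    for i in range(n):
        r, c = centroids[i]
        r0, r1 = r - half, r + half + 1
        c0, c1 = c - half, c + half + 1
        kr0, kc0 = max(0, -r0), max(0, -c0)
        kr1 = kernel.shape[0] - max(0, r1 - image_size)
        kc1 = kernel.shape[1] - max(0, c1 - image_size)
        r0, c0 = max(0, r0), max(0, c0)
        r1, c1 = min(image_size, r1), min(image_size, c1)
        sub = kernel[kr0:kr1, kc0:kc1]
        stack[:, r0:r1, c0:c1] += (
            recording.traces[i][:, None, None] * sub[None, :, :]
        )
        nuclear[r0:r1, c0:c1] += n_kernel[kr0:kr1, kc0:kc1]
    return FieldRender(
        stack=stack.astype(np.float32),
        nuclear=nuclear.astype(np.float32),
        centroids=centroids,
    )


# ---------------------------------------------------------------------------
# MEA simulation


@dataclass
class BurstEvent:
    """One scheduled burst: packet of spikes injected on a fraction of
    electrodes at a fixed intra-burst ISI."""

    time: float  # s, packet onset
    fraction: float  # participating fraction of electrodes, (0, 1]
    n_spikes: int  # spikes per participating electrode
    isi: float  # intra-burst inter-spike interval, s (< 0.1)


@dataclass
class MEAConfig:
    """Configuration of one synthetic MEA well.

    The well has ``n_electrodes`` electrodes (16 on the reference plate
    format) sampled at ``sampling_rate`` Hz (12.5 kHz by default).
    Background activity is an independent homogeneous Poisson process per
    electrode at ``background_rate`` Hz; each :class:`BurstEvent` in
    ``burst_schedule`` injects a synchronous spike packet.
    """

    n_electrodes: int = 16
    duration: float = 60.0
    background_rate: float = 1.0
    burst_schedule: List[BurstEvent] = dc_field(default_factory=list)
    sampling_rate: float = 12500.0
    spike_amplitude_sigma: float = 10.0
    onset_jitter: float = 0.005  # s, per-electrode packet-onset jitter
    seed: int = 0

    def validate(self) -> None:
        if self.n_electrodes <= 0:
            raise ConfigurationError("n_electrodes must be positive")
        if self.duration <= 0:
            raise ConfigurationError("duration must be positive")
        if self.background_rate < 0:
            raise ConfigurationError("background_rate must be >= 0")
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be positive")
        for ev in self.burst_schedule:
            if not 0 < ev.fraction <= 1:
                raise ConfigurationError("burst fraction must be in (0, 1]")
            if ev.isi >= 0.1 or ev.isi <= 0:
                raise ConfigurationError("scheduled burst ISI must be in (0, 0.1) s")
            if ev.n_spikes < 1:
                raise ConfigurationError("burst n_spikes must be >= 1")
            if not 0 <= ev.time < self.duration:
                raise ConfigurationError("burst time must lie inside the recording")


@dataclass
class MEAGroundTruth:
    """Scheduled truth for one simulated well."""

    spike_times: Dict[int, np.ndarray]  # all true spike times per electrode
    burst_windows: List[Tuple[float, float, Tuple[int, ...]]]  # (start, end, electrodes)


def generate_spike_trains(config: MEAConfig) -> Tuple[List[SpikeTrain], MEAGroundTruth]:
    """Simulate per-electrode spike time lists.

    Background spikes are a homogeneous Poisson process; each scheduled
    burst injects ``n_spikes`` regularly spaced spikes (with a small
    random onset jitter per electrode) on ``ceil(fraction * n_electrodes)``
    randomly chosen electrodes.  Times are sorted ascending.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    per_electrode: Dict[int, List[np.ndarray]] = {
        e: [] for e in range(config.n_electrodes)
    }
    for e in range(config.n_electrodes):
        n_bg = rng.poisson(config.background_rate * config.duration)
        per_electrode[e].append(np.sort(rng.uniform(0, config.duration, n_bg)))
    windows = []
    for ev in config.burst_schedule:
        k = int(math.ceil(ev.fraction * config.n_electrodes))
        chosen = rng.choice(config.n_electrodes, size=k, replace=False)
        end = ev.time
        for e in np.sort(chosen):
            onset = ev.time + rng.uniform(0, config.onset_jitter)
            times = onset + np.arange(ev.n_spikes) * ev.isi
            times = times[times < config.duration]
            per_electrode[int(e)].append(times)
            if times.size:
                end = max(end, float(times[-1]))
        windows.append((ev.time, end, tuple(int(e) for e in np.sort(chosen))))
    trains = []
    truth_times = {}
    for e in range(config.n_electrodes):
        t = np.sort(np.concatenate(per_electrode[e]))
        trains.append(SpikeTrain(electrode_id=e, times=t))
        truth_times[e] = t
    return trains, MEAGroundTruth(spike_times=truth_times, burst_windows=windows)


def spike_waveform(sampling_rate: float) -> np.ndarray:
    """Biphasic extracellular spike template, unit peak magnitude.

    A dominant negative deflection (the extremum, centred) followed by a
    smaller positive rebound; total length ~1.6 ms.
    """
    t = np.arange(-0.0008, 0.0008, 1.0 / sampling_rate)
    w = -np.exp(-(t**2) / (2 * 0.00015**2)) + 0.5 * np.exp(
        -((t - 0.00035) ** 2) / (2 * 0.00025**2)
    )
    return w / np.max(np.abs(w))


def render_voltage_traces(
    trains: Sequence[SpikeTrain], config: MEAConfig
) -> np.ndarray:
    """Render spike trains as sampled voltage: unit-SD Gaussian noise plus
    a biphasic waveform of peak amplitude ``spike_amplitude_sigma`` (in
    noise-SD units) at each spike time.

    Returns an ``(n_electrodes, n_samples)`` float array in the order of
    ``trains``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1_000_003)
    n_samples = int(round(config.duration * config.sampling_rate))
    wave = spike_waveform(config.sampling_rate) * config.spike_amplitude_sigma
    centre = int(np.argmax(np.abs(wave)))
    out = np.empty((len(trains), n_samples))
    for i, train in enumerate(trains):
        if train.n_spikes and train.times[-1] >= config.duration:
            raise ConfigurationError("spike times must be < duration")
        v = rng.normal(0.0, 1.0, n_samples)
        for t in train.times:
            s0 = int(round(t * config.sampling_rate)) - centre
            a, b = max(0, s0), min(n_samples, s0 + wave.size)
            if a < b:
                v[a:b] += wave[a - s0 : b - s0]
        out[i] = v
    return out
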