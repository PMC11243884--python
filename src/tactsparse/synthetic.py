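"""Seeded synthetic tactile grasp generator.

Emulates the statistical structure of high-density tactile-glove grasping
data that the sparsification survey exploits: events that are localized in
both space and time.  Each trial is a smooth, unimodal temporal pressure
envelope (a ~5 s grasp) multiplied by a spatially compact sum of Gaussian
activation blobs on a 32 x 32 taxel grid of which 548 positions carry a
physical sensor, plus additive Gaussian sensor noise, quantized to a 10-bit
ADC scale.

The generator is a statistical stand-in for real glove data, not a
biomechanical model: it reproduces spatiotemporal sparsity, temporal
smoothness and quantized dynamic range, but no per-object grasp signatures.
Everything is a pure function of (model, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ParameterError
from .io import TactileRecording


@dataclass(frozen=True)
class GraspModel:
    """Parameters of one synthetic grasp trial.

    Defaults describe the study conditions: a 32 x 32 grid carrying 548
    sensors, a ~5 s grasp (onset 1.5 s, offset 6.5 s) inside an 8 s trial
    sampled at 32 Hz, peak pressure 600 counts on a 10-bit scale, three
    activation blobs of spatial sigma 2 taxels, and 2 counts of sensor noise.
    """

    grid_rows: int = 32
    grid_cols: int = 32
    n_active_sensors: int = 548
    sampling_rate: float = 32.0      # Hz
    duration: float = 8.0            # s
    onset_time: float = 1.5          # s
    offset_time: float = 6.5         # s
    peak_pressure: float = 600.0     # ADC counts
    n_blobs: int = 3
    blob_width: float = 2.0          # spatial Gaussian sigma, taxels
    temporal_smoothness: float = 0.4  # rise/fall time constant, s
    noise_sd: float = 2.0            # ADC counts
    bit_depth: int = 10
    seed: int = 0

    def validate(self) -> None:
        if not (self.grid_rows >= 1 and self.grid_cols >= 1):
            raise ParameterError("grid_rows/grid_cols: must be positive")
        if not 1 <= self.n_active_sensors <= self.grid_rows * self.grid_cols:
            raise ParameterError(
                "n_active_sensors: must satisfy 1 <= n <= grid_rows*grid_cols"
            )
        if not self.sampling_rate > 0:
            raise ParameterError("sampling_rate: must be positive")
        if not self.duration > 0:
            raise ParameterError("duration: must be positive")
        if not 0 < self.onset_time < self.offset_time < self.duration:
            raise ParameterError(
                "onset_time/offset_time: need 0 < onset < offset < duration"
            )
        if self.peak_pressure < 0 or self.peak_pressure >= 2**self.bit_depth:
            raise ParameterError(
                f"peak_pressure: must lie in [0, 2^{self.bit_depth})"
            )
        if self.n_blobs < 1:
            raise ParameterError("n_blobs: must be >= 1")
        if not self.blob_width > 0:
            raise ParameterError("blob_width: must be positive")
        if not self.temporal_smoothness > 0:
            raise ParameterError("temporal_smoothness: must be positive")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd: must be non-negative")
        if not 1 <= self.bit_depth <= 16:
            raise ParameterError("bit_depth: must be in [1, 16]")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.sampling_rate))

    @property
    def peak_time(self) -> float:
        """Center of the envelope plateau (nominal time of peak activity)."""
        return 0.5 * (self.onset_time + self.offset_time)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.sampling_rate


@dataclass(frozen=True)
class JitterSpec:
    """Per-trial variability for :func:`generate_dataset`.

    onset_sd shifts the whole grasp in time (s); amplitude_sd scales peak
    pressure (multiplicative, 1 + N(0, sd)); center_sd perturbs blob centers
    (taxels).
    """

    onset_sd: float = 0.2
    amplitude_sd: float = 0.1
    center_sd: float = 1.0

    @classmethod
    def none(cls) -> "JitterSpec":
        return cls(0.0, 0.0, 0.0)


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def temporal_envelope(model: GraspModel, t: np.ndarray | None = None,
                      onset: float | None = None,
                      offset: float | None = None) -> np.ndarray:
    """Smooth rise/plateau/fall bump in [0, 1].

    Exactly zero before ``onset`` and after ``offset``; C1-smooth edges with
    rise/fall time ``temporal_smoothness``.
    """
    if t is None:
        t = model.times
    onset = model.onset_time if onset is None else onset
    offset = model.offset_time if offset is None else offset
    tau = min(model.temporal_smoothness, 0.5 * (offset - onset))
    rise = _smoothstep((t - onset) / tau)
    fall = _smoothstep((offset - t) / tau)
    return rise * fall


def sensor_mask(model: GraspModel) -> np.ndarray:
    """Fixed seeded subset of the grid marking the physical sensors.

    The real glove's 548-of-1024 layout is not published, so the mask is a
    uniform random subset reproducible from the model seed.
    """
    rng = np.random.default_rng([int(model.seed), 0x5EED])
    n_total = model.grid_rows * model.grid_cols
    idx = rng.choice(n_total, size=model.n_active_sensors, replace=False)
    mask = np.zeros(n_total, dtype=bool)
    mask[idx] = True
    return mask.reshape(model.grid_rows, model.grid_cols)


def _blob_field(model: GraspModel, mask: np.ndarray, centers: np.ndarray,
                amplitudes: np.ndarray) -> np.ndarray:
    rr, cc = np.mgrid[0:model.grid_rows, 0:model.grid_cols]
    field = np.zeros((model.grid_rows, model.grid_cols))
    for (r0, c0), a in zip(centers, amplitudes):
        d2 = (rr - r0) ** 2 + (cc - c0) ** 2
        field += a * np.exp(-d2 / (2.0 * model.blob_width**2))
    field *= mask
    peak = field.max()
    if peak > 0:
        field /= peak
    return field


def _draw_centers(model: GraspModel, rng: np.random.Generator) -> np.ndarray:
    # keep blob centers away from the border so blobs stay on the grid
    margin = min(2.0, model.grid_rows / 4, model.grid_cols / 4)
    r = rng.uniform(margin, model.grid_rows - 1 - margin, size=model.n_blobs)
    c = rng.uniform(margin, model.grid_cols - 1 - margin, size=model.n_blobs)
    return np.column_stack([r, c])


def _render(model: GraspModel, mask: np.ndarray, onset: float, offset: float,
            peak: float, centers: np.ndarray, amplitudes: np.ndarray,
            rng: np.random.Generator, metadata: dict[str, str]) -> TactileRecording:
    env = temporal_envelope(model, onset=onset, offset=offset)
    field = _blob_field(model, mask, centers, amplitudes)
    frames = peak * env[:, None, None] * field[None, :, :]
    if model.noise_sd > 0:
        noise = rng.normal(0.0, model.noise_sd, size=frames.shape)
        frames = frames + noise * mask[None, :, :]
    top = 2**model.bit_depth - 1
    frames = np.rint(np.clip(frames, 0, top)).astype(np.uint16)
    return TactileRecording(
        frames=frames,
        sensor_mask=mask,
        sampling_rate=model.sampling_rate,
        bit_depth=model.bit_depth,
        metadata=metadata,
    )


def generate_grasp(model: GraspModel) -> TactileRecording:
    """Generate one synthetic grasp recording.

    Per-taxel signal = smooth unimodal temporal envelope (zero outside
    [onset, offset]) x spatial Gaussian blob amplitudes + zero-mean Gaussian
    noise on masked-in taxels, clipped to [0, 2**bit_depth - 1] and rounded
    to integers.  Identical model (including seed) gives bit-identical
    output.
    """
    model.validate()
    mask = sensor_mask(model)
    rng = np.random.default_rng([int(model.seed), 1])
    centers = _draw_centers(model, rng)
    amplitudes = rng.uniform(0.6, 1.0, size=model.n_blobs)
    return _render(
        model, mask, model.onset_time, model.offset_time, model.peak_pressure,
        centers, amplitudes, rng,
        metadata={"source": "synthetic", "seed": str(model.seed)},
    )


def _noise_stream(model: GraspModel, shift: float, peak: float,
                  centers: np.ndarray) -> np.random.Generator:
    """Noise generator seeded by the trial's realized parameters, so equal
    parameters (zero jitter) reproduce equal noise."""
    import hashlib

    payload = np.asarray([shift, peak, *centers.ravel()], dtype=np.float64).tobytes()
    digest = hashlib.sha256(payload).digest()
    sub = int.from_bytes(digest[:8], "little")
    return np.random.default_rng([int(model.seed), 3, sub])


def generate_dataset(model: GraspModel, n_trials: int,
                     jitter: JitterSpec | None = None) -> list[TactileRecording]:
    """Generate ``n_trials`` grasp recordings with per-trial jitter.

    Onset/offset shift together by N(0, onset_sd); peak pressure scales by
    max(0.1, 1 + N(0, amplitude_sd)); blob centers move by N(0, center_sd)
    per coordinate.  Each trial's jitter comes from an independent seeded
    stream and the sensor-noise stream is a deterministic function of the
    trial's realized parameters, so a zero-jitter dataset consists of
    exactly identical recordings (apart from metadata) while jittered trials
    get independent noise.  The trial index is recorded in metadata.
    """
    model.validate()
    if n_trials < 1:
        raise ParameterError("n_trials: must be >= 1")
    jitter = JitterSpec.none() if jitter is None else jitter
    mask = sensor_mask(model)
    base_rng = np.random.default_rng([int(model.seed), 1])
    base_centers = _draw_centers(model, base_rng)
    base_amplitudes = base_rng.uniform(0.6, 1.0, size=model.n_blobs)

    recordings = []
    for trial in range(n_trials):
        rng = np.random.default_rng([int(model.seed), 2, trial])
        shift = rng.normal(0.0, jitter.onset_sd) if jitter.onset_sd > 0 else 0.0
        # keep the grasp inside the trial window
        lo, hi = -model.onset_time * 0.9, (model.duration - model.offset_time) * 0.9
        shift = float(np.clip(shift, lo, hi))
        scale = 1.0 + (rng.normal(0.0, jitter.amplitude_sd) if jitter.amplitude_sd > 0 else 0.0)
        scale = max(0.1, scale)
        peak = min(model.peak_pressure * scale, 2**model.bit_depth - 1)
        centers = base_centers + (
            rng.normal(0.0, jitter.center_sd, size=base_centers.shape)
            if jitter.center_sd > 0 else 0.0
        )
        centers = np.column_stack([
            np.clip(centers[:, 0], 0, model.grid_rows - 1),
            np.clip(centers[:, 1], 0, model.grid_cols - 1),
        ])
        noise_rng = _noise_stream(model, shift, peak, centers)
        rec = _render(
            model, mask, model.onset_time + shift, model.offset_time + shift,
            peak, centers, base_amplitudes, noise_rng,
            metadata={
                "source": "synthetic",
                "seed": str(model.seed),
                "trial": str(trial),
                "object": f"object_{trial % 26:02d}",
            },
        )
        recordings.append(rec)
    return recordings


def with_seed(model: GraspModel, seed: int) -> GraspModel:
    """Convenience: same model, different seed."""
    return replace(model, seed=int(seed))
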