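"""Synthetic 9-channel IMU exercise data.

Emulates recordings from a body-worn inertial/magnetic sensor unit
(tri-axial accelerometer, gyroscope and magnetometer, 25 Hz) collected
while subjects perform one of eight physiotherapy exercises.  Each
exercise class is a :class:`MotionTemplate` — one sinusoid plus baseline
per channel — so class separability is controlled by two knobs: the
inter-template gap and the noise level.  Subjects contribute additive
per-channel offsets, mimicking sensor-placement bias.

The generator is the test bed for the whole pipeline: every downstream
stage (splitting, transfer-feature extraction, classification,
evaluation) is exercised on tables produced here, with no external
download required.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataio import DEFAULT_FEATURE_NAMES, FeatureTable

N_CHANNELS = 9
N_CLASSES = 8

#: Per-class row counts emulating the reference dataset's imbalance:
#: 276,625 rows total, largest class 41,000, smallest 31,625.  Only the
#: two extremes are pinned by the source data; the six middle counts are
#: an evenly spaced decreasing sequence (step 750) chosen so the total
#: is exact.
REFERENCE_CLASS_COUNTS = (41000, 35875, 35125, 34375, 33625, 32875, 32125, 31625)
REFERENCE_TOTAL_ROWS = 276_625


def reference_class_proportions() -> np.ndarray:
    """Class proportions of the emulated benchmark dataset (sum to 1)."""
    counts = np.asarray(REFERENCE_CLASS_COUNTS, dtype=float)
    return counts / counts.sum()


@dataclass(frozen=True)
class MotionTemplate:
    """Deterministic per-class motion signature.

    Each of the 9 channels is ``amplitude * sin(2*pi*frequency*t + phase)
    + baseline``; evaluating at a time vector is a pure function of the
    parameters.

    Parameters are arrays of length 9 (channel order acc_x..mag_z);
    amplitudes and frequencies must be nonnegative.
    """

    amplitude: np.ndarray
    frequency: np.ndarray
    phase: np.ndarray
    baseline: np.ndarray

    def __post_init__(self) -> None:
        for name in ("amplitude", "frequency", "phase", "baseline"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (N_CHANNELS,):
                raise ValueError(
                    f"{name} must have exactly {N_CHANNELS} entries, got shape {arr.shape}"
                )
            object.__setattr__(self, name, arr)
        if np.any(self.amplitude < 0):
            raise ValueError("amplitudes must be nonnegative")
        if np.any(self.frequency < 0):
            raise ValueError("frequencies must be nonnegative")

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        """Evaluate the noise-free template at times ``t`` (seconds).

        Returns a ``len(t) x 9`` matrix.
        """
        t = np.asarray(t, dtype=float)[:, None]
        return (
            self.amplitude[None, :]
            * np.sin(2.0 * np.pi * self.frequency[None, :] * t + self.phase[None, :])
            + self.baseline[None, :]
        )


@dataclass(frozen=True)
class SimSpec:
    """Full description of a synthetic study: templates, subjects, noise.

    Attributes
    ----------
    templates : one MotionTemplate per class (K entries).
    class_proportions : nonnegative weights over classes, summing to 1.
    n_subjects : number of simulated subjects (default 5).
    subject_offset_sd : sd of the per-subject per-channel additive offset.
    noise_sd : sd of the iid Gaussian measurement noise.
    sample_rate : sampling rate in Hz (default 25).
    repetitions_per_subject : recordings pooled per (subject, class).
    seed : base seed for all randomness in this spec.
    """

    templates: tuple[MotionTemplate, ...]
    class_proportions: np.ndarray
    n_subjects: int = 5
    subject_offset_sd: float = 0.0
    noise_sd: float = 0.0
    sample_rate: float = 25.0
    repetitions_per_subject: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "templates", tuple(self.templates))
        props = np.asarray(self.class_proportions, dtype=float)
        object.__setattr__(self, "class_proportions", props)
        if len(props) != len(self.templates):
            raise ValueError(
                "class_proportions length must equal the number of templates"
            )
        if np.any(props < 0):
            raise ValueError("class proportions must be nonnegative")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"class proportions must sum to 1 (got {props.sum()!r})"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.subject_offset_sd < 0:
            raise ValueError("subject_offset_sd must be nonnegative")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be at least 1")

    @property
    def n_classes(self) -> int:
        return len(self.templates)

    def to_dict(self) -> dict:
        """Serializable form (for YAML config / sidecar metadata)."""
        return {
            "templates": [
                {
                    "amplitude": t.amplitude.tolist(),
                    "frequency": t.frequency.tolist(),
                    "phase": t.phase.tolist(),
                    "baseline": t.baseline.tolist(),
                }
                for t in self.templates
            ],
            "class_proportions": self.class_proportions.tolist(),
            "n_subjects": self.n_subjects,
            "subject_offset_sd": self.subject_offset_sd,
            "noise_sd": self.noise_sd,
            "sample_rate": self.sample_rate,
            "repetitions_per_subject": self.repetitions_per_subject,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimSpec":
        known = {
            "templates",
            "class_proportions",
            "n_subjects",
            "subject_offset_sd",
            "noise_sd",
            "sample_rate",
            "repetitions_per_subject",
            "seed",
        }
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown SimSpec keys: {sorted(unknown)}")
        templates = tuple(
            MotionTemplate(
                amplitude=np.asarray(t["amplitude"], dtype=float),
                frequency=np.asarray(t["frequency"], dtype=float),
                phase=np.asarray(t["phase"], dtype=float),
                baseline=np.asarray(t["baseline"], dtype=float),
            )
            for t in d["templates"]
        )
        kwargs = {k: v for k, v in d.items() if k != "templates"}
        kwargs["class_proportions"] = np.asarray(
            d["class_proportions"], dtype=float
        )
        return cls(templates=templates, **kwargs)


@dataclass(frozen=True)
class SensorRecording:
    """One continuous recording of one subject performing one exercise."""

    subject_id: int
    label: int
    samples: np.ndarray  # T x 9, time-ordered
    sample_rate: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 2 or samples.shape[0] < 1 or samples.shape[1] != N_CHANNELS:
            raise ValueError(f"samples must be T x {N_CHANNELS} with T >= 1")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples must be finite")


def _subject_offsets(spec: SimSpec) -> np.ndarray:
    """Per-subject per-channel offsets, drawn once from the spec seed.

    Deterministic in ``spec.seed`` only, so every recording of a subject
    shares the same offset regardless of per-recording seeds.
    """
    rng = np.random.default_rng(spec.seed)
    return rng.normal(0.0, spec.subject_offset_sd, size=(spec.n_subjects, N_CHANNELS))


def generate_recording(
    spec: SimSpec,
    class_index: int,
    subject_id: int,
    duration_s: float = 20.0,
    seed: int = 0,
) -> SensorRecording:
    """Simulate one recording: template + subject offset + Gaussian noise.

    ``samples[t, c] = template_c(t / sample_rate) + offset[subject, c] + eps``
    with ``eps ~ N(0, noise_sd^2)``.  Bit-reproducible given identical
    arguments.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if not 0 <= class_index < spec.n_classes:
        raise IndexError(
            f"class_index {class_index} out of range for {spec.n_classes} classes"
        )
    if not 0 <= subject_id < spec.n_subjects:
        raise IndexError(
            f"subject_id {subject_id} out of range for {spec.n_subjects} subjects"
        )
    n = int(round(duration_s * spec.sample_rate))
    n = max(n, 1)
    t = np.arange(n, dtype=float) / spec.sample_rate
    clean = spec.templates[class_index].evaluate(t)
    offsets = _subject_offsets(spec)[subject_id]
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, spec.noise_sd, size=clean.shape) if spec.noise_sd > 0 else 0.0
    return SensorRecording(
        subject_id=subject_id,
        label=class_index,
        samples=clean + offsets[None, :] + noise,
        sample_rate=spec.sample_rate,
    )


def largest_remainder_counts(n: int, proportions: np.ndarray) -> np.ndarray:
    """Apportion ``n`` rows to classes by the largest-remainder method.

    Quotas ``n * p_k`` are floored; the remaining rows go to the classes
    with the largest fractional remainders (ties broken by lower index).
    The result always sums exactly to ``n``.
    """
    proportions = np.asarray(proportions, dtype=float)
    if abs(proportions.sum() - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1")
    quota = n * proportions
    counts = np.floor(quota).astype(int)
    short = n - counts.sum()
    remainders = quota - counts
    # stable argsort on -remainder → ties broken by lowest class index
    order = np.argsort(-remainders, kind="stable")
    counts[order[:short]] += 1
    return counts


def generate_dataset(spec: SimSpec, n_rows: int, seed: int = 0) -> FeatureTable:
    """Pool recordings across subjects/classes into a shuffled flat table.

    Per-class row counts follow ``largest_remainder_counts(n_rows,
    spec.class_proportions)``.  Rows of each class are drawn from
    recordings spread round-robin over subjects and repetitions; the final
    row order is a seeded permutation.
    """
    if n_rows < spec.n_classes:
        raise ValueError("n_rows must be at least the number of classes")
    counts = largest_remainder_counts(n_rows, spec.class_proportions)
    rng = np.random.default_rng(seed)
    blocks: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    for k, need in enumerate(counts):
        if need == 0:
            continue
        rows: list[np.ndarray] = []
        got = 0
        rep = 0
        while got < need:
            for subject in range(spec.n_subjects):
                if got >= need:
                    break
                remaining = need - got
                duration = max(remaining / spec.sample_rate, 1.0 / spec.sample_rate)
                rec = generate_recording(
                    spec,
                    class_index=k,
                    subject_id=subject,
                    duration_s=min(duration, 20.0),
                    seed=int(rng.integers(0, 2**31)),
                )
                take = min(rec.samples.shape[0], remaining)
                rows.append(rec.samples[:take])
                got += take
            rep += 1
        blocks.append(np.concatenate(rows, axis=0)[:need])
        labels.append(np.full(need, k, dtype=int))
    features = np.concatenate(blocks, axis=0)
    y = np.concatenate(labels)
    perm = rng.permutation(len(y))
    return FeatureTable(
        features=features[perm],
        labels=y[perm],
        feature_names=list(DEFAULT_FEATURE_NAMES),
    )


def make_templates(
    n_classes: int = N_CLASSES,
    baseline_gap: float = 3.0,
    amplitude: float = 1.0,
) -> tuple[MotionTemplate, ...]:
    """Build a family of class templates with controllable separation.

    Class ``k`` gets per-channel baselines ``k * baseline_gap`` modulated
    by a fixed channel pattern, frequencies in the 0.4–1.8 Hz band of
    typical exercise cadence, and class-specific phases.  With
    ``baseline_gap=0`` all classes share identical statistics up to phase,
    which is the chance-level regime when phases are also equalised.
    """
    templates = []
    for k in range(n_classes):
        c = np.arange(N_CHANNELS)
        amp = np.full(N_CHANNELS, amplitude)
        freq = 0.4 + 0.2 * ((c + k) % 7)
        phase = (2.0 * np.pi * k / max(n_classes, 1)) + 0.3 * c
        base = baseline_gap * k * (1.0 + 0.15 * ((c % 3) - 1))
        templates.append(
            MotionTemplate(amplitude=amp, frequency=freq, phase=phase, baseline=base)
        )
    return tuple(templates)


def reference_sim_spec(
    baseline_gap: float = 3.0,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> SimSpec:
    """The reference study conditions for the synthetic benchmark.

    Well-separated templates (baseline gap 3 sensor units against noise
    sd 0.5), five subjects with placement offsets, 25 Hz, and the
    emulated class imbalance (largest class 41,000/276,625 of the mass).
    """
    return SimSpec(
        templates=make_templates(baseline_gap=baseline_gap),
        class_proportions=reference_class_proportions(),
        n_subjects=5,
        subject_offset_sd=0.3,
        noise_sd=noise_sd,
        sample_rate=25.0,
        repetitions_per_subject=1,
        seed=seed,
    )


def identical_template_spec(noise_sd: float = 1.0, seed: int = 0) -> SimSpec:
    """All classes share one template: labels carry no signal (chance floor)."""
    one = MotionTemplate(
        amplitude=np.full(N_CHANNELS, 1.0),
        frequency=np.full(N_CHANNELS, 1.0),
        phase=np.zeros(N_CHANNELS),
        baseline=np.zeros(N_CHANNELS),
    )
    return SimSpec(
        templates=(one,) * N_CLASSES,
        class_proportions=np.full(N_CLASSES, 1.0 / N_CLASSES),
        n_subjects=5,
        subject_offset_sd=0.0,
        noise_sd=noise_sd,
        sample_rate=25.0,
        seed=seed,
    )
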