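"""Class-conditional synthetic single-lead ECG generator.

Each beat is a sum of five Gaussians (P, Q, R, S, T) placed on an RR schedule
drawn from a lognormal interval model parameterized by mean heart rate and the
coefficient of variation (CV) of RR intervals. Class semantics:

* ``N`` — regular rhythm (low RR CV), full P-QRS-T morphology;
* ``A`` — atrial fibrillation surrogate: irregular rhythm (high RR CV) with
  the P wave suppressed;
* ``O`` — other rhythm: perturbed morphology (widened QRS, inverted T) with
  mildly irregular rhythm;
* ``~`` — noise-dominated: template amplitude far below the additive noise.

Additive white Gaussian noise plus an optional 0.3 Hz baseline-wander
sinusoid exercise the high-pass preprocessing stage. Everything is
deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ecg_io import LABELS, EcgRecord, RecordSet, ValidationError

#: PhysioNet-2017 class counts (N, A, O, ~) used for the imbalanced preset.
PAPER_CLASS_COUNTS = {"N": 5154, "A": 771, "O": 2557, "~": 46}


@dataclass
class GeneratorConfig:
    """Settings for one synthetic record."""

    fs: float = 300.0
    duration_s: float = 30.0
    mean_hr_bpm: float = 70.0
    rr_cv: float = 0.03
    noise_sd: float = 0.03
    class_label: str = "N"
    seed: int = 0
    #: amplitude of the 0.3 Hz baseline-wander sinusoid (0 disables)
    wander_amp: float = 0.1
    #: overall scaling of the beat template
    template_amp: float = 1.0
    #: per-wave morphology overrides {wave: (amp, width_s, offset_s)}
    morphology: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.duration_s <= 0:
            raise ValidationError("fs and duration_s must be positive")
        if self.rr_cv < 0 or self.noise_sd < 0:
            raise ValidationError("rr_cv and noise_sd must be non-negative")
        if self.class_label not in LABELS:
            raise ValidationError(f"unknown class label {self.class_label!r}")


# (amplitude in normalized units, width in s, offset from R peak in s)
_BASE_MORPHOLOGY = {
    "P": (0.15, 0.025, -0.20),
    "Q": (-0.10, 0.010, -0.030),
    "R": (1.00, 0.012, 0.0),
    "S": (-0.15, 0.010, 0.030),
    "T": (0.30, 0.060, 0.25),
}

#: Class presets layered on top of explicit GeneratorConfig fields.
CLASS_PRESETS: dict[str, dict] = {
    "N": {"rr_cv": 0.03, "noise_sd": 0.03, "morphology": {}},
    "A": {"rr_cv": 0.25, "noise_sd": 0.05, "morphology": {"P": (0.0, 0.025, -0.20)}},
    "O": {
        "rr_cv": 0.08,
        "noise_sd": 0.04,
        "morphology": {
            "Q": (-0.10, 0.022, -0.045),
            "R": (0.85, 0.026, 0.0),
            "S": (-0.15, 0.022, 0.045),
            "T": (-0.20, 0.060, 0.25),
        },
    },
    "~": {"rr_cv": 0.10, "noise_sd": 0.50, "template_amp": 0.10, "morphology": {}},
}


def config_for_class(label: str, seed: int = 0, **overrides) -> GeneratorConfig:
    """Build a GeneratorConfig from the class preset plus explicit overrides."""
    preset = dict(CLASS_PRESETS[label]) if label in CLASS_PRESETS else {}
    preset.update(overrides)
    return GeneratorConfig(class_label=label, seed=seed, **preset)


def _draw_rr_intervals(rng: np.random.Generator, mean_rr: float, cv: float,
                       total_s: float) -> np.ndarray:
    """Lognormal RR intervals with the requested mean and CV, covering total_s."""
    if cv <= 0:
        n = int(np.ceil(total_s / mean_rr)) + 2
        return np.full(n, mean_rr)
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean_rr) - sigma2 / 2.0
    out: list[float] = []
    t = 0.0
    while t < total_s + mean_rr:
        rr = float(rng.lognormal(mu, np.sqrt(sigma2)))
        rr = min(max(rr, 0.25), 2.5)  # physiological clamp
        out.append(rr)
        t += rr
    return np.asarray(out)


def generate_record(config: GeneratorConfig) -> EcgRecord:
    """Generate one synthetic ECG record; deterministic given ``config.seed``.

    The emitted RR interval series and R-peak sample indices are stored in
    ``record.meta`` so tests can verify the rhythm model directly.
    """
    rng = np.random.default_rng(config.seed)
    n = int(round(config.fs * config.duration_s))
    t = np.arange(n) / config.fs
    mean_rr = 60.0 / config.mean_hr_bpm

    rr = _draw_rr_intervals(rng, mean_rr, config.rr_cv, config.duration_s)
    r_times = np.cumsum(rr)
    # first beat lands after one interval; keep beats whose R peak is in range
    r_times = r_times[r_times < config.duration_s]

    morphology = dict(_BASE_MORPHOLOGY)
    morphology.update(config.morphology)

    x = np.zeros(n)
    for r_t in r_times:
        for amp, width, offset in morphology.values():
            if amp == 0.0:
                continue
            center = r_t + offset
            x += amp * np.exp(-0.5 * ((t - center) / width) ** 2)
    x *= config.template_amp

    if config.wander_amp:
        phase = rng.uniform(0, 2 * np.pi)
        x += config.wander_amp * np.sin(2 * np.pi * 0.3 * t + phase)
    if config.noise_sd:
        x += rng.normal(0.0, config.noise_sd, size=n)

    rid = f"syn-{config.class_label}-{config.seed:08d}"
    used_rr = rr[: r_times.size]
    return EcgRecord(
        x,
        fs=config.fs,
        label=config.class_label,
        record_id=rid,
        meta={
            "rr_intervals": used_rr,
            "r_peak_samples": np.round(r_times * config.fs).astype(int),
            "config": config,
        },
    )


def largest_remainder_counts(n: int, proportions: dict[str, float]) -> dict[str, int]:
    """Apportion ``n`` among classes by the largest-remainder method.

    Ties in remainders break by the iteration order of ``proportions``.
    """
    total = sum(proportions.values())
    quotas = {k: n * v / total for k, v in proportions.items()}
    counts = {k: int(np.floor(q)) for k, q in quotas.items()}
    seats = n - sum(counts.values())
    order = sorted(proportions, key=lambda k: quotas[k] - counts[k], reverse=True)
    for k in order[:seats]:
        counts[k] += 1
    return counts


def generate_dataset(
    n: int,
    imbalance: str = "paper_proportions",
    seed: int = 0,
    duration_range_s: tuple[float, float] = (30.0, 60.0),
    fixed_duration_s: float | None = None,
    records_per_subject: int = 1,
    fs: float = 300.0,
) -> RecordSet:
    """Generate an n-record synthetic dataset.

    ``imbalance="paper_proportions"`` follows the severe 5154/771/2557/46
    class imbalance of the public 2017 single-lead benchmark via
    largest-remainder apportionment (every class guaranteed >= 1 record);
    ``"balanced"`` splits evenly. Record durations are drawn uniformly from
    ``duration_range_s`` (or fixed). Subjects are assigned round-robin in
    groups of ``records_per_subject`` so each subject's records span classes,
    supporting leave-one-subject-out evaluation.
    """
    if n < len(LABELS):
        raise ValidationError(
            f"n={n} too small to represent all {len(LABELS)} classes"
        )
    if imbalance == "paper_proportions":
        counts = largest_remainder_counts(n, PAPER_CLASS_COUNTS)
    elif imbalance == "balanced":
        counts = largest_remainder_counts(n, {lab: 1.0 for lab in LABELS})
    else:
        raise ValidationError(f"unknown imbalance scheme {imbalance!r}")
    for lab in LABELS:
        if counts.get(lab, 0) < 1:
            # guarantee representation: take one from the largest class
            counts[lab] = 1
            counts[max(counts, key=counts.get)] -= 1

    rng = np.random.default_rng(seed)
    labels: list[str] = []
    for lab in LABELS:
        labels.extend([lab] * counts[lab])
    # interleave classes so round-robin subject grouping mixes them
    order = rng.permutation(n)
    labels = [labels[i] for i in order]

    n_subjects = int(np.ceil(n / records_per_subject))
    records = []
    for i, lab in enumerate(labels):
        if fixed_duration_s is not None:
            dur = fixed_duration_s
        else:
            dur = float(rng.uniform(*duration_range_s))
        hr = float(rng.uniform(60.0, 90.0))
        cfg = config_for_class(
            lab,
            seed=int(rng.integers(0, 2**31 - 1)),
            duration_s=dur,
            mean_hr_bpm=hr,
            fs=fs,
        )
        rec = generate_record(cfg)
        rec.record_id = f"rec{i:05d}"
        rec.subject_id = f"subj{i % n_subjects:04d}"
        records.append(rec)
    return RecordSet(records)


def generator_config_from_yaml(path) -> GeneratorConfig:
    """Build a GeneratorConfig from a YAML preset file.

    The file holds GeneratorConfig fields; ``morphology`` entries map wave
    names to [amplitude, width_s, offset_s] triples.
    """
    from pathlib import Path

    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    if "morphology" in raw:
        raw["morphology"] = {k: tuple(v) for k, v in raw["morphology"].items()}
    return GeneratorConfig(**raw)
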