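"""Ground-truth-known synthetic cohorts emulating the two-condition study.

The generator emulates a paired recording design: each subject is
recorded in both a "normal" and an "scz" (NMDA-antagonist-model-like)
condition, 8 epochs/day for 5 days, 10 s per epoch, 10 channels at
1,000 Hz, with channels grouped into frontal (4), parietal (4) and
occipital (2) regions.

Signal model, per epoch
-----------------------
Each region r has a band-limited (55-95 Hz) Gaussian driver d_r. Directed
region-level influence is an explicit lagged linear term: an edge
(src, tgt, lag, gain) adds ``gain * d_src(t - lag)`` to d_tgt. A channel
in region r mixes the (unit-variance) region driver with a private
band-limited noise according to ``coupling_strength``, then admixes
broadband white noise according to an epoch-level irregularity weight:

    osc_c   = sqrt(c) * d_r + sqrt(1 - c) * private_band_noise_c
    noise_c = sqrt(sf) * shared_white + sqrt(1 - sf) * private_white_c
    x_c     = (1 - w) * osc_c + w * noise_c,   w = irregularity(epoch)

Condition ground truth
----------------------
* normal: strong coupling, weak irregularity, directed F->P and F->O
  edges (parietal/occipital are net inflow regions), irregularity mostly
  channel-private.
* scz: weak coupling, strong irregularity, bidirectional edges of equal
  gain among all region pairs (dense couplings, no net-flow hub), and a
  large *shared* fraction of the broadband admixture. The epoch-level
  irregularity jitter acts as a latent severity: epochs with more
  irregularity (higher complexity) also carry more common broadband
  signal (higher coherence/MI), which couples complexity and
  connectivity positively within the scz cohort.

Subjects share a per-subject base seed across conditions (paired design)
and carry small subject-level offsets of coupling and irregularity, so
paired group tests see correlated within-subject pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .layout import default_layout
from .recording import Recording, write_epoch_csv, write_manifest

CONDITIONS = ("normal", "scz")


@dataclass(frozen=True)
class ConditionParams:
    """Generator parameters for one recording condition.

    ``noise_scope`` sets where the non-globally-shared part of the
    broadband admixture lives: ``"region"`` (one noise source per
    region, making same-region channels near-copies of each other) or
    ``"channel"`` (independent noise per channel). ``sensor_noise`` is a
    small channel-private white-noise amplitude present in every
    channel.
    """

    coupling_strength: float  # region-driver share of oscillatory power, [0, 1]
    irregularity: float  # broadband-noise mixing weight, [0, 1]
    irregularity_jitter: float  # epoch-level latent-severity s.d.
    shared_noise_fraction: float  # globally shared share of broadband-noise power
    directed_edges: tuple = ()  # (src_region, tgt_region, lag_samples, gain)
    noise_scope: str = "channel"  # "channel" | "region"
    sensor_noise: float = 0.03

    def __post_init__(self):
        for name in ("coupling_strength", "irregularity", "shared_noise_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.noise_scope not in ("channel", "region"):
            raise ValueError("noise_scope must be 'channel' or 'region'")


NORMAL_PARAMS = ConditionParams(
    coupling_strength=1.0,
    irregularity=0.15,
    irregularity_jitter=0.06,
    shared_noise_fraction=0.10,
    # one full cycle of the 75 Hz band centre: the lagged inflow is
    # positively correlated with its source at zero lag
    directed_edges=(("F", "P", 13, 1.1), ("F", "O", 13, 1.1)),
    noise_scope="region",
    sensor_noise=0.001,
)

SCZ_PARAMS = ConditionParams(
    coupling_strength=0.65,
    irregularity=0.55,
    irregularity_jitter=0.12,
    shared_noise_fraction=0.75,
    directed_edges=(
        ("F", "P", 4, 3.0), ("P", "F", 4, 3.0),
        ("F", "O", 4, 3.0), ("O", "F", 4, 3.0),
        ("P", "O", 4, 3.0), ("O", "P", 4, 3.0),
    ),
    noise_scope="channel",
)


@dataclass(frozen=True)
class SynthConfig:
    """Design constants and condition parameter sets for a synthetic cohort."""

    n_subjects: int = 10
    n_days: int = 5
    epochs_per_day: int = 8
    epoch_seconds: float = 10.0
    fs: float = 1000.0
    band: tuple[float, float] = (55.0, 95.0)
    region_sizes: dict = field(
        default_factory=lambda: {"F": 4, "P": 4, "O": 2}
    )
    amplitude_uv: float = 50.0  # channel standard deviation, microvolts
    condition_params: dict = field(
        default_factory=lambda: {"normal": NORMAL_PARAMS, "scz": SCZ_PARAMS}
    )
    seed: int = 0

    def __post_init__(self):
        n = self.epoch_seconds * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ValueError("epoch_seconds * fs must be an integer sample count")
        if sum(self.region_sizes.values()) != len(self.channel_labels):
            raise ValueError("region_sizes inconsistent with the channel layout")

    @property
    def n_epoch_samples(self) -> int:
        return int(round(self.epoch_seconds * self.fs))

    @property
    def channel_labels(self) -> list[str]:
        layout = default_layout()
        labels = []
        for region in self.region_sizes:
            labels.extend(layout.region_channels(region))
        return labels

    @property
    def epochs_per_condition(self) -> int:
        return self.n_days * self.epochs_per_day


def _band_sos(band: tuple[float, float], fs: float):
    return signal.butter(4, band, btype="bandpass", fs=fs, output="sos")


def _osc_sos(band: tuple[float, float], fs: float):
    """Resonant (spectrally peaked) oscillator filter inside ``band``.

    Oscillatory components use a narrower sub-band centred on the band
    midpoint, so their in-band spectrum is peaked rather than flat: the
    normal condition's mostly-oscillatory channels are more regular
    (lower ordinal entropy) than channels diluted with broadband noise,
    whose in-band spectrum is flat.
    """
    center = 0.5 * (band[0] + band[1])
    half = 0.2 * (band[1] - band[0])
    return signal.butter(2, (center - half, center + half), btype="bandpass",
                         fs=fs, output="sos")


def _band_noise(rng: np.random.Generator, n: int, sos) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise (filtered white noise)."""
    x = signal.sosfilt(sos, rng.standard_normal(n + 500))[500:]  # drop transient
    return x / x.std()


def _lagged(x: np.ndarray, lag: int) -> np.ndarray:
    out = np.zeros_like(x)
    out[lag:] = x[:-lag]
    return out


def gen_known_series(kind: str, n: int, seed: int = 0) -> np.ndarray:
    """Deterministic fixture series with known ordinal-pattern statistics.

    Kinds: ``constant``, ``monotonic``, ``periodic``, ``iid_uniform``,
    ``logistic_map`` (fully chaotic, r = 4).
    """
    if n < 2:
        raise ValueError("n must be at least 2")
    rng = np.random.default_rng(seed)
    if kind == "constant":
        return np.full(n, 1.0)
    if kind == "monotonic":
        return np.arange(n, dtype=float)
    if kind == "periodic":
        return np.sin(2 * np.pi * np.arange(n) / 16.0)
    if kind == "iid_uniform":
        return rng.uniform(size=n)
    if kind == "logistic_map":
        x = np.empty(n)
        x[0] = 0.1 + 0.8 * rng.uniform()
        for i in range(1, n):
            x[i] = 4.0 * x[i - 1] * (1.0 - x[i - 1])
        return x
    raise ValueError(
        f"unknown kind {kind!r}; expected one of constant, monotonic, "
        "periodic, iid_uniform, logistic_map"
    )


def gen_coupled_pair(
    coupling: float,
    lag: int,
    n: int,
    fs: float = 256.0,
    band: tuple[float, float] = (55.0, 95.0),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """A unidirectionally coupled pair of band-limited series (x drives y).

    ``y`` receives a lagged, coupling-scaled copy of ``x`` plus
    independent band-limited noise; ``coupling=0`` gives two independent
    series. Ground truth for directed-estimator tests.
    """
    if not 0.0 <= coupling <= 1.0:
        raise ValueError("coupling must lie in [0, 1]")
    if lag < 1:
        raise ValueError("lag must be >= 1 sample")
    if lag >= n:
        raise ValueError("lag must be smaller than the series length")
    rng = np.random.default_rng(seed)
    sos = _band_sos(band, fs)
    x = _band_noise(rng, n, sos)
    noise = _band_noise(rng, n, sos)
    y = coupling * _lagged(x, lag) + np.sqrt(1.0 - coupling**2) * noise
    return x, y


def _subject_traits(config: SynthConfig, subject_index: int) -> tuple[float, float]:
    """Subject-level (coupling, irregularity) offsets, shared across conditions."""
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 7919, subject_index])
    )
    return rng.normal(0.0, 0.03), rng.normal(0.0, 0.03)


def _gen_epoch(
    config: SynthConfig,
    params: ConditionParams,
    rng: np.random.Generator,
    coupling_offset: float,
    irregularity_offset: float,
) -> np.ndarray:
    n = config.n_epoch_samples
    sos = _osc_sos(config.band, config.fs)
    layout = default_layout()

    drivers = {r: _band_noise(rng, n, sos) for r in config.region_sizes}
    base = dict(drivers)
    for src, tgt, lag, gain in params.directed_edges:
        drivers[tgt] = drivers[tgt] + gain * _lagged(base[src], lag)
    drivers = {r: d / d.std() for r, d in drivers.items()}

    # subject coupling perturbation shrinks toward the [0, 1] boundaries so a
    # condition pinned at full coupling stays exactly there
    c0 = params.coupling_strength
    c = float(np.clip(c0 + coupling_offset * 4.0 * c0 * (1.0 - c0), 0.0, 1.0))
    severity = rng.normal(0.0, params.irregularity_jitter)
    w = float(np.clip(params.irregularity + irregularity_offset + severity, 0.02, 0.9))
    sf = params.shared_noise_fraction

    shared_white = rng.standard_normal(n)
    channels = []
    for region in config.region_sizes:
        region_white = rng.standard_normal(n)
        for _label in layout.region_channels(region):
            private_osc = _band_noise(rng, n, sos)
            osc = np.sqrt(c) * drivers[region] + np.sqrt(1.0 - c) * private_osc
            local = region_white if params.noise_scope == "region" else rng.standard_normal(n)
            noise = np.sqrt(sf) * shared_white + np.sqrt(1.0 - sf) * local
            x = ((1.0 - w) * osc + w * noise
                 + params.sensor_noise * rng.standard_normal(n))
            channels.append(config.amplitude_uv * x / x.std())
    return np.vstack(channels)


def gen_subject(
    config: SynthConfig, condition: str, subject_index: int
) -> list[Recording]:
    """All epochs of one subject in one condition (n_days x epochs_per_day)."""
    if condition not in config.condition_params:
        raise ValueError(f"unknown condition {condition!r}")
    params = config.condition_params[condition]
    coupling_off, irr_off = _subject_traits(config, subject_index)
    cond_code = CONDITIONS.index(condition)
    labels = config.channel_labels
    recs = []
    for day in range(config.n_days):
        for epoch in range(config.epochs_per_day):
            rng = np.random.default_rng(
                np.random.SeedSequence(
                    [config.seed, subject_index, cond_code, day, epoch]
                )
            )
            samples = _gen_epoch(config, params, rng, coupling_off, irr_off)
            recs.append(
                Recording(
                    samples=samples,
                    fs=config.fs,
                    channel_labels=list(labels),
                    subject_id=f"S{subject_index:02d}",
                    condition=condition,
                    day=day,
                    epoch=epoch,
                )
            )
    return recs


def gen_cohort(config: SynthConfig) -> dict[tuple[str, str], list[Recording]]:
    """The full paired dataset: (subject_id, condition) -> epoch list."""
    if config.n_subjects < 2:
        raise ValueError("n_subjects must be at least 2")
    out: dict[tuple[str, str], list[Recording]] = {}
    for i in range(config.n_subjects):
        for condition in config.condition_params:
            recs = gen_subject(config, condition, i)
            out[(recs[0].subject_id, condition)] = recs
    return out


def write_cohort(config: SynthConfig, out_dir) -> str:
    """Write every epoch as CSV plus a manifest; returns the manifest path."""
    from pathlib import Path

    out_dir = Path(out_dir)
    rows = []
    for (subject, condition), recs in gen_cohort(config).items():
        for rec in recs:
            rel = f"{subject}/{condition}/day{rec.day}_epoch{rec.epoch}.csv"
            write_epoch_csv(rec, out_dir / rel)
            rows.append(
                {
                    "subject": subject,
                    "condition": condition,
                    "day": rec.day,
                    "epoch": rec.epoch,
                    "path": rel,
                }
            )
    manifest_path = out_dir / "manifest.csv"
    write_manifest(rows, manifest_path)
    return str(manifest_path)


def scaled_config(config: SynthConfig, n_subjects: int, n_days: int,
                  epochs_per_day: int) -> SynthConfig:
    """A reduced-size copy of a config (same conditions and constants)."""
    return replace(
        config,
        n_subjects=n_subjects,
        n_days=n_days,
        epochs_per_day=epochs_per_day,
    )
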