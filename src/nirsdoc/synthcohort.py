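"""Synthetic two-group resting-state fNIRS cohorts with known ground truth.

The generator emulates the study conditions of a DOC cohort: two groups
(8 "MCS-like", 10 "UWS-like") of 48-channel, 20-min, 11-Hz dual-wavelength
recordings whose HbT series carry a group-dependent latent covariance
structure, plus physiological confounds (cardiac ~1 Hz, respiration
0.2-0.6 Hz, Mayer waves ~0.1 Hz, slow drift, white noise, motion spikes)
and planted bad channels.

Generative model
----------------
Each subject draws a latent coupling graph A.  Its density is the group
parameter; edges fill the within-region (montage module) channel pairs
first and spend the remaining budget on random between-region pairs, so a
lower density means predominantly short-range coupling.  Thresholded
networks of low-density subjects therefore fragment into regional clusters
(long Lp, low Eg) while high-density subjects stay globally integrated —
the reduced long-range cortico-cortical integration attributed to UWS.

The band-limited (0.01-0.1 Hz) latent HbT signals are Gaussian mixtures on
the graph: s = row_normalise(I + gamma * A) z with iid z, where
gamma = (1 - sqrt(1 - c^2)) / c maps the coupling strength c in [0, 1) so
that an isolated coupled pair has population correlation exactly c.  The
full population correlation matrix is available in closed form
(:func:`population_correlation`); channels that are uncoupled *and* share
no neighbour are exactly uncorrelated, channels bridged by common
neighbours acquire the indirect correlation a mixing model implies.

Planted defects map one-to-one onto the quality-control rules: ``low_snr``
multiplies the channel's intensity by strong low-frequency gain noise
(SNR < 2); ``no_cardiac`` omits the cardiac oscillation; ``anticorrelated``
replaces the channel's slow content with the negated common signal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal

from .montage import Montage, default_montage
from .optics import OpticalModel, default_optics
from .recording import HemoRecording, RawRecording

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "population_correlation",
    "latent_graph",
    "latent_to_hbt",
    "forward_to_intensity",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]

DEFECTS = ("low_snr", "no_cardiac", "anticorrelated")

_DEFAULT_NOISE = {
    "cardiac": 0.6,      # uM, ~1 Hz arterial pulsation
    "respiration": 0.2,  # uM, 0.2-0.6 Hz
    "mayer": 0.25,       # uM, ~0.1 Hz blood-pressure waves
    "drift": 0.5,        # uM, very-low-frequency wander
    "white": 0.15,       # uM, sensor noise
    "global": 0.5,       # uM, systemic 0.01-0.1 Hz component shared by all channels
}


@dataclass(frozen=True)
class SynthConfig:
    """Cohort-level generator settings (the study conditions)."""

    n_group_a: int = 8            # MCS-like subjects
    n_group_b: int = 10           # UWS-like subjects
    n_channels: int = 48
    fs: float = 11.0              # Hz
    duration: float = 1200.0      # seconds (20 min)
    latent_density_a: float = 0.45
    latent_density_b: float = 0.22
    coupling_strength: float = 0.6
    signal_amplitude: float = 0.8  # uM, latent slow HbT signal
    noise_amplitudes: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_NOISE)
    )
    cardiac_freq: float = 1.0     # Hz
    motion_spike_rate: float = 0.2  # events / minute
    spike_amplitude: float = 8.0  # uM
    spike_width: float = 1.0      # seconds
    bad_channel_plan: tuple[tuple[int, str], ...] = (
        (5, "low_snr"), (22, "no_cardiac"), (40, "anticorrelated"),
    )  # (0-based channel index, defect)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_group_a < 0 or self.n_group_b < 0:
            raise ValueError("group sizes must be >= 0")
        if self.n_group_a + self.n_group_b == 0:
            raise ValueError("cohort must contain at least one subject")
        if self.duration < 300.0:
            raise ValueError(
                "duration must be >= 300 s (the pipeline extracts a 5-min segment)"
            )
        n = self.duration * self.fs
        if abs(n - round(n)) > 1e-9 or round(n) < 1:
            raise ValueError("duration * fs must be an integer sample count >= 1")
        for name, d in (("latent_density_a", self.latent_density_a),
                        ("latent_density_b", self.latent_density_b)):
            if not 0 <= d <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0 <= self.coupling_strength < 1:
            raise ValueError("coupling_strength must be in [0, 1)")
        for ch, defect in self.bad_channel_plan:
            if not 0 <= ch < self.n_channels:
                raise ValueError(f"bad-channel index {ch} out of range")
            if defect not in DEFECTS:
                raise ValueError(f"unknown defect {defect!r}")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))


@dataclass
class GroundTruth:
    """Everything the generator planted, for downstream verification."""

    labels: list[str]
    latent_adjacency: list[np.ndarray]
    planted_bad_channels: list[tuple[int, str]]
    injected_spikes: list[list[tuple[int, int]]]  # per subject: (channel, sample)

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.latent_adjacency):
            raise ValueError("labels length must equal cohort size")
        for a in self.latent_adjacency:
            if np.any(a != a.T) or np.any(np.diagonal(a)):
                raise ValueError("latent adjacency must be symmetric, zero diagonal")


# ---------------------------------------------------------------------------
# latent structure

def latent_graph(
    n_channels: int,
    density: float,
    modules: list[int] | None,
    rng: np.random.Generator,
    within_fill: float = 1.0,
) -> np.ndarray:
    """Random coupling graph with the given expected edge density.

    Within-module pairs are filled before between-module pairs: with an edge
    budget k = round(density * n_pairs), up to ``within_fill`` of the
    within-module pairs are taken first (at random) and the remainder of
    the budget goes to random between-module pairs, so low-density graphs
    are predominantly short-range.  With ``modules=None`` the graph is
    plain Erdos-Renyi with exactly k edges.
    """
    iu, ju = np.triu_indices(n_channels, k=1)
    n_pairs = len(iu)
    k = int(np.floor(density * n_pairs + 0.5))
    adj = np.zeros((n_channels, n_channels), dtype=bool)
    if k == 0:
        return adj
    if modules is None:
        chosen = rng.choice(n_pairs, size=k, replace=False)
    else:
        mod = np.asarray(modules)
        within = np.flatnonzero(mod[iu] == mod[ju])
        between = np.flatnonzero(mod[iu] != mod[ju])
        k_within = min(k, int(round(within_fill * len(within))))
        chosen = rng.choice(within, size=k_within, replace=False)
        k_between = min(k - k_within, len(between))
        if k_between > 0:
            chosen = np.concatenate(
                [chosen, rng.choice(between, size=k_between, replace=False)]
            )
    adj[iu[chosen], ju[chosen]] = True
    return adj | adj.T


def _gamma(coupling_strength: float) -> float:
    c = coupling_strength
    if not 0 <= c < 1:
        raise ValueError(f"coupling_strength must be in [0, 1), got {c}")
    if c == 0:
        return 0.0
    return (1.0 - np.sqrt(1.0 - c * c)) / c


def population_correlation(adjacency: np.ndarray, coupling_strength: float) -> np.ndarray:
    """Closed-form population correlation of the mixing model.

    With M = I + gamma * A and Sigma = M M^T, the model's correlation is
    r_ij = Sigma_ij / sqrt(Sigma_ii Sigma_jj).  For an isolated coupled pair
    this equals the coupling strength exactly; for the complete graph it
    tends to 1 as the coupling strength tends to 1.
    """
    a = np.asarray(adjacency, dtype=float)
    if np.any(a != a.T) or np.any(np.diagonal(a)):
        raise ValueError("adjacency must be symmetric with zero diagonal")
    g = _gamma(coupling_strength)
    m = np.eye(a.shape[0]) + g * a
    sigma = m @ m.T
    d = np.sqrt(np.diagonal(sigma))
    return sigma / np.outer(d, d)


def latent_to_hbt(
    adjacency: np.ndarray,
    coupling_strength: float,
    n_samples: int,
    seed: int | np.random.Generator,
    fs: float | None = None,
    band: tuple[float, float] | None = None,
) -> np.ndarray:
    """Unit-variance multichannel series with the model's correlation.

    Draws iid standard-normal innovations (optionally band-limited to
    ``band`` Hz at sampling rate ``fs``; the identical filter on every
    channel leaves the cross-correlation structure untouched), mixes them
    with row-normalised I + gamma*A, and returns (n_channels, n_samples).
    """
    a = np.asarray(adjacency, dtype=bool)
    if np.any(a != a.T) or np.any(np.diagonal(a)):
        raise ValueError("adjacency must be symmetric with zero diagonal")
    g = _gamma(coupling_strength)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z = rng.standard_normal((a.shape[0], n_samples))
    if band is not None:
        if fs is None:
            raise ValueError("band-limiting requires fs")
        sos = signal.butter(2, band, btype="bandpass", fs=fs, output="sos")
        z = signal.sosfiltfilt(sos, z, axis=-1)
        z = z / max(z.std(), np.finfo(float).tiny)  # common scalar: r preserved
    m = np.eye(a.shape[0]) + g * a.astype(float)
    m /= np.sqrt((m * m).sum(axis=1))[:, None]  # unit population variance
    return m @ z


# ---------------------------------------------------------------------------
# forward optics

def forward_to_intensity(
    hemo: HemoRecording,
    optics: OpticalModel | None = None,
    baseline: float | np.ndarray = 1.0,
) -> RawRecording:
    """Exact inverse of the MBLL conversion: concentrations -> intensity.

    dOD(lambda) = [eps @ (dHbO, dHbR)] * DPF * L, I = baseline * 10^-dOD.
    ``baseline`` may be scalar or per (channel, wavelength).
    """
    optics = optics or default_optics()
    coupling = optics.coupling_matrix()
    if np.linalg.cond(coupling) > 1e12:
        raise ValueError("singular extinction matrix")
    conc_mm = np.stack([hemo.hbo, hemo.hbr], axis=1) * 1e-3  # uM -> mM
    od = np.einsum("wc,ncs->nws", coupling, conc_mm)
    base = np.broadcast_to(np.asarray(baseline, dtype=float), od.shape[:2])
    intensity = base[..., None] * 10.0 ** (-od)
    return RawRecording(intensity, fs=hemo.fs, wavelengths=optics.wavelengths,
                        subject_id=hemo.subject_id)


# ---------------------------------------------------------------------------
# cohort assembly

def _oscillation(
    rng: np.random.Generator,
    n_ch: int,
    t: np.ndarray,
    freq: float,
    amp: float,
    phase_jitter: float = 0.25,
) -> np.ndarray:
    """Near-coherent systemic sinusoid: common phase with per-channel jitter.

    Systemic oscillations (cardiac pulsation, respiration, Mayer waves)
    arrive nearly simultaneously across the scalp, so channel phases
    scatter only mildly (SD ``phase_jitter`` rad) around a common subject
    phase; amplitudes carry mild lognormal jitter.
    """
    phase0 = rng.uniform(0, 2 * np.pi)
    phases = phase0 + rng.normal(0, phase_jitter, n_ch)
    amps = amp * np.exp(rng.normal(0, 0.2, n_ch))
    return amps[:, None] * np.sin(2 * np.pi * freq * t[None, :] + phases[:, None])


def _lowfreq_noise(
    rng: np.random.Generator,
    shape: tuple[int, ...],
    fs: float,
    cutoff: float | tuple[float, float],
) -> np.ndarray:
    """Unit-SD low-pass (or band-pass) filtered Gaussian noise, per row."""
    x = rng.standard_normal(shape)
    if isinstance(cutoff, tuple):
        sos = signal.butter(2, cutoff, btype="bandpass", fs=fs, output="sos")
    else:
        sos = signal.butter(2, cutoff, btype="lowpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, x, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    return x / np.where(sd > 0, sd, 1.0)


def _generate_subject(
    cfg: SynthConfig,
    density: float,
    montage: Montage,
    optics: OpticalModel,
    rng: np.random.Generator,
    subject_id: str,
) -> tuple[RawRecording, np.ndarray, list[tuple[int, int]]]:
    n_ch, n = cfg.n_channels, cfg.n_samples
    t = np.arange(n) / cfg.fs
    amp = dict(_DEFAULT_NOISE)
    amp.update(cfg.noise_amplitudes)
    bad = dict(cfg.bad_channel_plan)

    adj = latent_graph(n_ch, density, montage.module_assignment()
                       if montage.n_channels == n_ch else None, rng)
    slow = cfg.signal_amplitude * latent_to_hbt(
        adj, cfg.coupling_strength, n, rng, fs=cfg.fs, band=(0.01, 0.1)
    )
    common = amp["global"] * _lowfreq_noise(rng, (1, n), cfg.fs, (0.01, 0.1))
    drift = amp["drift"] * _lowfreq_noise(rng, (n_ch, n), cfg.fs, 0.01)
    x = slow + common + drift  # slow content, uM HbT

    f_card = float(np.clip(cfg.cardiac_freq * (1 + rng.normal(0, 0.05)), 0.8, 1.6))
    cardiac = _oscillation(rng, n_ch, t, f_card, amp["cardiac"])
    for ch, d in bad.items():
        if d == "no_cardiac":
            cardiac[ch] = 0.0
    x = x + cardiac
    x = x + _oscillation(rng, n_ch, t, rng.uniform(0.2, 0.6), amp["respiration"])
    x = x + _oscillation(rng, n_ch, t, float(np.clip(rng.normal(0.1, 0.01), 0.05, 0.15)),
                         amp["mayer"])

    # anticorrelated defect: the channel is replaced by the negated common
    # signal, modelling an inverted-coupling channel.  The common reference
    # is region-balanced (mean of the region means) so the inversion is
    # negative against every region's shared component, not only the
    # largest one.
    anti = [ch for ch, d in bad.items() if d == "anticorrelated"]
    if anti:
        others = np.setdiff1d(np.arange(n_ch), anti)
        modules = np.asarray(montage.module_assignment()
                             if montage.n_channels == n_ch else [0] * n_ch)
        region_means = [
            x[[c for c in others if modules[c] == m]].mean(axis=0)
            for m in np.unique(modules[others])
        ]
        common_signal = np.mean(region_means, axis=0)
        for ch in anti:
            x[ch] = -2.0 * common_signal

    x = x + amp["white"] * rng.standard_normal((n_ch, n))

    # motion spikes: boxcar transients shared across channels with random gains
    spikes: list[tuple[int, int]] = []
    w = max(1, int(round(cfg.spike_width * cfg.fs)))
    n_events = rng.poisson(cfg.motion_spike_rate * cfg.duration / 60.0)
    for _ in range(n_events):
        onset = int(rng.integers(0, max(1, n - w)))
        sign = rng.choice([-1.0, 1.0])
        gains = sign * cfg.spike_amplitude * rng.normal(1.0, 0.3, n_ch)
        for ch in anti:
            gains[ch] = -gains[ch]  # inverted-coupling channel flips transients too
        x[:, onset : onset + w] += gains[:, None]
        spikes.extend((int(ch), onset) for ch in range(n_ch))

    # split HbT into HbO/HbR (HbO-dominant); zero-mean for an exact round trip
    split = amp["white"] * 0.3 * rng.standard_normal((n_ch, n))
    hbo, hbr = 0.7 * x + split, 0.3 * x - split
    hbo -= hbo.mean(axis=1, keepdims=True)
    hbr -= hbr.mean(axis=1, keepdims=True)
    hemo = HemoRecording.from_hbo_hbr(hbo, hbr, fs=cfg.fs, subject_id=subject_id)

    baseline = np.exp(rng.normal(0, 0.1, (n_ch, 2)))  # per-channel optode gains
    raw = forward_to_intensity(hemo, optics, baseline=baseline)

    # low-SNR defect: strong low-frequency multiplicative gain noise
    for ch, d in bad.items():
        if d == "low_snr":
            eta = 0.30 * _lowfreq_noise(rng, (2, n), cfg.fs, 0.4)
            raw.intensity[ch] *= 10.0 ** (-eta)
    return raw, adj, spikes


def generate_cohort(
    config: SynthConfig,
    montage: Montage | None = None,
    optics: OpticalModel | None = None,
) -> tuple[list[RawRecording], GroundTruth]:
    """Generate one RawRecording per subject plus the planted ground truth.

    Group A subjects draw denser latent coupling graphs than group B, so the
    expected global-efficiency AUC of group A exceeds group B's.  Identical
    config and seed give bit-identical cohorts.
    """
    montage = montage or default_montage()
    optics = optics or default_optics()
    rng = np.random.default_rng(config.seed)
    recordings: list[RawRecording] = []
    labels: list[str] = []
    adjacencies: list[np.ndarray] = []
    spikes_all: list[list[tuple[int, int]]] = []
    plan = [("MCS", config.latent_density_a)] * config.n_group_a + [
        ("UWS", config.latent_density_b)
    ] * config.n_group_b
    for i, (label, density) in enumerate(plan):
        sid = f"sub-{i + 1:02d}"
        raw, adj, spikes = _generate_subject(config, density, montage, optics, rng, sid)
        recordings.append(raw)
        labels.append(label)
        adjacencies.append(adj)
        spikes_all.append(spikes)
    gt = GroundTruth(
        labels=labels,
        latent_adjacency=adjacencies,
        planted_bad_channels=list(config.bad_channel_plan),
        injected_spikes=spikes_all,
    )
    return recordings, gt


# ---------------------------------------------------------------------------
# on-disk cohort layout: per-subject CSV + JSON ground truth + TOML montage

def write_cohort(
    out_dir: str | Path,
    recordings: list[RawRecording],
    gt: GroundTruth,
    montage: Montage | None = None,
    config: SynthConfig | None = None,
) -> Path:
    out = Path(out_dir)
    (out / "subjects").mkdir(parents=True, exist_ok=True)
    fs = recordings[0].fs if recordings else 11.0
    for rec in recordings:
        (out / "subjects" / f"{rec.subject_id}.csv").write_text(rec.to_csv())
    (out / "montage.toml").write_text((montage or default_montage()).to_toml())
    doc = {
        "fs": fs,
        "subjects": [r.subject_id for r in recordings],
        "labels": gt.labels,
        "planted_bad_channels": [[ch, d] for ch, d in gt.planted_bad_channels],
        "latent_edges": [
            np.argwhere(np.triu(a, 1)).tolist() for a in gt.latent_adjacency
        ],
        "injected_spikes": [[list(p) for p in s] for s in gt.injected_spikes],
    }
    (out / "ground_truth.json").write_text(json.dumps(doc))
    if config is not None:
        cfg = {k: (list(v) if isinstance(v, tuple) else v)
               for k, v in vars(config).items()}
        cfg["bad_channel_plan"] = [list(p) for p in config.bad_channel_plan]
        (out / "config.json").write_text(json.dumps(cfg, indent=1))
    return out


def read_cohort(in_dir: str | Path) -> tuple[list[RawRecording], GroundTruth]:
    src = Path(in_dir)
    doc = json.loads((src / "ground_truth.json").read_text())
    fs = float(doc["fs"])
    recordings = []
    n_ch = None
    for sid in doc["subjects"]:
        rec = RawRecording.from_csv(
            (src / "subjects" / f"{sid}.csv").read_text(), fs=fs, subject_id=sid
        )
        n_ch = rec.n_channels
        recordings.append(rec)
    adjacencies = []
    for edges in doc["latent_edges"]:
        a = np.zeros((n_ch, n_ch), dtype=bool)
        for i, j in edges:
            a[i, j] = a[j, i] = True
        adjacencies.append(a)
    gt = GroundTruth(
        labels=list(doc["labels"]),
        latent_adjacency=adjacencies,
        planted_bad_channels=[(int(c), str(d)) for c, d in doc["planted_bad_channels"]],
        injected_spikes=[[(int(c), int(s)) for c, s in subj]
                         for subj in doc["injected_spikes"]],
    )
    return recordings, gt
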