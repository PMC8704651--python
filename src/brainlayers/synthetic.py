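"""Synthetic motor-imagery EEG with planted band-limited coherent coupling.

The generator emulates the structure of a four-class motor-imagery session:
22 electrodes (10-10 system), 250 Hz sampling, 72 trials per class laid out
as consecutive paradigm trials of ``trial_spacing`` seconds in randomized
class order, with the imagery-related activity confined to an
``imagery_window`` inside each trial (cue at 2 s, imagery until 6 s in the
emulated paradigm).

Coupling model
--------------
Each :class:`Coupling` plants a shared band-limited Gaussian source: white
noise band-pass filtered to the named band (zero-phase forward-backward IIR,
so the two coupled channels stay exactly aligned), normalized to unit
standard deviation per trial, and added with weight ``strength`` to both
electrodes of the pair on top of independent background noise of standard
deviation ``noise_sd`` on every channel.  A coupling with
``class_label=None`` is active in every trial and models class-independent
background connectivity; ``strength_jitter`` redraws the weight once per
recording (uniformly within +/- jitter) to emulate between-subject /
between-session variability.

The mixing weight maps to measured band coherence through the per-bin
signal-to-noise ratio, roughly ``coh = (snr / (1 + snr))**2`` with
``snr = strength**2 * (fs/2) / (bandwidth * noise_sd**2)`` per coupled
channel pair; the mapping is characterized empirically in the test suite.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import signal

from .connectivity import BANDS

__all__ = [
    "CHANNELS_1010",
    "Coupling",
    "GroupCoupling",
    "KEY_ELECTRODES",
    "PLANTED_PAIRS",
    "SynthConfig",
    "EEGRecording",
    "default_couplings",
    "default_config",
    "generate_recording",
    "generate_dataset",
    "save_recording",
    "load_recording",
]

#: The 22-electrode 10-10 montage of the reference motor-imagery dataset.
CHANNELS_1010: tuple[str, ...] = (
    "Fz", "FC3", "FC1", "FCz", "FC2", "FC4",
    "C5", "C3", "C1", "Cz", "C2", "C4", "C6",
    "CP3", "CP1", "CPz", "CP2", "CP4",
    "P1", "Pz", "P2", "POz",
)


@dataclass(frozen=True)
class Coupling:
    """A planted coherent source between one electrode pair in one band."""

    class_label: int | None  # None = active in every class (background)
    pair: tuple[int, int]
    band: str
    strength: float
    strength_jitter: float = 0.0

    @property
    def electrodes(self) -> tuple[int, ...]:
        return self.pair


@dataclass(frozen=True)
class GroupCoupling:
    """One band-limited rhythm shared by a whole electrode group.

    Models the large-scale oscillations that make real EEG coherence dense:
    a single source is mixed into every electrode of the group, each with
    its own weight drawn once per recording from
    ``strength +/- strength_jitter`` (clipped to [0, 1]).  All within-group
    electrode pairs then share the source and show high mutual coherence,
    graded by the two weights - unlike stacking many pairwise sources on one
    channel, which dilutes every individual coherence towards zero.
    """

    class_label: int | None
    electrodes: tuple[int, ...]
    band: str
    strength: float
    strength_jitter: float = 0.0


@dataclass(frozen=True)
class SynthConfig:
    """Study-design parameters of the synthetic motor-imagery dataset."""

    n_electrodes: int = 22
    fs: float = 250.0
    trial_len: float = 2.0  # analyzed imagery window length, seconds
    trials_per_class: int = 72
    n_classes: int = 4
    n_recordings: int = 18
    couplings: tuple[Coupling, ...] = ()
    noise_sd: float = 1.0
    seed: int = 0
    trial_spacing: float = 6.0  # paradigm trial length, seconds
    imagery_window: tuple[float, float] = (3.0, 6.0)  # active source window
    channel_labels: tuple[str, ...] = CHANNELS_1010

    def __post_init__(self) -> None:
        if self.n_electrodes < 2:
            raise ValueError("need at least 2 electrodes")
        if len(self.channel_labels) != self.n_electrodes:
            object.__setattr__(
                self,
                "channel_labels",
                tuple(f"ch{i}" for i in range(self.n_electrodes))
                if self.n_electrodes != len(CHANNELS_1010)
                else CHANNELS_1010,
            )
        n_samp = self.trial_len * self.fs
        if abs(n_samp - round(n_samp)) > 1e-9:
            raise ValueError("trial_len * fs must be an integer number of samples")
        for c in self.couplings:
            if c.band not in BANDS:
                raise ValueError(
                    f"unknown band {c.band!r}; expected one of {sorted(BANDS)}"
                )
            if not 0.0 <= c.strength <= 1.0:
                raise ValueError(f"coupling strength {c.strength} outside [0, 1]")
            els = c.electrodes
            if any(not 0 <= i < self.n_electrodes for i in els):
                raise ValueError(f"coupling electrodes {els} outside montage")
            if len(set(els)) < 2:
                raise ValueError("a coupling must join at least two distinct electrodes")
            if c.class_label is not None and not (
                1 <= c.class_label <= self.n_classes
            ):
                raise ValueError(f"coupling class {c.class_label} outside 1..{self.n_classes}")
        if self.noise_sd <= 0 and not self.couplings:
            raise ValueError(
                "degenerate signal: noise_sd <= 0 with no couplings would "
                "produce an all-zero recording"
            )
        lo, hi = self.imagery_window
        if not (0 <= lo < hi <= self.trial_spacing):
            raise ValueError("imagery_window must fit inside the paradigm trial")


@dataclass
class EEGRecording:
    """A continuous multichannel recording with per-trial class markers."""

    data: np.ndarray  # (channels, samples)
    fs: float
    channel_labels: tuple[str, ...]
    events: list[tuple[int, int]]  # (onset sample, class label)
    recording_id: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_labels):
            raise ValueError("data must have one row per channel label")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def electrode_index(label: str, channel_labels: Sequence[str] = CHANNELS_1010) -> int:
    """Index of an electrode name in the montage (case-insensitive)."""
    labels = [c.lower() for c in channel_labels]
    try:
        return labels.index(label.lower())
    except ValueError as exc:
        raise KeyError(f"electrode {label!r} not in montage") from exc


#: The class-specific ground-truth electrodes of the default study.
KEY_ELECTRODES: tuple[str, ...] = ("C3", "CP2", "P2", "POz")

#: Class -> planted beta-band electrode pair of the default study.
PLANTED_PAIRS: dict[int, tuple[str, str]] = {
    1: ("C3", "CP2"),
    2: ("C3", "POz"),
    3: ("P2", "POz"),
    4: ("CP2", "P2"),
}


def default_couplings(
    planted_strength: float = 0.9,
    background_strength: float = 0.62,
    background_jitter: float = 0.42,
) -> tuple[Coupling | GroupCoupling, ...]:
    """Default planted connectivity of the synthetic study.

    Two ingredients, chosen to mimic the qualitative structure of real
    motor-imagery coherence matrices (a broad class-independent background
    of shared rhythms plus focal class-specific couplings):

    * class-independent *group rhythms* in every band: each band's
      electrodes are partitioned into groups that share one band-limited
      source, with per-electrode mixing weights redrawn every recording
      (``background_strength`` +/- ``background_jitter``).  Within-group
      coherence is high and graded by the two weights, so edge membership
      after thresholding varies between recordings - every electrode has
      within-class metric variance, as between-subject variability produces
      in real data;
    * four class-specific beta pair couplings of strength
      ``planted_strength`` among the electrodes C3, CP2, P2 and POz
      (:data:`PLANTED_PAIRS`), one pair per motor-imagery class.  These are
      the ground-truth key electrodes the statistics chain should recover.
      In the beta band the key electrodes form their own background group
      (slightly weaker, so the planted source dominates their spectra).
    """
    e = electrode_index
    cps: list[Coupling | GroupCoupling] = []
    for cls, (a, b) in PLANTED_PAIRS.items():
        cps.append(Coupling(cls, (e(a), e(b)), "beta", planted_strength, 0.05))
    key = tuple(e(name) for name in KEY_ELECTRODES)
    rest = tuple(i for i in range(len(CHANNELS_1010)) if i not in key)
    # beta: three chained 7-electrode background groups over the non-key
    # electrodes (consecutive groups share one member so the layer stays
    # connected) plus a weaker group over the key electrodes bridged into
    # the background - weaker so the planted source dominates their spectra
    beta_groups = [rest[0:7], rest[6:13], rest[12:18] + (rest[0],)]
    for grp in beta_groups:
        cps.append(GroupCoupling(None, grp, "beta", background_strength, background_jitter))
    cps.append(GroupCoupling(None, key + (rest[3], rest[9]), "beta", 0.55, 0.15))
    # other-band rhythms: chained groups over stride-permuted electrode
    # orders, so every electrode carries activity in every band and each
    # band layer is connected (band-limited sources do not leak into other
    # bands' coherence)
    n = len(CHANNELS_1010)
    for band, stride in (("alpha", 5), ("theta", 3), ("delta", 7)):
        order = [(stride * i) % n for i in range(n)]
        for grp in _chained_groups(order, 7):
            cps.append(
                GroupCoupling(None, grp, band, background_strength, background_jitter)
            )
    return tuple(cps)


def _chained_groups(members: Sequence[int], size: int) -> list[tuple[int, ...]]:
    """Cover ``members`` with groups of ``size`` where consecutive groups
    share one member and the last wraps to the first (connected chain)."""
    groups = []
    step = size - 1
    for start in range(0, len(members) - 1, step):
        grp = list(members[start : start + size])
        if start + size >= len(members):
            grp = list(members[start:]) + [members[0]]
        groups.append(tuple(dict.fromkeys(grp)))
    return [g for g in groups if len(g) >= 2]


def default_config(seed: int = 0, **overrides) -> SynthConfig:
    """The default synthetic study: 18 recordings, 4 classes, 72 trials/class."""
    kw = dict(couplings=default_couplings(), seed=seed)
    kw.update(overrides)
    return SynthConfig(**kw)


def _band_sos(band: str, fs: float):
    lo, hi = BANDS[band]
    return signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")


def generate_recording(cfg: SynthConfig, recording_index: int) -> EEGRecording:
    """Generate one recording of the synthetic study.

    Deterministic given ``(cfg.seed, recording_index)``.  The event list
    contains ``trials_per_class * n_classes`` events in a randomized class
    order drawn from the recording's own RNG stream.
    """
    if not 0 <= recording_index < cfg.n_recordings:
        raise ValueError(
            f"recording_index {recording_index} outside 0..{cfg.n_recordings - 1}"
        )
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), recording_index]))
    fs = cfg.fs
    n_trials = cfg.trials_per_class * cfg.n_classes
    spacing = int(round(cfg.trial_spacing * fs))
    n_samples = n_trials * spacing

    classes = np.repeat(np.arange(1, cfg.n_classes + 1), cfg.trials_per_class)
    rng.shuffle(classes)
    onsets = np.arange(n_trials) * spacing

    data = cfg.noise_sd * rng.standard_normal((cfg.n_electrodes, n_samples))

    a0 = int(round(cfg.imagery_window[0] * fs))
    a1 = int(round(cfg.imagery_window[1] * fs))
    seg = a1 - a0
    sos_cache = {}
    for c in cfg.couplings:
        els = c.electrodes
        if isinstance(c, GroupCoupling):
            # one mixing weight per electrode, redrawn per recording
            weights = c.strength + rng.uniform(
                -c.strength_jitter, c.strength_jitter, size=len(els)
            )
        else:
            # pair coupling: both electrodes share one (jittered) weight
            w = c.strength + (
                rng.uniform(-c.strength_jitter, c.strength_jitter)
                if c.strength_jitter
                else 0.0
            )
            weights = np.full(len(els), w)
        weights = np.clip(weights, 0.0, 1.0)
        if c.class_label is None:
            active = np.arange(n_trials)
        else:
            active = np.flatnonzero(classes == c.class_label)
        if active.size == 0 or not weights.any():
            continue
        if c.band not in sos_cache:
            sos_cache[c.band] = _band_sos(c.band, fs)
        src = rng.standard_normal((active.size, seg))
        src = signal.sosfiltfilt(sos_cache[c.band], src, axis=-1)
        sd = src.std(axis=-1, keepdims=True)
        sd[sd == 0] = 1.0
        src = src / sd
        for k, t in enumerate(active):
            sl = slice(onsets[t] + a0, onsets[t] + a1)
            for i, w in zip(els, weights):
                data[i, sl] += w * src[k]

    events = [(int(o), int(c)) for o, c in zip(onsets, classes)]
    return EEGRecording(
        data=data,
        fs=fs,
        channel_labels=cfg.channel_labels,
        events=events,
        recording_id=recording_index,
    )


def generate_dataset(cfg: SynthConfig):
    """Yield every recording of the study in order (memory-friendly)."""
    for r in range(cfg.n_recordings):
        yield generate_recording(cfg, r)


def save_recording(rec: EEGRecording, path: str | Path) -> Path:
    """Serialize a recording to a compressed array container (.npz).

    A plain-text TSV sidecar ``<stem>.events.tsv`` with columns
    ``onset_sample`` and ``class`` is written next to it.
    """
    path = Path(path).with_suffix(".npz")
    events = np.asarray(rec.events, dtype=np.int64).reshape(-1, 2)
    np.savez_compressed(
        path,
        data=rec.data,
        fs=np.asarray(rec.fs),
        channel_labels=np.asarray(rec.channel_labels),
        events=events,
        recording_id=np.asarray(-1 if rec.recording_id is None else rec.recording_id),
    )
    sidecar = path.with_suffix("").with_suffix(".events.tsv")
    with open(sidecar, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["onset_sample", "class"])
        w.writerows(rec.events)
    return path


def load_recording(path: str | Path) -> EEGRecording:
    """Read a recording written by :func:`save_recording`."""
    with np.load(Path(path), allow_pickle=False) as z:
        rid = int(z["recording_id"])
        return EEGRecording(
            data=z["data"],
            fs=float(z["fs"]),
            channel_labels=tuple(str(c) for c in z["channel_labels"]),
            events=[(int(o), int(c)) for o, c in z["events"]],
            recording_id=None if rid < 0 else rid,
        )
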