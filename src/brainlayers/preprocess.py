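"""Common Average Reference filtering and epoching of the imagery window.

The CAR filter removes the spatial mean at every sample,

    V_i^CAR(t) = V_i^CR(t) - (1/N) sum_j V_j^CR(t),

where ``V_i^CR`` is the potential of electrode *i* against the common
recording reference and N is the number of electrodes.  It is a linear,
idempotent projection; after CAR the instantaneous sum over channels is
zero.

Epoching slices the analyzed imagery window - by default t = 3.5-5.5 s
relative to each trial onset - out of the continuous recording, grouped by
motor-imagery class.  Windows are half-open ``[start, end)`` in seconds so a
2-s window at 250 Hz is exactly 500 samples; epoching is pure slicing and
never resamples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["TrialSet", "car_filter", "epoch", "read_raw_eeg", "DEFAULT_WINDOW"]

DEFAULT_WINDOW: tuple[float, float] = (3.5, 5.5)


@dataclass
class TrialSet:
    """Epoched trials of a single motor-imagery class."""

    trials: np.ndarray  # (n_trials, channels, samples)
    fs: float
    class_label: int
    window: tuple[float, float] = DEFAULT_WINDOW
    channel_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.trials = np.asarray(self.trials, dtype=float)
        if self.trials.ndim != 3:
            raise ValueError("trials must have shape (n_trials, channels, samples)")
        expected = round((self.window[1] - self.window[0]) * self.fs)
        if self.trials.shape[0] and self.trials.shape[2] != expected:
            raise ValueError(
                f"window {self.window} at fs={self.fs} implies {expected} samples, "
                f"got {self.trials.shape[2]}"
            )

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]


def read_raw_eeg(path, event_id: dict | None = None):
    """Optional GDF/EDF ingestion behind the EEGRecording contract.

    Reads a raw file with MNE (an optional dependency; only needed when
    analyzing real recordings rather than the synthetic study) and returns
    an :class:`~brainlayers.synthetic.EEGRecording` with annotation onsets
    mapped to class labels through ``event_id``.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional path
        raise ImportError(
            "reading GDF/EDF files requires the optional 'mne' package"
        ) from exc
    from .synthetic import EEGRecording

    raw = mne.io.read_raw(str(path), preload=True, verbose="error")
    events, found = mne.events_from_annotations(raw, event_id=event_id,
                                                verbose="error")
    return EEGRecording(
        data=raw.get_data(),
        fs=float(raw.info["sfreq"]),
        channel_labels=tuple(raw.ch_names),
        events=[(int(s), int(c)) for s, _, c in events],
    )


def car_filter(data: np.ndarray) -> np.ndarray:
    """Subtract the instantaneous channel mean from every channel.

    Parameters
    ----------
    data : ndarray, shape (channels, samples)

    Raises
    ------
    ValueError
        For single-channel input, where CAR would return identically zero.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a (channels, samples) matrix")
    if x.shape[0] < 2:
        raise ValueError("CAR needs at least 2 channels (1-channel CAR is zero)")
    return x - x.mean(axis=0, keepdims=True)


def epoch(
    recording,
    window: tuple[float, float] = DEFAULT_WINDOW,
    classes: Sequence[int] | None = None,
) -> list[TrialSet]:
    """Slice the analysis window out of every trial, grouped by class.

    Parameters
    ----------
    recording : EEGRecording
        Continuous data with an ``events`` list of ``(onset_sample, class)``.
    window : (start, end) seconds relative to trial onset, half-open.
    classes : class universe; defaults to the four motor-imagery classes
        ``(1, 2, 3, 4)`` so classes with no events still yield an empty
        TrialSet.

    Returns
    -------
    list of TrialSet, one per class in ``classes`` order.
    """
    fs = recording.fs
    start, end = window
    if end <= start:
        raise ValueError("window end must exceed window start")
    i0 = int(round(start * fs))
    i1 = int(round(end * fs))
    if classes is None:
        classes = (1, 2, 3, 4)
    if not recording.events:
        warnings.warn("recording has no events; returning empty trial sets")
    n_samples = recording.data.shape[1]
    for onset, cls in recording.events:
        if onset + i0 < 0 or onset + i1 > n_samples:
            raise ValueError(
                f"event (onset={onset}, class={cls}): window "
                f"[{onset + i0}, {onset + i1}) exceeds recording bounds "
                f"[0, {n_samples})"
            )
    ch_labels = tuple(recording.channel_labels)
    out = []
    for cls in classes:
        segs = [
            recording.data[:, onset + i0 : onset + i1]
            for onset, c in recording.events
            if c == cls
        ]
        trials = (
            np.stack(segs)
            if segs
            else np.empty((0, recording.data.shape[0], i1 - i0))
        )
        out.append(
            TrialSet(
                trials=trials,
                fs=fs,
                class_label=cls,
                window=(start, end),
                channel_labels=ch_labels,
            )
        )
    return out
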