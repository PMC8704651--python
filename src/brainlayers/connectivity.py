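"""Trial-averaged magnitude-squared coherence and band-wise adjacency layers.

Functional connectivity between electrode pairs is estimated as

    C_xy(f) = |S_xy(f)|^2 / (S_xx(f) S_yy(f)),

where ``S_xy`` is the cross-power spectrum averaged over trials and ``S_xx``,
``S_yy`` are the trial-averaged auto-spectra.  Coherence from a single segment
is identically one, so both cross- and auto-spectra are averaged over the
trials of one motor-imagery class before the ratio is formed; with K
independent segments the estimator has a well known positive bias of about
1/K for incoherent signals, which sets the noise floor of the adjacency
matrices.

The per-frequency coherence tensor is collapsed into one symmetric
channels x channels adjacency matrix per electrophysiological band (the
"layers" of the multilayer model) by averaging the coherence magnitude over
the frequency bins that fall inside each band.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import signal

__all__ = [
    "BANDS",
    "BAND_ORDER",
    "SpectralEstimate",
    "BandLayer",
    "LayerStack",
    "cross_spectra",
    "coherence",
    "band_layers",
]

#: Electrophysiological bands in Hz, half-open intervals [f_lo, f_hi).
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}

#: Canonical layer order used throughout the package.
BAND_ORDER: tuple[str, ...] = tuple(BANDS)


@dataclass
class SpectralEstimate:
    """Trial-averaged cross-spectral density matrix.

    Attributes
    ----------
    csd : complex ndarray, shape (channels, channels, n_freqs)
        ``csd[i, j, f]`` is the average over trials of ``X_i(f) conj(X_j(f))``
        where ``X_i`` is the tapered DFT of channel ``i``.  Hermitian in the
        channel indices; the diagonal is real and non-negative.
    freqs : ndarray, shape (n_freqs,)
        Frequency grid in Hz, from 0 to the Nyquist frequency.
    """

    csd: np.ndarray
    freqs: np.ndarray

    @property
    def n_channels(self) -> int:
        return self.csd.shape[0]


@dataclass
class BandLayer:
    """One band-averaged coherence adjacency matrix (a network layer).

    ``matrix`` is symmetric with entries in [0, 1] and a unit diagonal
    (self-coherence).
    """

    matrix: np.ndarray
    band: str
    f_lo: float
    f_hi: float
    class_label: int | None = None
    recording_id: int | None = None
    channel_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("BandLayer.matrix must be square")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("BandLayer.matrix must be symmetric")
        if m.min() < -1e-10 or m.max() > 1 + 1e-10:
            raise ValueError("BandLayer entries must lie in [0, 1]")
        if not np.allclose(np.diag(m), 1.0, atol=1e-8):
            raise ValueError("BandLayer diagonal must be 1 (self-coherence)")
        self.matrix = m

    def to_frame(self):
        """Adjacency as a DataFrame with electrode names as index/columns
        (CSV-ready: ``layer.to_frame().to_csv(path)``)."""
        import pandas as pd

        labels = self.channel_labels or tuple(
            f"ch{i}" for i in range(self.matrix.shape[0])
        )
        return pd.DataFrame(self.matrix, index=labels, columns=labels)


@dataclass
class LayerStack:
    """Ordered band layers for one (recording, class) pair."""

    layers: list[BandLayer]
    class_label: int | None = None
    recording_id: int | None = None

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("LayerStack needs at least one layer")
        n = self.layers[0].matrix.shape[0]
        if any(l.matrix.shape[0] != n for l in self.layers):
            raise ValueError("all layers must share the channel ordering")

    @property
    def band_names(self) -> tuple[str, ...]:
        return tuple(l.band for l in self.layers)

    def __getitem__(self, band: str) -> BandLayer:
        for l in self.layers:
            if l.band == band:
                return l
        raise KeyError(band)


def cross_spectra(
    trials,
    *,
    taper: str = "hann",
    detrend: str | None = "linear",
) -> SpectralEstimate:
    """Trial-averaged cross-spectral density of a set of epochs.

    Each trial is one Welch segment: optionally linearly detrended, tapered,
    Fourier transformed, and the outer products ``X_i conj(X_j)`` averaged
    over trials.  No intra-trial sub-segmentation is applied, so a 2-s trial
    at 250 Hz yields a 0.5 Hz frequency resolution.

    Parameters
    ----------
    trials : TrialSet or ndarray, shape (n_trials, channels, samples)
    taper : window name passed to :func:`scipy.signal.get_window`, or None.
    detrend : "linear", "constant" or None.

    Raises
    ------
    ValueError
        If fewer than two trials are supplied: coherence estimated from a
        single segment is identically one and carries no information.
    """
    x, fs = _trials_array(trials)
    k, n_ch, n_s = x.shape
    if k < 2:
        raise ValueError(
            "cross_spectra needs at least 2 trials: single-segment coherence "
            "is identically 1 (the estimator only becomes informative after "
            "averaging cross-spectra over trials)"
        )
    if detrend is not None:
        x = signal.detrend(x, axis=-1, type=detrend)
    if taper is not None:
        win = signal.get_window(taper, n_s, fftbins=True)
        x = x * win
    X = np.fft.rfft(x, axis=-1)
    # csd[i, j, f] = mean_k X[k, i, f] * conj(X[k, j, f])
    csd = np.einsum("kif,kjf->ijf", X, np.conj(X)) / k
    freqs = np.fft.rfftfreq(n_s, d=1.0 / fs)
    return SpectralEstimate(csd=csd, freqs=freqs)


def coherence(spec: SpectralEstimate) -> np.ndarray:
    """Magnitude-squared coherence tensor from a spectral estimate.

    Returns ``C`` with ``C[i, j, f] = |S_ij|^2 / (S_ii S_jj)``, clipped to
    [0, 1] against rounding and with the self-coherence diagonal set to 1.
    """
    csd = spec.csd
    auto = np.real(np.einsum("iif->if", csd))  # (channels, n_freqs)
    if np.any(auto <= 0):
        bad = np.argwhere(auto <= 0)[0]
        raise ValueError(
            f"auto-spectrum of channel {bad[0]} is non-positive at frequency "
            f"{spec.freqs[bad[1]]:g} Hz; coherence is undefined there"
        )
    denom = auto[:, None, :] * auto[None, :, :]
    C = np.abs(csd) ** 2 / denom
    C = np.clip(C, 0.0, 1.0)
    idx = np.arange(C.shape[0])
    C[idx, idx, :] = 1.0
    return C


def band_layers(
    C: np.ndarray,
    freqs: np.ndarray,
    bands: Mapping[str, tuple[float, float]] = BANDS,
    *,
    class_label: int | None = None,
    recording_id: int | None = None,
    channel_labels: Sequence[str] | None = None,
) -> LayerStack:
    """Average a coherence tensor over each band's frequency bins.

    Bands are half-open intervals ``[f_lo, f_hi)`` so adjacent bands never
    share an edge bin; the DC bin is always excluded.
    """
    freqs = np.asarray(freqs, dtype=float)
    layers = []
    for name, (lo, hi) in bands.items():
        mask = (freqs >= lo) & (freqs < hi) & (freqs > 0)
        if not mask.any():
            raise ValueError(
                f"band {name!r} = [{lo}, {hi}) Hz contains no grid frequency "
                f"(resolution {freqs[1] - freqs[0]:g} Hz)"
            )
        m = C[:, :, mask].mean(axis=-1)
        m = 0.5 * (m + m.T)  # enforce exact symmetry against rounding
        np.fill_diagonal(m, 1.0)
        layers.append(
            BandLayer(
                matrix=m,
                band=name,
                f_lo=lo,
                f_hi=hi,
                class_label=class_label,
                recording_id=recording_id,
                channel_labels=tuple(channel_labels) if channel_labels else None,
            )
        )
    return LayerStack(layers=layers, class_label=class_label, recording_id=recording_id)


def _trials_array(trials) -> tuple[np.ndarray, float]:
    """Accept a TrialSet or a bare (trials, channels, samples) array."""
    fs = getattr(trials, "fs", None)
    data = getattr(trials, "trials", trials)
    x = np.asarray(data, dtype=float)
    if x.ndim != 3:
        raise ValueError("expected trials with shape (n_trials, channels, samples)")
    return x, float(fs) if fs is not None else 1.0
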