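"""Preprocessing, spectral estimation and individualized frequency bands.

The stages here standardize a recording to the common analysis format
(256 Hz, 0.1-45 Hz band, common average reference), cut it into 2-s epochs,
screen epochs with amplitude/variance/EMG-proxy criteria, estimate Welch
power spectra at 0.5 Hz resolution, locate the per-subject frequency
landmarks (transition frequency TF, individual alpha frequency IAF) and
derive the individualized eight-band scheme

    delta  = [TF-4, TF-2)        beta1 = [14, 20)
    theta  = [TF-2, TF)          beta2 = [20, 30)
    alpha1 = [TF, (TF+IAF)/2)    gamma = [30, 40)
    alpha2 = [(TF+IAF)/2, IAF)
    alpha3 = [IAF, IAF+2)

TF is the spectral power minimum in 3-8 Hz and IAF the maximum power peak in
6-14 Hz, both read off the channel-mean spectrum on the 0.5 Hz grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal

from .recording import Recording

TARGET_FS = 256.0
BAND_EDGES_HZ = (0.1, 45.0)
EPOCH_LENGTH_S = 2.0
GRID_STEP_HZ = 0.5
GRID_RANGE_HZ = (0.5, 45.0)
TF_RANGE_HZ = (3.0, 8.0)
IAF_RANGE_HZ = (6.0, 14.0)

BAND_NAMES = ("delta", "theta", "alpha1", "alpha2", "alpha3",
              "beta1", "beta2", "gamma")


@dataclass
class Epochs:
    subject_id: str
    data: np.ndarray            # n_epochs x channels x samples
    fs: float
    epoch_length: float
    channel_labels: tuple = ()
    kept_mask: np.ndarray = None  # over the epochs of the *original* split

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("epoch array must be 3-D")
        n_samp = int(round(self.fs * self.epoch_length))
        if self.data.shape[2] != n_samp:
            raise ValueError("samples per epoch must equal fs * epoch_length")
        if self.kept_mask is None:
            self.kept_mask = np.ones(self.data.shape[0], dtype=bool)
        self.kept_mask = np.asarray(self.kept_mask, dtype=bool)

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def kept_fraction(self) -> float:
        return self.n_epochs / max(len(self.kept_mask), 1)


@dataclass
class PowerSpectrum:
    subject_id: str
    freqs: np.ndarray           # Hz, 0.5 Hz spacing over [0.5, 45]
    psd: np.ndarray             # channels x bins, uV^2/Hz
    channel_labels: tuple = ()

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.psd = np.asarray(self.psd, dtype=float)
        step = np.diff(self.freqs)
        if len(step) and not np.allclose(step, GRID_STEP_HZ):
            raise ValueError("frequency grid spacing must be exactly 0.5 Hz")
        if np.any(self.psd < 0):
            raise ValueError("negative power density")

    @property
    def global_psd(self) -> np.ndarray:
        return self.psd.mean(axis=0)


@dataclass
class FrequencyLandmarks:
    subject_id: str
    tf: float
    iaf: float
    flags: frozenset = frozenset()

    @property
    def valid(self) -> bool:
        return "invalid" not in self.flags


@dataclass
class BandScheme:
    """Ordered mapping band name -> [low, high) in Hz."""
    edges: dict
    flags: frozenset = frozenset()

    def __post_init__(self):
        if tuple(self.edges) != BAND_NAMES:
            raise ValueError(f"bands must be exactly {BAND_NAMES}")
        for name, (lo, hi) in self.edges.items():
            if not hi > lo:
                raise ValueError(f"band {name} has non-positive width")

    def __getitem__(self, name):
        return self.edges[name]

    def bin_mask(self, freqs: np.ndarray, name: str) -> np.ndarray:
        lo, hi = self.edges[name]
        freqs = np.asarray(freqs)
        return (freqs >= lo - 1e-9) & (freqs < hi - 1e-9)


# ---------------------------------------------------------------------------
# operations

def standardize_recording(recording: Recording) -> Recording:
    """Resample to 256 Hz, band-pass 0.1-45 Hz (zero phase), re-reference to
    the common average."""
    if recording.fs < TARGET_FS - 1e-9:
        raise ValueError(
            f"sampling rate {recording.fs} Hz below the 256 Hz minimum standard"
        )
    if recording.n_channels < 2:
        raise ValueError("need at least 2 channels for common average reference")
    data = recording.data
    if abs(recording.fs - TARGET_FS) > 1e-9:
        frac = Fraction(int(round(TARGET_FS * 1000)),
                        int(round(recording.fs * 1000)))
        data = signal.resample_poly(data, frac.numerator, frac.denominator,
                                    axis=1)
    # zero-phase band-pass applied as the Butterworth forward-backward
    # power response in the frequency domain: the 0.1 Hz corner's impulse
    # response is longer than typical recordings, so time-domain filtering
    # would be dominated by edge transients
    lo, hi = BAND_EDGES_HZ
    data = data - data.mean(axis=1, keepdims=True)
    freqs = np.fft.rfftfreq(data.shape[1], 1.0 / TARGET_FS)
    with np.errstate(divide="ignore"):
        r_hp = np.where(freqs > 0,
                        (freqs / lo) ** 4 / (1.0 + (freqs / lo) ** 4), 0.0)
    r_lp = 1.0 / (1.0 + (freqs / hi) ** 20)
    data = np.fft.irfft(np.fft.rfft(data, axis=1) * (r_hp * r_lp),
                        n=data.shape[1], axis=1)
    data = data - data.mean(axis=0, keepdims=True)
    return Recording(recording.subject_id, recording.channel_labels, TARGET_FS,
                     data, recording.provenance, recording.ground_truth,
                     dict(recording.meta, standardized=True))


def epoch_recording(recording: Recording,
                    epoch_length: float = EPOCH_LENGTH_S) -> Epochs:
    """Split into consecutive non-overlapping epochs; drop the partial tail."""
    n_samp = int(round(recording.fs * epoch_length))
    n_ep = recording.data.shape[1] // n_samp
    if n_ep < 1:
        raise ValueError(
            f"recording of {recording.duration:.2f} s shorter than one "
            f"{epoch_length} s epoch"
        )
    cut = recording.data[:, : n_ep * n_samp]
    data = cut.reshape(recording.n_channels, n_ep, n_samp).transpose(1, 0, 2)
    return Epochs(recording.subject_id, data, recording.fs, epoch_length,
                  recording.channel_labels)


@dataclass
class RejectionCriteria:
    """Epoch screening thresholds (programmatic proxy for expert scoring).

    amp_max_uv       peak-to-peak ceiling on any channel
    var_z_max        |z| ceiling on per-epoch broadband variance
    emg_ratio_max    ceiling on the 30-45 Hz / 1-30 Hz power ratio; None means
                     2x the recording-median ratio
    """
    amp_max_uv: float = 100.0
    var_z_max: float = 3.0
    emg_ratio_max: float | None = None
    warn_kept_fraction: float = 0.75


def _epoch_band_power(data: np.ndarray, fs: float, lo: float, hi: float):
    """Mean power of each epoch in [lo, hi] Hz (mean over channels)."""
    n = data.shape[2]
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    spec = np.abs(np.fft.rfft(data, axis=2)) ** 2
    m = (freqs >= lo) & (freqs <= hi)
    return spec[:, :, m].mean(axis=(1, 2))


def reject_epochs(epochs: Epochs,
                  criteria: RejectionCriteria | None = None) -> Epochs:
    """Drop epochs failing amplitude, variance or EMG-ratio screening."""
    if criteria is None:
        criteria = RejectionCriteria()
    if epochs.n_epochs < 1:
        raise ValueError("no epochs to screen")
    data = epochs.data
    n_ep = epochs.n_epochs

    ptp = data.max(axis=2) - data.min(axis=2)          # epochs x channels
    bad_amp = (ptp > criteria.amp_max_uv).any(axis=1)

    var = data.var(axis=2).mean(axis=1)
    sd = var.std()
    z = (var - var.mean()) / sd if sd > 0 else np.zeros(n_ep)
    bad_var = np.abs(z) > criteria.var_z_max

    hi_p = _epoch_band_power(data, epochs.fs, 30.0, 45.0)
    lo_p = _epoch_band_power(data, epochs.fs, 1.0, 30.0)
    ratio = hi_p / np.maximum(lo_p, 1e-30)
    thr = criteria.emg_ratio_max
    if thr is None:
        thr = 2.0 * np.median(ratio)
    bad_emg = ratio > thr

    keep = ~(bad_amp | bad_var | bad_emg)
    if not keep.any():
        counts = {"amplitude": int(bad_amp.sum()),
                  "variance": int(bad_var.sum()),
                  "emg-ratio": int(bad_emg.sum())}
        worst = max(counts, key=counts.get)
        raise ValueError(
            f"all {n_ep} epochs rejected (dominating criterion: {worst}, "
            f"counts {counts})"
        )
    frac = keep.mean()
    if frac < criteria.warn_kept_fraction:
        warnings.warn(
            f"{epochs.subject_id}: kept epoch fraction {frac:.2f} below "
            f"{criteria.warn_kept_fraction}", RuntimeWarning, stacklevel=2)
    return Epochs(epochs.subject_id, data[keep], epochs.fs,
                  epochs.epoch_length, epochs.channel_labels, kept_mask=keep)


def welch_psd(epochs: Epochs) -> PowerSpectrum:
    """Welch PSD: Hann-windowed periodogram of each full epoch, averaged.

    Each 2-s epoch is one Welch segment, giving exactly 0.5 Hz resolution at
    256 Hz; the grid is restricted to [0.5, 45] Hz.
    """
    if epochs.n_epochs < 1:
        raise ValueError("no epochs")
    df = 1.0 / epochs.epoch_length
    if abs(df - GRID_STEP_HZ) > 1e-12:
        raise ValueError(
            f"epoch length {epochs.epoch_length} s gives {df} Hz resolution, "
            f"not the required {GRID_STEP_HZ} Hz"
        )
    n = epochs.data.shape[2]
    win = signal.get_window("hann", n)
    scale = 2.0 / (epochs.fs * (win ** 2).sum())
    spec = np.abs(np.fft.rfft(epochs.data * win, axis=2)) ** 2 * scale
    freqs = np.fft.rfftfreq(n, 1.0 / epochs.fs)
    psd = spec.mean(axis=0)                     # channels x bins
    m = (freqs >= GRID_RANGE_HZ[0] - 1e-9) & (freqs <= GRID_RANGE_HZ[1] + 1e-9)
    return PowerSpectrum(epochs.subject_id, freqs[m], psd[:, m],
                         epochs.channel_labels)


def detect_landmarks(spectrum: PowerSpectrum,
                     channel_subset=None) -> FrequencyLandmarks:
    """Locate TF (power minimum in 3-8 Hz) and IAF (maximum power peak in
    6-14 Hz) on the channel-mean spectrum.

    ``channel_subset`` restricts the mean to named channels (e.g. a posterior
    subset); default is all channels.
    """
    if channel_subset is None:
        g = spectrum.global_psd
    else:
        lower = [c.lower() for c in spectrum.channel_labels]
        idx = []
        for ch in channel_subset:
            try:
                idx.append(lower.index(ch.lower()))
            except ValueError:
                raise ValueError(f"channel {ch!r} not in spectrum") from None
        g = spectrum.psd[idx].mean(axis=0)
    if not np.all(np.isfinite(g)):
        raise ValueError("non-finite spectrum")
    f = spectrum.freqs
    flags = set()

    m_tf = (f >= TF_RANGE_HZ[0] - 1e-9) & (f <= TF_RANGE_HZ[1] + 1e-9)
    if not m_tf.any():
        raise ValueError("grid does not cover the 3-8 Hz TF search range")
    i_tf = np.flatnonzero(m_tf)
    tf = float(f[i_tf[np.argmin(g[i_tf])]])
    if tf in (f[i_tf[0]], f[i_tf[-1]]):
        flags.add("tf-boundary-hit")

    m_iaf = (f >= IAF_RANGE_HZ[0] - 1e-9) & (f <= IAF_RANGE_HZ[1] + 1e-9)
    if not m_iaf.any():
        raise ValueError("grid does not cover the 6-14 Hz IAF search range")
    i_iaf = np.flatnonzero(m_iaf)
    peaks, _ = signal.find_peaks(g)
    peaks = peaks[np.isin(peaks, i_iaf)]
    if len(peaks):
        iaf = float(f[peaks[np.argmax(g[peaks])]])
    else:
        iaf = float(f[i_iaf[np.argmax(g[i_iaf])]])
        flags.add("no-peak")
    if iaf in (f[i_iaf[0]], f[i_iaf[-1]]):
        flags.add("iaf-boundary-hit")

    if tf >= iaf:
        flags.add("invalid")
    return FrequencyLandmarks(spectrum.subject_id, tf, iaf, frozenset(flags))


def individual_band_scheme(landmarks: FrequencyLandmarks) -> BandScheme:
    """Build the per-subject eight-band scheme from TF and IAF."""
    tf, iaf = landmarks.tf, landmarks.iaf
    if not tf < iaf:
        raise ValueError(f"tf={tf} >= iaf={iaf}: no valid alpha partition")
    flags = set()
    delta_lo = tf - 4.0
    if delta_lo < GRID_RANGE_HZ[0]:
        delta_lo = GRID_RANGE_HZ[0]
        flags.add("delta-low-clipped")
    mid = (tf + iaf) / 2.0
    edges = {
        "delta": (delta_lo, tf - 2.0),
        "theta": (tf - 2.0, tf),
        "alpha1": (tf, mid),
        "alpha2": (mid, iaf),
        "alpha3": (iaf, iaf + 2.0),
        "beta1": (14.0, 20.0),
        "beta2": (20.0, 30.0),
        "gamma": (30.0, 40.0),
    }
    return BandScheme(edges, frozenset(flags))


# ---------------------------------------------------------------------------
# tidy exports

def psd_frame(spectrum: PowerSpectrum) -> pd.DataFrame:
    rows = []
    labels = spectrum.channel_labels or tuple(
        f"ch{i}" for i in range(spectrum.psd.shape[0]))
    for ci, ch in enumerate(labels):
        rows.append(pd.DataFrame({
            "subject_id": spectrum.subject_id, "channel": ch,
            "frequency": spectrum.freqs, "psd": spectrum.psd[ci]}))
    rows.append(pd.DataFrame({
        "subject_id": spectrum.subject_id, "channel": "global",
        "frequency": spectrum.freqs, "psd": spectrum.global_psd}))
    return pd.concat(rows, ignore_index=True)


def landmarks_frame(landmarks_list) -> pd.DataFrame:
    return pd.DataFrame([
        {"subject_id": lm.subject_id, "tf": lm.tf, "iaf": lm.iaf,
         "flags": ";".join(sorted(lm.flags))} for lm in landmarks_list])
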