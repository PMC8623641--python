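"""Multichannel EEG containers, EDF/matrix input, epoching and band filtering.

The processing convention mirrors standard resting-state EEG pipelines:
continuous recordings are cut into fixed-length artifact-screened epochs and
band-pass filtered into the four canonical rhythms (delta 1-4 Hz, theta
4-8 Hz, alpha 8-12 Hz, beta 12-30 Hz) with a third-order Butterworth filter.
Filtering is zero-phase by default (forward-backward application of the
order-3 prototype) so that phase-based coupling measures downstream are not
biased by the filter's group delay; a single-pass mode is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

__all__ = [
    "EEGRecording",
    "BandDefinition",
    "CANONICAL_BANDS",
    "ArtifactRejected",
    "read_edf",
    "read_matrix",
    "extract_epoch",
    "bandpass",
]


class ArtifactRejected(Exception):
    """Raised when an epoch violates the amplitude guard.

    Carries the offending channels and the peak absolute amplitude so the
    rejection is an explicit, inspectable event rather than a silent drop.
    """

    def __init__(self, channels: list[str], peak_uv: float, guard_uv: float):
        self.channels = channels
        self.peak_uv = peak_uv
        self.guard_uv = guard_uv
        super().__init__(
            f"epoch rejected: |amplitude| {peak_uv:.1f} uV exceeds guard "
            f"{guard_uv:.1f} uV on channels {channels}"
        )


@dataclass(frozen=True)
class BandDefinition:
    """A frequency band [f_lo, f_hi] in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self):
        if not 0 < self.f_lo < self.f_hi:
            raise ValueError(f"invalid band {self.name}: ({self.f_lo}, {self.f_hi})")


#: The four canonical EEG rhythms.
CANONICAL_BANDS: dict[str, BandDefinition] = {
    "delta": BandDefinition("delta", 1.0, 4.0),
    "theta": BandDefinition("theta", 4.0, 8.0),
    "alpha": BandDefinition("alpha", 8.0, 12.0),
    "beta": BandDefinition("beta", 12.0, 30.0),
}


@dataclass
class EEGRecording:
    """A channels x samples EEG matrix in microvolts with its sampling rate.

    Channel labels follow the 10-20 system (Fp1, T6, CPz, ...).
    """

    subject_id: str
    channel_labels: list[str]
    data: np.ndarray  # (n_channels, n_samples), microvolts
    fs: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples matrix")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains NaN or Inf")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("number of labels does not match number of channels")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            dupes = sorted(
                {l for l in self.channel_labels if self.channel_labels.count(l) > 1}
            )
            raise ValueError(f"duplicate channel labels: {dupes}")
        if self.n_channels < 2:
            raise ValueError("at least 2 channels are required")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.channel_labels.index(label)]


def read_edf(path, subject_id: str | None = None) -> EEGRecording:
    """Read an EDF file into an :class:`EEGRecording` (data in microvolts).

    All channels must share one sampling rate; mixed-rate files are rejected
    with an error naming the offending channels.
    """
    import mne

    # Pre-scan the EDF header: mne silently renames duplicate labels and can
    # resample mixed-rate channels, so both invariants are checked on the
    # raw header before delegating the decoding.
    with open(path, "rb") as fh:
        hdr = fh.read(256)
        if len(hdr) < 256:
            raise ValueError(f"not a valid EDF file: {path}")
        ns = int(hdr[252:256].decode("ascii", "replace"))
        sig = fh.read(256 * ns)
    labels = [
        sig[16 * k : 16 * (k + 1)].decode("ascii", "replace").strip()
        for k in range(ns)
    ]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate channel labels in EDF header: {dupes}")
    ns_off = ns * (16 + 80 + 8 + 8 + 8 + 8 + 8 + 80)
    n_samps = [
        int(sig[ns_off + 8 * k : ns_off + 8 * (k + 1)].decode("ascii", "replace"))
        for k in range(ns)
    ]
    if len(set(n_samps)) > 1:
        by_rate: dict[int, list[str]] = {}
        for lab, r in zip(labels, n_samps):
            by_rate.setdefault(int(r), []).append(lab)
        raise ValueError(f"mixed sampling rates across channels: {by_rate}")

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data_uv = raw.get_data() * 1e6  # mne returns volts
    return EEGRecording(
        subject_id=subject_id or str(path),
        channel_labels=list(raw.ch_names),
        data=data_uv,
        fs=float(raw.info["sfreq"]),
    )


def read_matrix(path, labels, fs: float, subject_id: str | None = None) -> EEGRecording:
    """Read a plain numeric channels x samples matrix (TSV or ``.npy``).

    ``labels`` is either a list of channel names or a path to a text file
    with one label per line.
    """
    path = str(path)
    if path.endswith(".npy"):
        data = np.load(path)
    else:
        data = np.loadtxt(path, delimiter="\t")
    if not isinstance(labels, (list, tuple)):
        with open(labels) as fh:
            labels = [line.strip() for line in fh if line.strip()]
    return EEGRecording(subject_id or path, list(labels), np.atleast_2d(data), fs)


def extract_epoch(
    rec: EEGRecording,
    start_s: float,
    duration_s: float = 20.0,
    amplitude_guard_uv: float | None = 150.0,
) -> EEGRecording:
    """Cut a contiguous fixed-length epoch from a recording.

    The amplitude guard is a programmatic stand-in for visual artifact
    screening: if any sample exceeds ``amplitude_guard_uv`` in magnitude the
    epoch is rejected by raising :class:`ArtifactRejected`.  Pass ``None`` to
    disable the guard.
    """
    if start_s < 0 or duration_s <= 0:
        raise ValueError("start and duration must be non-negative/positive")
    i0 = int(round(start_s * rec.fs))
    i1 = i0 + int(round(duration_s * rec.fs))
    if i1 > rec.n_samples:
        raise ValueError(
            f"epoch [{start_s}, {start_s + duration_s}) s exceeds recording "
            f"duration {rec.duration_s:.2f} s"
        )
    sl = rec.data[:, i0:i1]
    if amplitude_guard_uv is not None:
        peaks = np.max(np.abs(sl), axis=1)
        bad = peaks > amplitude_guard_uv
        if np.any(bad):
            raise ArtifactRejected(
                [rec.channel_labels[i] for i in np.flatnonzero(bad)],
                float(peaks.max()),
                amplitude_guard_uv,
            )
    meta = dict(rec.meta)
    meta.update(epoch_start_s=start_s, epoch_duration_s=duration_s)
    return replace(rec, data=sl.copy(), meta=meta)


def _design_bandpass(band: BandDefinition, fs: float, order: int = 3):
    if band.f_hi >= fs / 2:
        raise ValueError(
            f"band {band.name} upper edge {band.f_hi} Hz >= Nyquist {fs / 2} Hz"
        )
    return signal.butter(
        order, [band.f_lo, band.f_hi], btype="bandpass", fs=fs, output="sos"
    )


def bandpass(
    rec: EEGRecording,
    band: BandDefinition,
    order: int = 3,
    zero_phase: bool = True,
) -> EEGRecording:
    """Band-pass filter every channel with an order-``order`` Butterworth.

    ``order`` is the prototype order; zero-phase application (default) runs
    the filter forward and backward, squaring the magnitude response.
    """
    sos = _design_bandpass(band, rec.fs, order)
    if zero_phase:
        out = signal.sosfiltfilt(sos, rec.data, axis=1)
    else:
        out = signal.sosfilt(sos, rec.data, axis=1)
    meta = dict(rec.meta)
    meta.update(band=band.name, filter_order=order, zero_phase=zero_phase)
    return replace(rec, data=out, meta=meta)


def bandpass_response(
    band: BandDefinition, fs: float, freqs, order: int = 3, zero_phase: bool = True
) -> np.ndarray:
    """Analytic magnitude response of the designed filter at ``freqs`` (Hz)."""
    sos = _design_bandpass(band, fs, order)
    _, h = signal.sosfreqz(sos, worN=2 * np.pi * np.asarray(freqs) / fs)
    mag = np.abs(h)
    return mag**2 if zero_phase else mag
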