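"""Pairwise functional-connectivity measures and matrix assembly.

Implements three classical coupling measures between band-filtered EEG
channels and assembles full symmetric connectivity matrices:

* **PLI** (phase lag index): ``|<sign(sin(dphi(t)))>|`` over time, where
  ``dphi`` is the instantaneous phase difference from the analytic signal.
  Ranges 0..1; insensitive to zero-lag (volume-conduction) coupling.
* **MSC** (magnitude squared coherence): Welch segment-averaged
  ``|<X Y*>|^2 / (<|X|^2><|Y|^2>)``, averaged over the in-band frequency
  bins.  Ranges 0..1; with a single segment it is identically 1.
* **Spectrogram MI**: mutual information between the channels' normalized
  time-frequency energy distributions, in bits.

The EpEn coupling measure lives in :mod:`eegconn.epen`; the matrix builder
here dispatches to it so all four measures share one interface.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy import signal

from .io import BandDefinition, EEGRecording
from .epen import HMMConfig, epen_coupling

__all__ = [
    "WelchConfig",
    "ConnectivityMatrix",
    "pli",
    "pli_from_phase_diff",
    "msc",
    "spectral_mi",
    "mi_from_distributions",
    "normalized_spectrograms",
    "build_connectivity_matrix",
    "MEASURES",
]

MEASURES = ("EpEn", "PLI", "MSC", "MI")


@dataclass(frozen=True)
class WelchConfig:
    """Segmentation settings for Welch spectra and spectrograms.

    Defaults: 1-second segments (``segment_length=None`` resolves to ``fs``
    samples), 50% overlap, Hann taper.
    """

    segment_length: int | None = None
    overlap: float = 0.5
    window: str = "hann"

    def __post_init__(self):
        if not 0 <= self.overlap < 1:
            raise ValueError("overlap must be in [0, 1)")

    def nperseg(self, fs: float, n: int) -> int:
        L = self.segment_length if self.segment_length is not None else int(round(fs))
        if L > n:
            raise ValueError(f"segment length {L} exceeds signal length {n}")
        return L

    def n_segments(self, fs: float, n: int) -> int:
        L = self.nperseg(fs, n)
        step = L - int(L * self.overlap)
        return 1 + (n - L) // step


@dataclass
class ConnectivityMatrix:
    """Symmetric n x n connectivity values for one (measure, band, subject)."""

    measure: str
    band: BandDefinition | None
    values: np.ndarray
    channel_labels: list[str]
    subject_id: str = ""
    meta: dict | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("connectivity values must be square")
        off = ~np.eye(n, dtype=bool)
        if not np.allclose(self.values[off], self.values.T[off], atol=1e-9):
            raise ValueError("connectivity matrix must be symmetric")

    def to_tsv(self, path, sidecar: bool = True) -> None:
        import pandas as pd

        df = pd.DataFrame(
            self.values, index=self.channel_labels, columns=self.channel_labels
        )
        df.to_csv(path, sep="\t", float_format="%.17g")
        if sidecar:
            side = {
                "measure": self.measure,
                "band": asdict(self.band) if self.band else None,
                "subject_id": self.subject_id,
                "meta": self.meta or {},
            }
            with open(str(path) + ".json", "w") as fh:
                json.dump(side, fh, indent=1)

    @classmethod
    def from_tsv(cls, path) -> "ConnectivityMatrix":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
        measure, band, subject, meta = "", None, "", {}
        try:
            with open(str(path) + ".json") as fh:
                side = json.load(fh)
            measure = side.get("measure", "")
            subject = side.get("subject_id", "")
            meta = side.get("meta", {})
            if side.get("band"):
                band = BandDefinition(**side["band"])
        except FileNotFoundError:
            pass
        return cls(measure, band, df.values, list(df.columns), subject, meta)


# ---------------------------------------------------------------- PLI


def pli_from_phase_diff(delta_phi) -> float:
    """PLI from a precomputed phase-difference series (radians)."""
    d = np.asarray(delta_phi, dtype=float)
    if d.size == 0:
        raise ValueError("empty phase-difference series")
    return float(abs(np.mean(np.sign(np.sin(d)))))


def instantaneous_phase(x, edge_discard: float = 0.05) -> np.ndarray:
    """Instantaneous phase via the Hilbert analytic signal.

    A fraction ``edge_discard`` of samples is dropped at each end, where the
    analytic signal is dominated by edge transients.
    """
    x = np.asarray(x, dtype=float)
    phase = np.angle(signal.hilbert(x))
    k = int(len(x) * edge_discard)
    return phase[k : len(x) - k] if k else phase


def pli(x, y, edge_discard: float = 0.05) -> float:
    """Phase lag index of two band-limited series, in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D series")
    if len(x) < 2:
        raise ValueError("series too short for phase estimation")
    dphi = instantaneous_phase(x, edge_discard) - instantaneous_phase(y, edge_discard)
    return pli_from_phase_diff(dphi)


# ---------------------------------------------------------------- MSC


def msc(
    x,
    y,
    fs: float,
    band: BandDefinition | None = None,
    cfg: WelchConfig = WelchConfig(),
) -> float:
    """Band-averaged Welch magnitude squared coherence, in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D series")
    L = cfg.nperseg(fs, len(x))
    if cfg.n_segments(fs, len(x)) < 2:
        warnings.warn(
            "single Welch segment: coherence is identically 1", RuntimeWarning
        )
    f, cxy = signal.coherence(
        x, y, fs=fs, window=cfg.window, nperseg=L, noverlap=int(L * cfg.overlap)
    )
    if band is not None:
        mask = (f >= band.f_lo) & (f <= band.f_hi)
        if not np.any(mask):
            raise ValueError(f"no frequency bins inside band {band.name}")
        cxy = cxy[mask]
    return float(np.mean(cxy))


# ---------------------------------------------------------------- MI


def normalized_spectrograms(
    x,
    y,
    fs: float,
    band: BandDefinition | None = None,
    cfg: WelchConfig = WelchConfig(),
):
    """Normalized spectrograms Cx, Cy and cross distribution Cxy.

    Cx(k,f) = |X(k,f)|^2 / sum|X|^2, likewise Cy; the cross distribution is
    Cxy(k,f) = |X(k,f) Y*(k,f)| / sum|X Y*|.  When a band is given the
    time-frequency grid is restricted to in-band bins *before*
    normalization, so each distribution sums to 1 over the retained grid.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D series")
    L = cfg.nperseg(fs, len(x))
    f, _, X = signal.stft(
        x, fs=fs, window=cfg.window, nperseg=L, noverlap=int(L * cfg.overlap)
    )
    _, _, Y = signal.stft(
        y, fs=fs, window=cfg.window, nperseg=L, noverlap=int(L * cfg.overlap)
    )
    if band is not None:
        mask = (f >= band.f_lo) & (f <= band.f_hi)
        if not np.any(mask):
            raise ValueError(f"no frequency bins inside band {band.name}")
        X, Y = X[mask], Y[mask]
    Px = np.abs(X) ** 2
    Py = np.abs(Y) ** 2
    Pxy = np.abs(X * np.conj(Y))
    for P, name in ((Px, "x"), (Py, "y"), (Pxy, "cross")):
        if P.sum() <= 0:
            raise ValueError(f"all-zero spectrogram for {name}")
    return Px / Px.sum(), Py / Py.sum(), Pxy / Pxy.sum()


def mi_from_distributions(cx, cy, cxy) -> float:
    """MI in bits between normalized distributions on a common grid.

    ``sum cxy log2(cxy / (cx cy))`` with the convention 0*log(.) = 0.
    """
    cx = np.asarray(cx, dtype=float)
    cy = np.asarray(cy, dtype=float)
    cxy = np.asarray(cxy, dtype=float)
    nz = cxy > 0
    return float(np.sum(cxy[nz] * np.log2(cxy[nz] / (cx[nz] * cy[nz]))))


def spectral_mi(
    x,
    y,
    fs: float,
    band: BandDefinition | None = None,
    cfg: WelchConfig = WelchConfig(),
) -> float:
    """Mutual information of the two channels' normalized spectrograms (bits)."""
    cx, cy, cxy = normalized_spectrograms(x, y, fs, band, cfg)
    return mi_from_distributions(cx, cy, cxy)


# ---------------------------------------------------------------- assembly


def build_connectivity_matrix(
    rec: EEGRecording,
    measure: str,
    band: BandDefinition | None = None,
    welch: WelchConfig = WelchConfig(),
    hmm: HMMConfig | None = None,
    epen_mode: str = "literal",
) -> ConnectivityMatrix:
    """Evaluate one measure on all unordered channel pairs of a recording.

    ``rec`` is expected to be already band-filtered for the requested band
    (spectral measures additionally restrict to in-band bins).  The result
    is symmetric by construction; the diagonal is left at 0 and carries no
    meaning.
    """
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; choose from {MEASURES}")
    n = rec.n_channels
    if n < 2:
        raise ValueError("need at least 2 channels")
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            xi, xj = rec.data[i], rec.data[j]
            if measure == "PLI":
                v = pli(xi, xj)
            elif measure == "MSC":
                v = msc(xi, xj, rec.fs, band, welch)
            elif measure == "MI":
                v = spectral_mi(xi, xj, rec.fs, band, welch)
            else:
                v = epen_coupling(xi, xj, hmm or HMMConfig(dim=2), mode=epen_mode)
            vals[i, j] = vals[j, i] = v
    meta = {"epen_mode": epen_mode} if measure == "EpEn" else {}
    return ConnectivityMatrix(
        measure=measure,
        band=band,
        values=vals,
        channel_labels=list(rec.channel_labels),
        subject_id=rec.subject_id,
        meta=meta,
    )
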