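"""Three-rule channel pruning on pre-band-pass data.

A channel is flagged bad if any of the following holds:

1. **corr** — its maximum Pearson correlation with the other channels'
   HbT series is 0 or less.  Two robustness details: the correlation signal
   is the unfiltered HbT with only the slow drift removed (0.01 Hz
   high-pass), because nonstationary drift has so few degrees of freedom
   per recording that it produces large spurious correlations of arbitrary
   sign; and only channels passing the SNR and cardiac rules serve as
   correlation partners, because a channel whose own signal is noise cannot
   certify another channel's physiological validity (its large-amplitude
   noise correlates with anything at random sign);
2. **snr**  — its raw-intensity SNR (temporal mean / temporal SD, minimum
   over the two wavelengths) is below 2;
3. **cardiac** — its raw intensity shows no cardiac component: the spectral
   power fraction in the 0.8-1.6 Hz band is below threshold *and* there is
   no local spectral peak in that band.

The rules must run before band-pass filtering (the 0.01-0.1 Hz filter would
strip the cardiac band entirely).
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .recording import HemoRecording, RawRecording

__all__ = ["QCReport", "prune_channels", "apply_mask"]


@dataclass
class QCReport:
    """Per-channel quality metrics and bad-channel flags."""

    snr: np.ndarray  # min over wavelengths of mean/SD of raw intensity
    max_corr: np.ndarray  # max Pearson r against all other channels (HbT)
    cardiac_ratio: np.ndarray  # band power fraction in [0.8, 1.6] Hz
    cardiac_peak: np.ndarray  # bool: local spectral peak present in band
    reasons: list[frozenset[str]] = field(default_factory=list)

    @property
    def n_channels(self) -> int:
        return len(self.snr)

    @property
    def bad(self) -> np.ndarray:
        return np.array([len(r) > 0 for r in self.reasons])

    @property
    def good_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.bad)

    def active_mask(self) -> np.ndarray:
        return ~self.bad

    def to_rows(self) -> list[dict]:
        return [
            {
                "channel": i + 1,
                "snr": float(self.snr[i]),
                "max_corr": float(self.max_corr[i]),
                "cardiac_ratio": float(self.cardiac_ratio[i]),
                "cardiac_peak": bool(self.cardiac_peak[i]),
                "bad": bool(self.bad[i]),
                "reasons": ",".join(sorted(self.reasons[i])),
            }
            for i in range(self.n_channels)
        ]

    def to_csv(self) -> str:
        rows = self.to_rows()
        buf = io.StringIO()
        cols = list(rows[0])
        buf.write(",".join(cols) + "\n")
        for r in rows:
            buf.write(",".join(str(r[c]) for c in cols) + "\n")
        return buf.getvalue()

    def to_json(self) -> str:
        return json.dumps(self.to_rows(), indent=1)


def _cardiac_metrics(
    x: np.ndarray,
    fs: float,
    band: tuple[float, float],
    peak_window: tuple[float, float],
    peak_factor: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Band power fraction and local-peak presence from Welch periodograms.

    ``x`` is (n_channels, n_samples); all channels are processed in one
    vectorised Welch call.  Median averaging across segments makes the
    estimate robust to transient motion spikes, whose broadband energy
    would otherwise mimic a peak.
    """
    n = x.shape[0]
    nper = min(x.shape[-1], max(256, int(round(fs * 60))))
    f, p = signal.welch(signal.detrend(x, axis=-1), fs=fs, nperseg=nper,
                        average="median", axis=-1)
    total = np.trapezoid(p, f, axis=-1)
    in_band = (f >= band[0]) & (f <= band[1])
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(
            total > 0, np.trapezoid(p[:, in_band], f[in_band], axis=-1) / total, 0.0
        )
    in_window = (f >= peak_window[0]) & (f <= peak_window[1])
    if not np.any(in_band) or not np.any(in_window):
        return ratio, np.zeros(n, dtype=bool)
    floor = np.maximum(np.median(p[:, in_window], axis=-1), np.finfo(float).tiny)
    peak = p[:, in_band].max(axis=-1) > peak_factor * floor
    return ratio, peak


def prune_channels(
    raw: RawRecording,
    hemo_unfiltered: HemoRecording,
    snr_threshold: float = 2.0,
    cardiac_band: tuple[float, float] = (0.8, 1.6),
    cardiac_ratio_threshold: float = 0.05,
    peak_window: tuple[float, float] = (0.5, 2.5),
    peak_factor: float = 5.0,
    corr_highpass: float | None = 0.01,
) -> QCReport:
    """Apply the three pruning rules; returns every metric for every channel.

    ``hemo_unfiltered`` must be the MBLL output *before* band-pass filtering.
    The cardiac spectrum is assessed on the longer-wavelength raw intensity
    (850 nm), where the arterial pulsation is strongest.  ``corr_highpass``
    sets the drift-removal cutoff for the correlation rule (None disables
    it and correlates the fully unfiltered HbT).
    """
    n = raw.n_channels
    if n < 2:
        raise ValueError("channel pruning needs >= 2 channels (correlation rule)")
    if hemo_unfiltered.filtered:
        raise ValueError("pruning must run on pre-band-pass data (cardiac band intact)")

    mean = raw.intensity.mean(axis=2)
    sd = raw.intensity.std(axis=2, ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        snr_per_wl = np.where(sd > 0, np.abs(mean) / sd, np.inf)
    snr = snr_per_wl.min(axis=1)

    ratios, peaks = _cardiac_metrics(
        raw.intensity[:, 1, :], raw.fs, cardiac_band, peak_window, peak_factor
    )

    hbt = hemo_unfiltered.hbt
    if corr_highpass is not None:
        sos = signal.butter(2, corr_highpass, btype="highpass",
                            fs=hemo_unfiltered.fs, output="sos")
        hbt = signal.sosfiltfilt(sos, hbt, axis=-1)
    r = np.corrcoef(hbt)
    np.fill_diagonal(r, -np.inf)
    # valid correlation partners: channels passing the other two rules
    partner_ok = (snr >= snr_threshold) & ~(
        (ratios < cardiac_ratio_threshold) & ~peaks
    )
    max_corr = np.empty(n)
    for ch in range(n):
        partners = partner_ok.copy()
        partners[ch] = False
        if not np.any(partners):
            partners = np.ones(n, dtype=bool)
            partners[ch] = False
        max_corr[ch] = np.nanmax(r[ch, partners])

    reasons: list[frozenset[str]] = []
    for ch in range(n):
        why = set()
        if max_corr[ch] <= 0:
            why.add("corr")
        if snr[ch] < snr_threshold:
            why.add("snr")
        if ratios[ch] < cardiac_ratio_threshold and not peaks[ch]:
            why.add("cardiac")
        reasons.append(frozenset(why))
    return QCReport(snr=snr, max_corr=max_corr, cardiac_ratio=ratios,
                    cardiac_peak=peaks, reasons=reasons)


def apply_mask(obj, qc: QCReport):
    """Mark bad channels missing on an FCMatrix or HemoRecording.

    For an ``FCMatrix`` the bad rows/columns become NaN and the active mask
    is intersected; for a ``HemoRecording`` the bad channels' series become
    NaN.  Downstream averages use only surviving channels and renormalise by
    the surviving count.
    """
    from .connectivity import FCMatrix  # local import to avoid a cycle

    if np.all(qc.bad):
        raise ValueError("all channels failed QC; nothing left to analyse")
    if isinstance(obj, FCMatrix):
        if obj.r.shape[0] != qc.n_channels:
            raise ValueError("QC report channel count does not match FC matrix")
        active = obj.active & qc.active_mask()
        r = obj.r.copy()
        r[~active, :] = np.nan
        r[:, ~active] = np.nan
        return FCMatrix(r=r, active=active, subject_id=obj.subject_id)
    if isinstance(obj, HemoRecording):
        if obj.n_channels != qc.n_channels:
            raise ValueError("QC report channel count does not match recording")
        conc = obj.conc.copy()
        conc[qc.bad, :, :] = np.nan
        return obj.with_conc(conc)
    raise TypeError(f"cannot apply QC mask to {type(obj).__name__}")
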