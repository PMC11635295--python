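"""Raw intensity -> denoised hemoglobin concentration changes.

Processing order: modified Beer-Lambert conversion, 0.01-0.1 Hz band-pass,
PCA motion correction, extraction of a 5-min stable segment.

Conventions
-----------
* Optical-density baseline I0 is the *geometric* temporal mean per
  channel/wavelength, i.e. dOD(t) = -(log10 I(t) - mean_t log10 I).  dOD is
  therefore exactly zero-mean ("zero-mean-log" contract), which makes the
  forward/inverse conversion pair an exact round trip for zero-mean planted
  concentrations.
* Band-pass: 3rd-order Butterworth applied forward-backward (zero phase);
  order and band overridable.
* PCA: across channels, per chromophore (HbO and HbR; HbT is recomputed as
  their sum), on the full series; default 1 component removed.
* Stable segment: contiguous window minimising the total across-channel
  energy of the first difference of HbT; earliest offset wins ties.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .optics import OpticalModel
from .recording import HBO, HBR, HemoRecording, RawRecording

__all__ = [
    "optical_density",
    "mbll_convert",
    "bandpass",
    "pca_motion_correct",
    "select_stable_segment",
]


def optical_density(raw: RawRecording) -> np.ndarray:
    """Optical-density change dOD = -log10(I / I0), I0 = geometric temporal mean.

    Returns an array of shape (n_channels, 2, n_samples); each series is
    exactly zero-mean by construction.
    """
    log_i = np.log10(raw.intensity)  # positivity enforced by RawRecording
    return -(log_i - log_i.mean(axis=2, keepdims=True))


def mbll_convert(raw: RawRecording, optics: OpticalModel | None = None) -> HemoRecording:
    """Modified Beer-Lambert conversion to (dHbO, dHbR, dHbT) in relative uM.

    Solves, per channel and sample, the 2x2 linear system
    dOD(lambda) = [eps(lambda,HbO) dHbO + eps(lambda,HbR) dHbR] * DPF * L.
    """
    optics = optics or OpticalModel()
    od = optical_density(raw)
    coupling = optics.coupling_matrix()
    if np.linalg.cond(coupling) > 1e12:
        raise ValueError("singular extinction system; cannot invert MBLL")
    inv = np.linalg.inv(coupling)
    # (2x2) @ (channels x 2 x samples) over wavelength axis; mM -> uM
    conc_mm = np.einsum("cw,nws->ncs", inv, od)
    hbo, hbr = conc_mm[:, 0] * 1e3, conc_mm[:, 1] * 1e3
    return HemoRecording.from_hbo_hbr(hbo, hbr, fs=raw.fs, subject_id=raw.subject_id)


def bandpass(
    hemo: HemoRecording,
    low: float = 0.01,
    high: float = 0.1,
    order: int = 3,
) -> HemoRecording:
    """Zero-phase Butterworth band-pass of HbO and HbR; HbT recomputed as sum.

    The forward-backward application doubles the effective order and removes
    phase distortion; the passband is [low, high] Hz.
    """
    if not 0 < low < high < hemo.fs / 2:
        raise ValueError(
            f"invalid band edges ({low}, {high}) for fs = {hemo.fs} Hz"
        )
    sos = signal.butter(order, [low, high], btype="bandpass", fs=hemo.fs, output="sos")
    hbo = signal.sosfiltfilt(sos, hemo.conc[:, HBO], axis=-1)
    hbr = signal.sosfiltfilt(sos, hemo.conc[:, HBR], axis=-1)
    out = hemo.with_conc(np.stack([hbo, hbr, hbo + hbr], axis=1), filtered=True)
    return out


def _remove_components(x: np.ndarray, n_components: int) -> tuple[np.ndarray, float]:
    """Remove the top principal components of a channels x time matrix.

    Returns the cleaned matrix and the fraction of (mean-removed) variance
    that was taken out.
    """
    mean = x.mean(axis=1, keepdims=True)
    xc = x - mean
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    total = float(np.sum(s**2))
    if total == 0.0:
        return x.copy(), 0.0
    removed = u[:, :n_components] @ np.diag(s[:n_components]) @ vt[:n_components]
    frac = float(np.sum(s[:n_components] ** 2) / total)
    return xc - removed + mean, frac


def pca_motion_correct(
    hemo: HemoRecording,
    n_components: int | None = 1,
    variance_fraction: float | None = None,
) -> tuple[HemoRecording, dict[str, float]]:
    """PCA motion correction across channels, per chromophore.

    Motion artifacts are typically global (shared across channels) and so
    dominate the leading principal components of the channel x time matrix;
    removing those components suppresses them.  Either a fixed component
    count (default 1) or a target removed-variance fraction may be given.

    Returns the corrected recording and the removed-variance fraction per
    chromophore. ``n_components = 0`` is the identity.
    """
    if hemo.n_channels < 2 or hemo.n_samples < 2:
        raise ValueError("PCA correction needs >= 2 channels and >= 2 samples")
    cleaned = []
    report: dict[str, float] = {}
    for c, name in ((HBO, "HbO"), (HBR, "HbR")):
        x = hemo.conc[:, c]
        if variance_fraction is not None:
            if not 0 <= variance_fraction < 1:
                raise ValueError("variance_fraction must be in [0, 1)")
            s = np.linalg.svd(x - x.mean(axis=1, keepdims=True), compute_uv=False)
            frac = np.cumsum(s**2) / max(np.sum(s**2), np.finfo(float).tiny)
            k = int(np.searchsorted(frac, variance_fraction) + 1)
            k = min(k, hemo.n_channels - 1)
        else:
            k = int(n_components or 0)
        if k >= hemo.n_channels:
            raise ValueError(
                f"n_components = {k} must be < n_channels = {hemo.n_channels}"
            )
        xc, frac_removed = _remove_components(x, k) if k > 0 else (x.copy(), 0.0)
        cleaned.append(xc)
        report[name] = frac_removed
    hbo, hbr = cleaned
    out = hemo.with_conc(np.stack([hbo, hbr, hbo + hbr], axis=1), pca_corrected=True)
    return out, report


def select_stable_segment(
    hemo: HemoRecording, length: float = 300.0, offset: int | None = None
) -> HemoRecording:
    """Extract the most stable contiguous window of *length* seconds.

    Stability score of a window is the summed across-channel energy of the
    first difference of HbT inside it; the window with the minimum score is
    returned (earliest offset on ties).  ``offset`` forces a fixed start
    sample instead, for reproducibility.
    """
    w = int(round(length * hemo.fs))
    n = hemo.n_samples
    if w < 2:
        raise ValueError("segment length too short")
    if n < w:
        raise ValueError(
            f"recording ({n / hemo.fs:.1f} s) shorter than requested segment ({length} s)"
        )
    if offset is None:
        d2 = np.diff(hemo.hbt, axis=1) ** 2  # (channels, n-1)
        energy = d2.sum(axis=0)
        # window [o, o+w) covers diffs o .. o+w-2  -> w-1 diff terms
        csum = np.concatenate([[0.0], np.cumsum(energy)])
        scores = csum[w - 1 :] - csum[: n - w + 1]
        offset = int(np.argmin(scores))  # argmin returns first minimum
    if offset < 0 or offset + w > n:
        raise ValueError("segment offset out of range")
    out = hemo.with_conc(hemo.conc[:, :, offset : offset + w], segment_offset=offset)
    return out
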