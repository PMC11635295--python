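"""In-memory containers for raw optical and hemodynamic recordings.

`RawRecording` holds strictly positive dual-wavelength intensity time series
(channel x wavelength x sample, arbitrary units); `HemoRecording` holds the
derived chromophore concentration changes (channel x {HbO, HbR, HbT} x
sample, relative uM) together with provenance flags so every preprocessing
step is auditable.  The on-disk dialect is plain CSV: one row per
channel/wavelength (``ch1_w730 ...``) or per channel/chromophore, columns are
samples.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np

CHROMOPHORES = ("HbO", "HbR", "HbT")
HBO, HBR, HBT = 0, 1, 2


@dataclass
class RawRecording:
    """Dual-wavelength optical intensity series for one subject.

    ``intensity`` has shape (n_channels, 2, n_samples) and must be strictly
    positive (its logarithm is taken during conversion).
    """

    intensity: np.ndarray
    fs: float
    wavelengths: tuple[float, float] = (730.0, 850.0)
    subject_id: str = "subject"

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 3 or self.intensity.shape[1] != 2:
            raise ValueError(
                "intensity must have shape (n_channels, 2 wavelengths, n_samples)"
            )
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(self.intensity > 0):
            ch, wl, t = np.argwhere(~(self.intensity > 0))[0]
            raise ValueError(
                f"non-positive intensity at channel {ch + 1}, wavelength index "
                f"{wl}, sample {t} (log is undefined)"
            )

    @property
    def n_channels(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_samples(self) -> int:
        return self.intensity.shape[2]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    # ---- CSV dialect -----------------------------------------------------

    def to_csv(self) -> str:
        buf = io.StringIO()
        n_samples = self.n_samples
        buf.write("series," + ",".join(f"s{t}" for t in range(n_samples)) + "\n")
        for ch in range(self.n_channels):
            for w, wl in enumerate(self.wavelengths):
                row = self.intensity[ch, w]
                buf.write(
                    f"ch{ch + 1}_w{int(wl)},"
                    + ",".join(repr(float(v)) for v in row) + "\n"
                )
        return buf.getvalue()

    @classmethod
    def from_csv(cls, text: str, fs: float, subject_id: str = "subject") -> "RawRecording":
        lines = [ln for ln in text.strip().splitlines() if ln]
        header, rows = lines[0], lines[1:]
        del header
        series: dict[tuple[int, float], np.ndarray] = {}
        for ln in rows:
            name, rest = ln.split(",", 1)
            chpart, wpart = name.split("_w")
            ch = int(chpart[2:])
            wl = float(wpart)
            series[(ch, wl)] = np.fromstring(rest, sep=",")
        chans = sorted({ch for ch, _ in series})
        wls = sorted({wl for _, wl in series})
        if len(wls) != 2:
            raise ValueError("expected exactly two wavelengths in CSV")
        inten = np.stack(
            [np.stack([series[(ch, wl)] for wl in wls]) for ch in chans]
        )
        return cls(inten, fs=fs, wavelengths=(wls[0], wls[1]), subject_id=subject_id)


@dataclass
class HemoRecording:
    """Hemoglobin concentration-change series for one subject.

    ``conc`` has shape (n_channels, 3, n_samples) with chromophore order
    (HbO, HbR, HbT), in relative uM; HbT = HbO + HbR elementwise.
    """

    conc: np.ndarray
    fs: float
    subject_id: str = "subject"
    filtered: bool = False
    pca_corrected: bool = False
    segment_offset: int | None = None  # sample offset of extracted segment

    def __post_init__(self) -> None:
        self.conc = np.asarray(self.conc, dtype=float)
        if self.conc.ndim != 3 or self.conc.shape[1] != 3:
            raise ValueError("conc must have shape (n_channels, 3, n_samples)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @classmethod
    def from_hbo_hbr(
        cls, hbo: np.ndarray, hbr: np.ndarray, fs: float, **kw
    ) -> "HemoRecording":
        hbo = np.asarray(hbo, dtype=float)
        hbr = np.asarray(hbr, dtype=float)
        conc = np.stack([hbo, hbr, hbo + hbr], axis=1)
        return cls(conc, fs=fs, **kw)

    @property
    def n_channels(self) -> int:
        return self.conc.shape[0]

    @property
    def n_samples(self) -> int:
        return self.conc.shape[2]

    @property
    def hbt(self) -> np.ndarray:
        return self.conc[:, HBT, :]

    @property
    def hbo(self) -> np.ndarray:
        return self.conc[:, HBO, :]

    @property
    def hbr(self) -> np.ndarray:
        return self.conc[:, HBR, :]

    def check_hbt_sum(self, atol: float = 1e-9) -> bool:
        return bool(
            np.allclose(self.conc[:, HBT], self.conc[:, HBO] + self.conc[:, HBR], atol=atol)
        )

    def with_conc(self, conc: np.ndarray, **flags) -> "HemoRecording":
        new = replace(self)
        new.conc = np.asarray(conc, dtype=float)
        for k, v in flags.items():
            setattr(new, k, v)
        return new

    def to_csv(self) -> str:
        buf = io.StringIO()
        buf.write("series," + ",".join(f"s{t}" for t in range(self.n_samples)) + "\n")
        for ch in range(self.n_channels):
            for c, name in enumerate(CHROMOPHORES):
                buf.write(
                    f"ch{ch + 1}_{name},"
                    + ",".join(repr(float(v)) for v in self.conc[ch, c])
                    + "\n"
                )
        return buf.getvalue()
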