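"""Band power, percent change, EC-EO alpha reactivity, and alpha peak/CoG.

Spectra are plain rectangular-window FFT power spectra of 2-s epochs
(0.5-Hz resolution), normalized so that the sum over all one-sided bins
equals the mean squared amplitude of the epoch (Parseval).  The band
partition uses contiguous half-open intervals [1,4), [4,8), [8,13),
[13,18), [18,31), [31,50] Hz so every 0.5-Hz bin between the printed
integer band edges is assigned deterministically and relative powers sum
to one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .core_io import Recording

__all__ = [
    "BandScheme", "TRADITIONAL_BANDS", "AlphaDescriptor",
    "epoch_spectrum", "band_powers", "percent_change",
    "ec_eo_alpha_ratio", "alpha_peak_cog", "spectral_table",
]


@dataclass(frozen=True)
class BandScheme:
    """Ordered, contiguous, non-overlapping frequency bands."""

    names: tuple
    edges: tuple  # len(names)+1 increasing edges in Hz

    def __post_init__(self):
        if len(self.edges) != len(self.names) + 1:
            raise ValueError("need len(names)+1 edges")
        if not all(a < b for a, b in zip(self.edges, self.edges[1:])):
            raise ValueError("edges must be increasing")

    @property
    def lo(self) -> float:
        return self.edges[0]

    @property
    def hi(self) -> float:
        return self.edges[-1]

    def band_edges(self, name: str) -> tuple:
        i = self.names.index(name)
        return self.edges[i], self.edges[i + 1]


#: Delta, theta, alpha, slow beta, fast beta, gamma.
TRADITIONAL_BANDS = BandScheme(
    names=("delta", "theta", "alpha", "slow_beta", "fast_beta", "gamma"),
    edges=(1.0, 4.0, 8.0, 13.0, 18.0, 31.0, 50.0),
)


@dataclass
class AlphaDescriptor:
    """Individual alpha peak frequency and spectral center of gravity (Hz).

    ``peak_hz``/``cog_hz`` are ``None`` with ``ok=False`` when the smoothed
    spectrum has no interior local maximum in the search range.
    """

    peak_hz: float | None
    cog_hz: float | None
    ok: bool


def epoch_spectrum(epoch: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided power spectrum of one 2-s single-channel epoch.

    Returns ``(freqs, power)`` at 0.5-Hz resolution with
    ``sum(power) == mean(epoch**2)`` (Parseval).
    """
    epoch = np.asarray(epoch, dtype=np.float64)
    n = epoch.shape[-1]
    if abs(n - 2 * fs) > 0.5:
        raise ValueError(f"epoch must be 2 s long ({2 * fs:.0f} samples), got {n}")
    X = np.fft.rfft(epoch)
    p = (np.abs(X) ** 2) / n**2
    p[..., 1:] *= 2.0
    if n % 2 == 0:
        p[..., -1] /= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return freqs, p


def band_powers(freqs: np.ndarray, power: np.ndarray,
                scheme: BandScheme = TRADITIONAL_BANDS) -> pd.DataFrame:
    """Absolute (uV^2) and relative power per band.

    Bins are assigned to the band whose half-open interval ``[lo, hi)``
    contains them; the top edge of the last band is inclusive.  Relative
    power is normalized by the total over the scheme's full range, so the
    relative values sum to 1.
    """
    freqs = np.asarray(freqs)
    power = np.asarray(power, dtype=np.float64)
    rows = []
    for i, name in enumerate(scheme.names):
        lo, hi = scheme.edges[i], scheme.edges[i + 1]
        if i == len(scheme.names) - 1:
            sel = (freqs >= lo) & (freqs <= hi)
        else:
            sel = (freqs >= lo) & (freqs < hi)
        rows.append((name, float(power[..., sel].sum(axis=-1))))
    total = sum(v for _, v in rows)
    return pd.DataFrame(
        {"band": [n for n, _ in rows],
         "absolute": [v for _, v in rows],
         "relative": [v / total if total > 0 else np.nan for _, v in rows]})


def band_power(freqs: np.ndarray, power: np.ndarray, lo: float, hi: float,
               inclusive_hi: bool = False) -> float:
    """Summed power in [lo, hi) (or [lo, hi])."""
    freqs = np.asarray(freqs)
    sel = (freqs >= lo) & ((freqs <= hi) if inclusive_hi else (freqs < hi))
    return float(np.asarray(power)[..., sel].sum(axis=-1))


def percent_change(p_inside: float, p_outside: float) -> float:
    """(inside/outside)*100 - 100; NaN when the reference power is zero."""
    if p_outside == 0:
        return float("nan")
    return p_inside / p_outside * 100.0 - 100.0


def ec_eo_alpha_ratio(epochs, channels: Sequence[str] = ("O1", "O2"),
                      scheme: BandScheme = TRADITIONAL_BANDS,
                      n_per_condition: int | None = None) -> float:
    """Occipital alpha power ratio eyes-closed / eyes-open.

    Mean alpha absolute power over non-rejected EC epochs and the listed
    channels divided by the same quantity over EO epochs.  When
    ``n_per_condition`` is given only the first available epochs per
    condition enter the ratio.
    """
    lo, hi = scheme.band_edges("alpha")
    ch_idx = [epochs.channel_labels.index(c) for c in channels]
    powers = {}
    for cond in ("EC", "EO"):
        sel = [i for i in range(epochs.n_epochs)
               if epochs.condition[i] == cond and not epochs.rejected[i]]
        if n_per_condition is not None:
            sel = sel[:n_per_condition]
        if not sel:
            raise ValueError(f"no usable {cond} epochs")
        vals = []
        for i in sel:
            for c in ch_idx:
                f, p = epoch_spectrum(epochs.epochs[i, c], epochs.fs)
                vals.append(band_power(f, p, lo, hi))
        powers[cond] = float(np.mean(vals))
    if powers["EO"] == 0:
        raise ValueError("zero eyes-open alpha power: ratio undefined")
    return powers["EC"] / powers["EO"]


def alpha_peak_cog(freqs: np.ndarray, power: np.ndarray, frame: int = 11,
                   order: int = 5, search: tuple = (7.0, 13.0)) -> AlphaDescriptor:
    """Alpha peak frequency and center of gravity from a mean power spectrum.

    The spectrum is smoothed with a Savitzky-Golay filter (default frame 11,
    polynomial order 5); the peak is the highest interior local maximum
    within the search range that exceeds the spectrum value at both range
    endpoints.  CoG is the power-weighted mean frequency over the range,
    computed from the smoothed spectrum.  Both are missing (``ok=False``)
    when no such local maximum exists.
    """
    if frame % 2 == 0 or frame <= order:
        raise ValueError("Savitzky-Golay frame must be odd and exceed the order")
    freqs = np.asarray(freqs)
    power = np.asarray(power, dtype=np.float64)
    if freqs[0] > 1.0 or freqs[-1] < 40.0 - 1e-9:
        raise ValueError("spectrum must cover 1-40 Hz")
    smooth = savgol_filter(power, frame, order)
    sel = (freqs >= search[0]) & (freqs <= search[1])
    f, p = freqs[sel], smooth[sel]
    interior = np.arange(1, len(p) - 1)
    is_max = (p[interior] > p[interior - 1]) & (p[interior] >= p[interior + 1])
    cand = interior[is_max]
    cand = cand[(p[cand] > p[0]) & (p[cand] > p[-1])]
    if len(cand) == 0:
        return AlphaDescriptor(None, None, False)
    peak = float(f[cand[np.argmax(p[cand])]])
    w = np.clip(p, 0.0, None)
    cog = float(np.sum(f * w) / np.sum(w)) if w.sum() > 0 else None
    return AlphaDescriptor(peak, cog, True)


def mean_spectrum(epochs, channel: str) -> tuple[np.ndarray, np.ndarray]:
    """Mean power spectrum of a channel across non-rejected epochs."""
    c = epochs.channel_labels.index(channel)
    keep = [i for i in range(epochs.n_epochs) if not epochs.rejected[i]]
    if not keep:
        raise ValueError("all epochs rejected")
    specs = []
    for i in keep:
        f, p = epoch_spectrum(epochs.epochs[i, c], epochs.fs)
        specs.append(p)
    return f, np.mean(specs, axis=0)


def spectral_table(epochs, subject: str, condition: str,
                   scheme: BandScheme = TRADITIONAL_BANDS,
                   max_epochs: int | None = None) -> pd.DataFrame:
    """Tidy per-channel band-power table for one recording condition.

    Columns: subject, channel, band, condition, absolute, relative,
    n_epochs.  Power is averaged across the first ``max_epochs``
    non-rejected epochs (all of them when ``None``).
    """
    keep = [i for i in range(epochs.n_epochs) if not epochs.rejected[i]]
    if max_epochs is not None:
        keep = keep[:max_epochs]
    if not keep:
        raise ValueError("all epochs rejected")
    out = []
    for c, lab in enumerate(epochs.channel_labels):
        specs = []
        for i in keep:
            f, p = epoch_spectrum(epochs.epochs[i, c], epochs.fs)
            specs.append(p)
        bp = band_powers(f, np.mean(specs, axis=0), scheme)
        for _, row in bp.iterrows():
            out.append({"subject": subject, "channel": lab, "band": row["band"],
                        "condition": condition, "absolute": row["absolute"],
                        "relative": row["relative"], "n_epochs": len(keep)})
    return pd.DataFrame(out)
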