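"""Core data model and file I/O for EEG-fMRI recordings.

The in-memory container is :class:`Recording`: a channels-by-samples matrix in
microvolts plus labelled event trains stored as integer sample indices
(0-based).  Sample indices rather than seconds are used everywhere inside the
pipeline so that artifact epochs align exactly; conversion to/from seconds
happens only at the file boundary.

Supported on-disk dialects are EDF+ and BrainVision (.vhdr/.vmrk/.eeg).
Reading goes through MNE.  No EDF or BrainVision *writer* is available in the
runtime environment, so minimal writers for both dialects are implemented
here; they emit files that MNE (and other standard readers) parse.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

#: Event labels used throughout the pipeline.
TR = "TR"
RPEAK = "RPEAK"
EC_ONSET = "EC_ONSET"
EO_ONSET = "EO_ONSET"

#: The 18 10-20 scalp electrodes analysed (Cz is the reference, kept as
#: metadata, never a data row).
TEN_TWENTY_18 = (
    "Fp1", "Fp2", "F3", "F4", "F7", "F8", "Fz", "C3", "C4",
    "P3", "P4", "Pz", "T3", "T4", "T5", "T6", "O1", "O2",
)
ECG_LABEL = "ECG"

#: Posterior electrodes (used by alpha topography scoring).
POSTERIOR = ("P3", "P4", "Pz", "T5", "T6", "O1", "O2")

#: Left/right homologous pairs and anterior/posterior mirror pairs of the
#: montage, used for polarity-inversion scoring of IC topographies.
LR_PAIRS = (("Fp1", "Fp2"), ("F3", "F4"), ("F7", "F8"), ("C3", "C4"),
            ("P3", "P4"), ("T3", "T4"), ("T5", "T6"), ("O1", "O2"))
AP_PAIRS = (("Fp1", "O1"), ("Fp2", "O2"), ("F3", "P3"), ("F4", "P4"),
            ("F7", "T5"), ("F8", "T6"), ("Fz", "Pz"))


class FormatError(ValueError):
    """Raised when a file cannot be parsed under the requested dialect."""


@dataclass
class EventTrain:
    """A labelled train of event onsets as strictly increasing sample indices."""

    label: str
    samples: np.ndarray

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("event label must be nonempty")
        self.samples = np.asarray(self.samples, dtype=np.int64)
        if self.samples.ndim != 1:
            raise ValueError("event samples must be 1-D")
        if len(self.samples) > 1 and not np.all(np.diff(self.samples) > 0):
            raise ValueError(f"event samples for {self.label!r} must be strictly increasing")

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class Recording:
    """Continuous multichannel time series in microvolts.

    Parameters
    ----------
    channel_labels
        Unique channel names (10-20 montage plus optional ECG).
    fs
        Sampling rate in Hz.
    data
        ``(n_channels, n_samples)`` array, microvolts.
    events
        Labelled event trains; indices in ``[0, n_samples)``.
    meta
        Free-form provenance notes (e.g. reference electrode name).
    """

    channel_labels: list[str]
    fs: float
    data: np.ndarray
    events: list[EventTrain] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=np.float64))
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("channel_labels length must match data rows")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        n = self.data.shape[1]
        for ev in self.events:
            if len(ev) and (ev.samples[0] < 0 or ev.samples[-1] >= n):
                raise ValueError(f"event {ev.label!r} index out of range [0, {n})")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def get_events(self, label: str) -> np.ndarray:
        for ev in self.events:
            if ev.label == label:
                return ev.samples
        return np.array([], dtype=np.int64)

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.channel_labels.index(label)]

    def pick(self, labels: Sequence[str]) -> "Recording":
        """Sub-recording restricted to the given channels (copy)."""
        idx = [self.channel_labels.index(l) for l in labels]
        return Recording(list(labels), self.fs, self.data[idx].copy(),
                         [EventTrain(e.label, e.samples.copy()) for e in self.events],
                         dict(self.meta))

    def copy_with(self, data: np.ndarray) -> "Recording":
        return Recording(list(self.channel_labels), self.fs, data,
                         [EventTrain(e.label, e.samples.copy()) for e in self.events],
                         dict(self.meta))


@dataclass
class PipelineConfig:
    """All printed analysis constants in one place.

    Defaults follow the standard simultaneous EEG-fMRI processing choices:
    1-50 Hz band-pass, 2-s epochs, 5-volume sliding window for gradient AAS,
    210-ms R-to-BCG-peak delay, 4 principal components for OBS, Savitzky-Golay
    frame 11 / order 5 with a 7-13 Hz alpha search range.  The epoch
    rejection threshold (peak-to-peak) defaults to 500 uV: rejection targets
    gross movement/blink transients and must sit above the BCG artifact
    amplitude, since rejection runs before BCG correction.
    """

    band_scheme: str = "traditional"
    epoch_len_s: float = 2.0
    filter_low_hz: float = 1.0
    filter_high_hz: float = 50.0
    bcg_delay_s: float = 0.21
    ga_window_volumes: int = 5
    bcg_window_cycles: int = 21
    obs_n_pcs: int = 4
    sg_frame: int = 11
    sg_order: int = 5
    alpha_search_low_hz: float = 7.0
    alpha_search_high_hz: float = 13.0
    hrf_peak_s: float = 6.0
    hrf_dispersion_s: float = 1.2
    reject_uv: float = 500.0
    channels: tuple = TEN_TWENTY_18
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.epoch_len_s > 0:
            raise ValueError("epoch length must be positive")
        if not self.filter_low_hz < self.filter_high_hz:
            raise ValueError("filter low edge must be below high edge")
        for name in ("ga_window_volumes", "bcg_window_cycles", "sg_frame", "sg_order"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        d = yaml.safe_load(text) or {}
        if "channels" in d:
            d["channels"] = tuple(d["channels"])
        return cls(**d)

    def to_file(self, path: str | Path) -> None:
        d = asdict(self)
        d["channels"] = list(d["channels"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


# ---------------------------------------------------------------------------
# Event TSV I/O
# ---------------------------------------------------------------------------

def read_events(path: str | Path) -> list[EventTrain]:
    """Read a 2-column TSV (label, sample) into one train per distinct label.

    Rows may be unsorted; duplicated (label, sample) pairs are dropped with a
    warning.  Non-integer sample values raise a parse error.
    """
    df = pd.read_csv(path, sep="\t")
    if not {"label", "sample"}.issubset(df.columns):
        raise FormatError(f"{path}: expected columns 'label' and 'sample'")
    try:
        samples = df["sample"].astype(np.int64)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: non-integer sample value") from exc
    if not np.array_equal(samples.to_numpy(), df["sample"].to_numpy()):
        raise FormatError(f"{path}: non-integer sample value")
    trains = []
    for label, grp in df.assign(sample=samples).groupby("label", sort=True):
        vals = np.unique(grp["sample"].to_numpy())
        if len(vals) < len(grp):
            warnings.warn(f"duplicated samples for event label {label!r} deduplicated")
        trains.append(EventTrain(str(label), vals))
    return trains


def write_events(trains: Sequence[EventTrain], path: str | Path) -> None:
    rows = [(t.label, int(s)) for t in trains for s in t.samples]
    pd.DataFrame(rows, columns=["label", "sample"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# EDF+ writing (16-bit) -- no writer ships with the environment
# ---------------------------------------------------------------------------

def _edf_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def _is_ecg(label: str) -> bool:
    return "ECG" in label.upper()


def write_recording(rec: Recording, path: str | Path, dialect: str = "EDF") -> None:
    """Write a Recording to EDF+ or BrainVision.

    EEG channels are stored in microvolts, ECG channels in millivolts
    (vendor convention); events become EDF+ annotations / BrainVision
    markers.  EDF record duration is 1 s; the final partial record, if any,
    is zero-padded (a warning is emitted because the roundtrip then returns
    extra trailing samples).
    """
    dialect = dialect.upper()
    if dialect == "EDF":
        _write_edf(rec, Path(path))
    elif dialect == "BRAINVISION":
        _write_brainvision(rec, Path(path))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _write_edf(rec: Recording, path: Path) -> None:
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_rec = math.ceil(rec.n_samples / fs)
    if n_rec * fs != rec.n_samples:
        warnings.warn("recording length is not a whole number of seconds; "
                      "final EDF record zero-padded")

    # annotation TALs, one block per 1-s data record
    tals: list[bytes] = []
    ev_by_rec: dict[int, list[bytes]] = {}
    for ev in rec.events:
        for s in ev.samples:
            t = s / fs
            ev_by_rec.setdefault(int(t), []).append(
                (f"+{t:.4f}\x14{ev.label}\x14\x00").encode("ascii"))
    for i in range(n_rec):
        block = (f"+{i}\x14\x14\x00").encode("ascii") + b"".join(ev_by_rec.get(i, []))
        tals.append(block)
    ann_bytes = max((len(b) for b in tals), default=2) + 2
    ann_ns = (ann_bytes + 1) // 2  # 2-byte "samples"

    labels = list(rec.channel_labels)
    nsig = len(labels) + 1
    phys_min, phys_max, scaled = [], [], []
    for ch, lab in enumerate(labels):
        x = rec.data[ch]
        if _is_ecg(lab):
            x = x / 1000.0  # store ECG in mV
        m = float(np.max(np.abs(x))) if x.size else 0.0
        m = m if m > 0 else 1.0
        phys_min.append(-m)
        phys_max.append(m)
        scaled.append(np.round(x / m * 32767.0).astype("<i2"))

    hdr = b""
    hdr += _edf_field("0", 8)
    hdr += _edf_field("X X X X", 80)                      # patient
    hdr += _edf_field("Startdate X X X X", 80)            # recording
    hdr += _edf_field("01.01.00", 8) + _edf_field("00.00.00", 8)
    hdr += _edf_field(256 * (nsig + 1), 8)
    hdr += _edf_field("EDF+C", 44)
    hdr += _edf_field(n_rec, 8)
    hdr += _edf_field(1, 8)                               # record duration s
    hdr += _edf_field(nsig, 4)

    def sig_fields(vals, width):
        return b"".join(_edf_field(v, width) for v in vals)

    all_labels = labels + ["EDF Annotations"]
    dims = [("mV" if _is_ecg(l) else "uV") for l in labels] + [""]
    hdr += sig_fields(all_labels, 16)
    hdr += sig_fields(["" for _ in all_labels], 80)       # transducer
    hdr += sig_fields(dims, 8)
    hdr += sig_fields([f"{v:.6g}" for v in phys_min] + ["-1"], 8)
    hdr += sig_fields([f"{v:.6g}" for v in phys_max] + ["1"], 8)
    hdr += sig_fields(["-32768"] * len(labels) + ["-32768"], 8)
    hdr += sig_fields(["32767"] * len(labels) + ["32767"], 8)
    hdr += sig_fields(["" for _ in all_labels], 80)       # prefiltering
    hdr += sig_fields([fs] * len(labels) + [ann_ns], 8)
    hdr += sig_fields(["" for _ in all_labels], 32)       # reserved

    with open(path, "wb") as fh:
        fh.write(hdr)
        for i in range(n_rec):
            lo, hi = i * fs, (i + 1) * fs
            for ch in range(len(labels)):
                seg = scaled[ch][lo:hi]
                if len(seg) < fs:
                    seg = np.concatenate([seg, np.zeros(fs - len(seg), dtype="<i2")])
                fh.write(seg.tobytes())
            fh.write(tals[i].ljust(2 * ann_ns, b"\x00"))


# ---------------------------------------------------------------------------
# BrainVision writing (.vhdr/.vmrk/.eeg, float32 multiplexed)
# ---------------------------------------------------------------------------

def _write_brainvision(rec: Recording, path: Path) -> None:
    path = path.with_suffix(".vhdr")
    stem = path.stem
    eeg_name, vmrk_name = stem + ".eeg", stem + ".vmrk"
    nch = rec.n_channels
    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg_name}",
        f"MarkerFile={vmrk_name}",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={nch}",
        f"SamplingInterval={1e6 / rec.fs:.6f}",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "[Channel Infos]",
    ]
    for i, lab in enumerate(rec.channel_labels, 1):
        unit = "mV" if _is_ecg(lab) else "µV"
        lines.append(f"Ch{i}={lab},,1,{unit}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")

    mlines = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg_name}",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,00000000000000000000",
    ]
    k = 2
    evs = sorted(((int(s), t.label) for t in rec.events for s in t.samples))
    for s, lab in evs:
        mlines.append(f"Mk{k}=Stimulus,{lab},{s + 1},1,0")
        k += 1
    (path.parent / vmrk_name).write_text("\n".join(mlines) + "\n", encoding="utf-8")

    out = rec.data.T.astype("<f4").copy()
    for i, lab in enumerate(rec.channel_labels):
        if _is_ecg(lab):
            out[:, i] /= 1000.0
    (path.parent / eeg_name).write_bytes(out.tobytes())


# ---------------------------------------------------------------------------
# Reading via MNE
# ---------------------------------------------------------------------------

def read_recording(path: str | Path, dialect: str = "EDF") -> Recording:
    """Read an EDF+ or BrainVision file into a Recording (microvolts).

    Annotations whose description matches a known event label become
    EventTrains; onset seconds are converted to sample indices by rounding.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    dialect = dialect.upper()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if dialect == "EDF":
                raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
            elif dialect == "BRAINVISION":
                raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
            else:
                raise ValueError(f"unknown dialect {dialect!r}")
    except (ValueError, TypeError) as exc:
        raise exc if isinstance(exc, ValueError) and "dialect" in str(exc) else FormatError(str(exc))
    except Exception as exc:  # mne raises assorted errors on truncated files
        raise FormatError(f"{path}: {exc}") from exc
    if not raw.info["sfreq"] or raw.info["sfreq"] <= 0:
        raise FormatError(f"{path}: missing or invalid sampling rate")

    data = raw.get_data() * 1e6  # MNE returns SI volts -> microvolts
    labels = list(raw.ch_names)
    fs = float(raw.info["sfreq"])

    ev: dict[str, list[int]] = {}
    for ann in raw.annotations:
        desc = ann["description"]
        if "/" in desc:  # BrainVision 'Stimulus/LABEL'
            desc = desc.split("/", 1)[1]
        if desc.startswith("New Segment"):
            continue
        ev.setdefault(desc, []).append(int(round(ann["onset"] * fs)))
    trains = [EventTrain(lab, np.unique(np.array(s, dtype=np.int64)))
              for lab, s in sorted(ev.items())]
    trains = [t for t in trains if len(t)]
    for t in trains:
        t.samples = t.samples[(t.samples >= 0) & (t.samples < data.shape[1])]
    return Recording(labels, fs, data, trains, {"source": str(path)})
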