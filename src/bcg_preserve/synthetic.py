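"""Synthetic EEG-fMRI subjects with known ground truth.

Each simulated subject is an 18-channel 10-20 EEG at 1000 Hz:

* per-channel 1/f background (spectrally shaped white noise, exponent 1);
* a single posterior alpha source (10 Hz) whose envelope follows alternating
  20-s eyes-closed / eyes-open blocks starting with eyes closed, so the
  configured amplitude ratio sets the true EC/EO alpha power ratio
  ((EC amp / EO amp)^2, default 3);
* an ECG channel built from a Gaussian-bump PQRST template at R times drawn
  with uniform RR jitter;
* a cardiac-locked BCG artifact: each heartbeat contributes, starting 210 ms
  after the R wave, a sum of three damped oscillations (3.2/6.4/9.6 Hz) with
  per-cycle per-component amplitude jitter, projected through left-right
  antisymmetric topographies so the IC polarity-inversion criterion is
  testable; artifact power is concentrated in 1-15 Hz;
* a TR-locked gradient artifact (TR = 2 s): a slice-frequency harmonic comb,
  bit-identical across TRs, scaled to a large multiple of the clean RMS;
* a BOLD voxel grid in which a fraction of voxels is negatively coupled to
  the epoch-wise occipital alpha power through a gamma HRF, on an AR(1)
  noise floor.

The contaminated EEG equals clean + BCG + GA sample-wise and every latent
component is returned in :class:`GroundTruth`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import yaml

from .core_io import (Recording, EventTrain, TEN_TWENTY_18, ECG_LABEL,
                      TR, RPEAK, EC_ONSET, EO_ONSET, write_recording, write_events)
from .spectral import epoch_spectrum, band_power

__all__ = ["SimulationConfig", "GroundTruth", "gen_clean_eeg", "gen_ecg",
           "gen_bcg_artifact", "gen_gradient_artifact", "gen_bold",
           "assemble_subject", "generate_cohort", "CHANNEL_XY"]

#: Approximate 10-20 scalp coordinates (x: left -1 .. right +1,
#: y: posterior -1 .. anterior +1), used to build artifact topographies.
CHANNEL_XY = {
    "Fp1": (-0.3, 1.0), "Fp2": (0.3, 1.0),
    "F7": (-0.8, 0.6), "F3": (-0.4, 0.6), "Fz": (0.0, 0.6),
    "F4": (0.4, 0.6), "F8": (0.8, 0.6),
    "T3": (-1.0, 0.0), "C3": (-0.5, 0.0), "C4": (0.5, 0.0), "T4": (1.0, 0.0),
    "T5": (-0.8, -0.6), "P3": (-0.4, -0.6), "Pz": (0.0, -0.6),
    "P4": (0.4, -0.6), "T6": (0.8, -0.6),
    "O1": (-0.3, -1.0), "O2": (0.3, -1.0),
}

#: Posterior alpha topography (occipital-dominant).
ALPHA_TOPO = {"O1": 1.0, "O2": 1.0, "Pz": 0.8, "P3": 0.7, "P4": 0.7,
              "T5": 0.5, "T6": 0.5}


@dataclass
class SimulationConfig:
    """All knobs of the simulator; defaults are the study conditions.

    Amplitudes in microvolts, times in seconds.  ``ec_amplitude`` defaults
    to sqrt(3) x ``eo_amplitude`` so the true EC/EO alpha power ratio is 3.
    """

    seed: int = 0
    duration_s: float = 240.0
    fs: float = 1000.0
    channels: tuple = TEN_TWENTY_18
    # 1/f background
    bg_exponent: float = 1.0
    bg_rms_uv: float = 10.0
    # alpha source; the phase random walk (rad/sqrt(s)) gives the rhythm a
    # realistic ~0.5-Hz linewidth and decorrelates it from the TR grid
    alpha_hz: float = 10.0
    alpha_phase_jitter: float = 2.0
    eo_amplitude_uv: float = 15.0
    ec_amplitude_uv: float = 15.0 * np.sqrt(3.0)
    alpha_topo: dict = field(default_factory=lambda: dict(ALPHA_TOPO))
    # task blocks
    block_len_s: float = 20.0
    start_condition: str = "EC"
    ramp_s: float = 0.5
    # cardiac
    rr_mean_s: float = 0.9
    rr_jitter_s: float = 0.1
    ecg_r_uv: float = 1000.0
    ecg_noise_uv: float = 10.0
    # BCG artifact
    bcg_delay_s: float = 0.21
    bcg_cycle_s: float = 0.6
    bcg_amplitude_uv: float = 150.0
    # damped oscillatory components: low cardiac harmonics dominate, with a
    # small sharp transient carrying the artifact's high-frequency edge
    bcg_harmonics_hz: tuple = (3.3, 6.6, 9.9, 13.6, 35.0)
    bcg_harmonic_rel: tuple = (0.75, 0.95, 0.5, 0.45, 0.15)
    bcg_decay_s: tuple = (0.12, 0.12, 0.15, 0.3, 0.05)
    bcg_rise_comp_s: tuple = (0.1, 0.1, 0.12, 0.2, 0.02)
    bcg_rise_s: float = 0.05
    bcg_jitter: float = 0.1
    # gradient artifact
    tr_s: float = 2.0
    slices_per_tr: int = 30
    ga_scale: float = 50.0
    ga_harmonics: int = 10
    # BOLD
    bold_shape: tuple = (10, 10, 10)
    coupled_fraction: float = 0.1
    bold_beta: float = -0.01
    bold_ar1: float = 0.3
    bold_noise_sd: float = 1.0

    def __post_init__(self):
        if self.rr_jitter_s >= self.rr_mean_s:
            raise ValueError("RR jitter must be below the mean RR interval")
        if self.rr_mean_s <= 0.3:
            raise ValueError("mean RR must exceed 0.3 s")
        if not (0 <= self.bcg_jitter <= 1):
            raise ValueError("BCG amplitude jitter must be in [0, 1]")
        if self.duration_s < self.block_len_s:
            raise ValueError("duration must cover at least one task block")
        if not (7 <= self.alpha_hz <= 13):
            raise ValueError("alpha frequency must lie within 7-13 Hz")
        if min(self.ec_amplitude_uv, self.eo_amplitude_uv, self.bg_rms_uv,
               self.bcg_amplitude_uv) < 0:
            raise ValueError("amplitudes must be nonnegative")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))

    @property
    def n_volumes(self) -> int:
        return int(self.duration_s // self.tr_s)

    @classmethod
    def from_file(cls, path) -> "SimulationConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        for k in ("channels", "bcg_harmonics_hz", "bcg_harmonic_rel", "bold_shape"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    def to_file(self, path) -> None:
        d = asdict(self)
        for k in ("channels", "bcg_harmonics_hz", "bcg_harmonic_rel", "bold_shape"):
            d[k] = list(d[k])
        d["ec_amplitude_uv"] = float(d["ec_amplitude_uv"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


@dataclass
class GroundTruth:
    """Everything the simulator knows that an analysis must recover."""

    rpeaks: np.ndarray                 # true R-wave sample indices
    clean: Recording                   # clean EEG (no ECG channel)
    bcg: np.ndarray                    # channels x samples artifact component
    ga: np.ndarray                     # channels x samples artifact component
    alpha_power: np.ndarray            # n_epochs x n_channels true clean alpha power
    ec_eo_ratio: float                 # configured (EC amp / EO amp)^2
    bold: np.ndarray | None = None     # voxels x volumes
    coupled_mask: np.ndarray | None = None
    beta: float | None = None


def _alpha_envelope(cfg: SimulationConfig) -> np.ndarray:
    """Per-sample alpha amplitude following the EC/EO block design."""
    n, fs = cfg.n_samples, cfg.fs
    block = int(round(cfg.block_len_s * fs))
    amps = {"EC": cfg.ec_amplitude_uv, "EO": cfg.eo_amplitude_uv}
    order = ["EC", "EO"] if cfg.start_condition == "EC" else ["EO", "EC"]
    env = np.empty(n)
    for i in range(int(np.ceil(n / block))):
        env[i * block:(i + 1) * block] = amps[order[i % 2]]
    ramp = int(round(cfg.ramp_s * fs))
    if ramp > 1:
        w = np.hanning(2 * ramp + 1)
        w /= w.sum()
        env = np.convolve(env, w, mode="same")
    return env


def _block_events(cfg: SimulationConfig) -> list[EventTrain]:
    block = int(round(cfg.block_len_s * cfg.fs))
    onsets = np.arange(0, cfg.n_samples, block)
    first_ec = cfg.start_condition == "EC"
    ec = onsets[0::2] if first_ec else onsets[1::2]
    eo = onsets[1::2] if first_ec else onsets[0::2]
    out = []
    if len(ec):
        out.append(EventTrain(EC_ONSET, ec))
    if len(eo):
        out.append(EventTrain(EO_ONSET, eo))
    return out


def _one_over_f(n: int, fs: float, exponent: float, rms: float,
                rng: np.random.Generator) -> np.ndarray:
    """Spectrally shaped white noise with power density ~ 1/f^exponent.

    The shaping is flat below 1 Hz to keep the variance finite; output is
    scaled to the requested RMS.
    """
    white = rng.standard_normal(n)
    X = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = 1.0 / np.maximum(f, 1.0) ** (exponent / 2.0)
    shape[0] = 0.0
    x = np.fft.irfft(X * shape, n=n)
    s = np.std(x)
    return x * (rms / s) if s > 0 else x


def gen_clean_eeg(cfg: SimulationConfig,
                  rng: np.random.Generator | None = None) -> tuple[Recording, dict]:
    """Clean EEG: 1/f background plus block-modulated posterior alpha.

    Returns the Recording (with EC/EO block-onset events) and a dict of
    ground-truth pieces (envelope, per-channel topography weights, the true
    EC/EO alpha power ratio).
    """
    rng = rng or np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    t = np.arange(n) / cfg.fs
    env = _alpha_envelope(cfg)
    phase = rng.uniform(0, 2 * np.pi)
    if cfg.alpha_phase_jitter > 0:
        phase = phase + np.cumsum(
            rng.normal(0, cfg.alpha_phase_jitter / np.sqrt(cfg.fs), n))
    source = env * np.sin(2 * np.pi * cfg.alpha_hz * t + phase)
    data = np.empty((len(cfg.channels), n))
    for i, ch in enumerate(cfg.channels):
        w = cfg.alpha_topo.get(ch, 0.0)
        data[i] = _one_over_f(n, cfg.fs, cfg.bg_exponent, cfg.bg_rms_uv, rng) + w * source
    rec = Recording(list(cfg.channels), cfg.fs, data, _block_events(cfg),
                    {"reference": "Cz", "kind": "clean"})
    truth = {"envelope": env,
             "alpha_weights": np.array([cfg.alpha_topo.get(c, 0.0) for c in cfg.channels]),
             "ec_eo_ratio": (cfg.ec_amplitude_uv / cfg.eo_amplitude_uv) ** 2}
    return rec, truth


def _pqrst_template(fs: float, r_uv: float) -> tuple[np.ndarray, int]:
    """Gaussian-bump PQRST waveform; returns (template, index of R peak)."""
    t = np.arange(-0.35, 0.45, 1.0 / fs)
    def g(mu, sd, a):
        return a * np.exp(-0.5 * ((t - mu) / sd) ** 2)
    w = (g(-0.2, 0.04, 0.15) + g(-0.04, 0.01, -0.15) + g(0.0, 0.012, 1.0)
         + g(0.035, 0.012, -0.25) + g(0.25, 0.05, 0.3)) * r_uv
    return w, int(np.argmin(np.abs(t)))


def gen_ecg(cfg: SimulationConfig,
            rng: np.random.Generator | None = None) -> tuple[Recording, EventTrain]:
    """Synthetic ECG channel with uniformly jittered RR intervals.

    The returned EventTrain holds the exact ground-truth R-peak samples.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    n, fs = cfg.n_samples, cfg.fs
    x = rng.normal(0, cfg.ecg_noise_uv, n)
    tmpl, r_off = _pqrst_template(fs, cfg.ecg_r_uv)
    times, tcur = [], 0.5
    while tcur < cfg.duration_s - 0.5:
        times.append(tcur)
        tcur += rng.uniform(cfg.rr_mean_s - cfg.rr_jitter_s,
                            cfg.rr_mean_s + cfg.rr_jitter_s)
    peaks = np.round(np.array(times) * fs).astype(np.int64)
    for p in peaks:
        lo = p - r_off
        hi = lo + len(tmpl)
        a, b = max(lo, 0), min(hi, n)
        x[a:b] += tmpl[a - lo:b - lo]
    rec = Recording([ECG_LABEL], fs, x[None, :], [EventTrain(RPEAK, peaks)],
                    {"kind": "ecg"})
    return rec, EventTrain(RPEAK, peaks)


def _bcg_waveform(cfg: SimulationConfig, amps: np.ndarray) -> np.ndarray:
    """One cardiac cycle of the BCG per harmonic component: (n_comp, L)."""
    nc = len(cfg.bcg_harmonics_hz)
    L = int(round(cfg.bcg_cycle_s * cfg.fs))
    t = np.arange(L) / cfg.fs
    # cosine fade over the last 100 ms avoids a truncation discontinuity
    fade_n = min(L, int(round(0.1 * cfg.fs)))
    fade = np.ones(L)
    fade[L - fade_n:] = 0.5 * (1 + np.cos(np.pi * np.arange(fade_n) / fade_n))
    decays = np.broadcast_to(np.atleast_1d(cfg.bcg_decay_s), (nc,))
    rises = np.broadcast_to(np.atleast_1d(getattr(cfg, "bcg_rise_comp_s",
                                                  cfg.bcg_rise_s)), (nc,))
    out = np.empty((nc, L))
    for k, (f, a, tau, tr) in enumerate(zip(cfg.bcg_harmonics_hz, amps,
                                            decays, rises)):
        onset = 0.5 * (1 - np.cos(np.pi * np.minimum(t / tr, 1.0)))
        envelope = onset * np.exp(-np.maximum(t - tr, 0) / tau) * fade
        out[k] = a * envelope * np.sin(2 * np.pi * f * t)
    return out


def bcg_topographies(cfg: SimulationConfig) -> np.ndarray:
    """Left-right antisymmetric spatial patterns, one per harmonic component.

    All patterns change sign across the midline (the polarity inversion the
    IC topography criterion looks for); the higher-frequency components are
    weighted toward posterior electrodes, where pulse-driven electrode
    motion is strongest in practice.
    """
    x = np.array([CHANNEL_XY[c][0] for c in cfg.channels])
    y = np.array([CHANNEL_XY[c][1] for c in cfg.channels])
    post = (1.0 - y) / 2.0  # 0 at frontal pole, 1 at occiput
    s = np.sign(x)
    pats = np.stack([
        s * (0.3 + 0.7 * np.abs(x)),
        s * (0.4 + 0.6 * np.abs(y)),
        s * (0.2 + 0.8 * post),
        s * (0.25 + 0.75 * post),
        s * (0.35 + 0.65 * post),
    ])[: len(cfg.bcg_harmonics_hz)]
    return pats / np.max(np.abs(pats), axis=1, keepdims=True)


def gen_bcg_artifact(cfg: SimulationConfig, rpeaks: np.ndarray,
                     rng: np.random.Generator | None = None) -> np.ndarray:
    """Cardiac-locked BCG artifact, channels x samples.

    Each heartbeat contributes damped oscillations whose global maximum is
    anchored ``bcg_delay_s`` after the R wave (the waveform onset is placed
    earlier by the peak latency within the cycle, but never before
    R + 10 ms); per-cycle, per-component amplitudes are multiplied by
    ``1 + jitter * U(-1, 1)``; components are projected through left-right
    antisymmetric topographies scaled so the strongest channel peaks near
    ``bcg_amplitude_uv``.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    rpeaks = np.asarray(rpeaks)
    if len(rpeaks) and (rpeaks.min() < 0 or rpeaks.max() >= n):
        raise ValueError("R peaks outside the recording")
    topo = bcg_topographies(cfg)
    base = np.array(cfg.bcg_harmonic_rel, dtype=float)
    # scale so the strongest channel's waveform peaks near bcg_amplitude_uv
    ref = topo.T @ _bcg_waveform(cfg, base)
    scale = cfg.bcg_amplitude_uv / np.max(np.abs(ref))
    t_peak = int(np.argmax(np.max(np.abs(ref), axis=0)))
    delay = max(int(round(cfg.bcg_delay_s * cfg.fs)) - t_peak,
                int(round(0.01 * cfg.fs)))
    out = np.zeros((len(cfg.channels), n))
    for r in rpeaks:
        amps = base * (1.0 + cfg.bcg_jitter * rng.uniform(-1, 1, len(base)))
        comp = _bcg_waveform(cfg, amps) * scale       # (3, L)
        lo = r + delay
        hi = min(lo + comp.shape[1], n)
        if lo >= n:
            continue
        out[:, lo:hi] += topo.T @ comp[:, :hi - lo]
    return out


def gen_gradient_artifact(cfg: SimulationConfig, tr_events: np.ndarray,
                          clean_rms_uv: float,
                          rng: np.random.Generator | None = None) -> np.ndarray:
    """TR-locked gradient artifact, channels x samples.

    One TR-long slice-harmonic comb (harmonics of slices_per_tr / TR) is
    tiled bit-identically from the first TR marker onward and scaled so its
    RMS is ``ga_scale`` times the clean-EEG RMS.  Channels share the
    waveform up to a fixed per-channel gain.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    n, fs = cfg.n_samples, cfg.fs
    tr_events = np.asarray(tr_events)
    L = int(round(cfg.tr_s * fs))
    if len(tr_events) > 1 and np.ptp(np.diff(tr_events)) > 1:
        raise ValueError("TR markers must be regularly spaced")
    t = np.arange(L) / fs
    f_slice = cfg.slices_per_tr / cfg.tr_s
    wave = np.zeros(L)
    for h in range(1, cfg.ga_harmonics + 1):
        if h * f_slice >= fs / 2:
            break
        wave += np.sin(2 * np.pi * h * f_slice * t + 0.7 * h) / np.sqrt(h)
    target = cfg.ga_scale * clean_rms_uv
    if np.std(wave) > 0 and target > 0:
        wave *= target / np.std(wave)
    else:
        wave[:] = 0.0
    gains = rng.uniform(0.7, 1.3, len(cfg.channels))
    start = int(tr_events[0]) if len(tr_events) else 0
    n_rep = int(np.ceil((n - start) / L))
    tiled = np.tile(wave, n_rep)[: n - start]
    out = np.zeros((len(cfg.channels), n))
    out[:, start:] = gains[:, None] * tiled[None, :]
    return out


def gen_bold(cfg: SimulationConfig, alpha_series: np.ndarray,
             rng: np.random.Generator | None = None) -> tuple[np.ndarray, np.ndarray]:
    """BOLD voxel grid negatively coupled to epoch-wise alpha power.

    Coupled voxels follow ``beta * (alpha (*) HRF)`` (mean-centered
    regressor) plus AR(1) noise; uncoupled voxels are noise only.  Returns
    (voxels x volumes matrix, boolean coupled mask).
    """
    from .fmri import gamma_hrf

    rng = rng or np.random.default_rng(cfg.seed)
    alpha_series = np.asarray(alpha_series, dtype=float)
    n_vol = cfg.n_volumes
    if len(alpha_series) != n_vol:
        raise ValueError(f"alpha series length {len(alpha_series)} != volumes {n_vol}")
    kern = gamma_hrf(cfg.tr_s, peak_s=6.0, dispersion_s=1.2)
    pad = len(kern) - 1  # steady-state start, matching the analysis predictor
    x = np.convolve(np.r_[np.full(pad, alpha_series[0]), alpha_series],
                    kern)[pad:pad + n_vol]
    x = x - x.mean()
    n_vox = int(np.prod(cfg.bold_shape))
    n_coupled = int(round(cfg.coupled_fraction * n_vox))
    mask = np.zeros(n_vox, dtype=bool)
    if cfg.bold_beta != 0.0 and n_coupled > 0:
        # the coupled region is a fixed "anatomical" voxel set shared by all
        # subjects of a cohort (drawn from a grid-determined stream), so
        # group-level inference across subjects is meaningful
        mask_rng = np.random.default_rng(abs(hash(cfg.bold_shape)) % 2**31)
        mask[mask_rng.choice(n_vox, n_coupled, replace=False)] = True
    eps = rng.normal(0, cfg.bold_noise_sd, (n_vox, n_vol))
    noise = np.empty_like(eps)
    noise[:, 0] = eps[:, 0]
    for tix in range(1, n_vol):
        noise[:, tix] = cfg.bold_ar1 * noise[:, tix - 1] + eps[:, tix]
    y = noise
    y[mask] += cfg.bold_beta * x
    return y, mask


def assemble_subject(cfg: SimulationConfig) -> tuple[Recording, GroundTruth]:
    """Build one contaminated subject: clean + BCG + GA, plus ECG and BOLD.

    The contaminated Recording carries the 18 EEG channels plus the ECG
    channel and all event trains (TR, true R peaks, EC/EO onsets).  The
    EEG rows satisfy contaminated = clean + BCG + GA exactly.
    """
    ss = np.random.SeedSequence(cfg.seed)
    r_bg, r_ecg, r_bcg, r_ga, r_bold = [np.random.default_rng(s)
                                        for s in ss.spawn(5)]
    clean, truth = gen_clean_eeg(cfg, r_bg)
    ecg, rtrain = gen_ecg(cfg, r_ecg)
    bcg = gen_bcg_artifact(cfg, rtrain.samples, r_bcg)
    tr_samples = np.arange(0, cfg.n_samples, int(round(cfg.tr_s * cfg.fs)),
                           dtype=np.int64)
    ga = gen_gradient_artifact(cfg, tr_samples, float(np.std(clean.data)), r_ga)

    # true per-epoch clean alpha power (2-s epochs, 8-13 Hz partition band)
    L = int(round(2.0 * cfg.fs))
    n_ep = cfg.n_samples // L
    alpha_power = np.empty((n_ep, clean.n_channels))
    for e in range(n_ep):
        seg = clean.data[:, e * L:(e + 1) * L]
        for c in range(clean.n_channels):
            f, p = epoch_spectrum(seg[c], cfg.fs)
            alpha_power[e, c] = band_power(f, p, 8.0, 13.0)
    o1 = list(cfg.channels).index("O1")
    bold, mask = gen_bold(cfg, alpha_power[:cfg.n_volumes, o1], r_bold)

    data = np.vstack([clean.data + bcg + ga, ecg.data])
    events = [EventTrain(TR, tr_samples), EventTrain(RPEAK, rtrain.samples.copy())]
    events += [EventTrain(e.label, e.samples.copy()) for e in clean.events]
    rec = Recording(list(cfg.channels) + [ECG_LABEL], cfg.fs, data, events,
                    {"reference": "Cz", "kind": "contaminated", "seed": cfg.seed})
    gt = GroundTruth(rpeaks=rtrain.samples, clean=clean, bcg=bcg, ga=ga,
                     alpha_power=alpha_power, ec_eo_ratio=truth["ec_eo_ratio"],
                     bold=bold, coupled_mask=mask, beta=cfg.bold_beta)
    return rec, gt


def generate_cohort(cfg: SimulationConfig, n_subjects: int):
    """Yield (subject_id, Recording, GroundTruth) with per-subject seeds."""
    for i in range(n_subjects):
        sub_cfg = replace(cfg, seed=int((cfg.seed + 7919 * (i + 1)) % 2**31))
        rec, gt = assemble_subject(sub_cfg)
        yield f"sub-{i + 1:02d}", rec, gt


def write_subject(rec: Recording, gt: GroundTruth, out_dir) -> None:
    """Write one subject to disk: EDF + events TSV + ground-truth arrays."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_recording(rec, out / "recording.edf", "EDF")
    write_events(rec.events, out / "events.tsv")
    np.savetxt(out / "clean_eeg.txt.gz", gt.clean.data)
    np.savetxt(out / "bcg.txt.gz", gt.bcg)
    np.savetxt(out / "ga.txt.gz", gt.ga)
    np.savetxt(out / "alpha_power.txt", gt.alpha_power)
    if gt.bold is not None:
        np.savetxt(out / "bold.txt.gz", gt.bold)
        np.savetxt(out / "coupled_mask.txt", gt.coupled_mask.astype(int), fmt="%d")
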