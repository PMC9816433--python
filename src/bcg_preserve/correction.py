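"""Gradient-artifact AAS and the BCG correction family.

Implemented strategies:

* ``ga_aas`` -- average artifact subtraction for the gradient artifact:
  sliding-window (5 volumes) mean template aligned to TR markers.
* ``bcg_aas`` -- AAS for the ballistocardiographic artifact: cardiac cycles
  extracted around R + 210 ms, sliding-window (21 cycles) mean template.
* ``bcg_obs`` -- optimal basis set: per-channel PCA over aligned artifact
  epochs; the mean waveform plus the leading principal components are
  fitted to and subtracted from every epoch.
* ``fit_ica`` / ``score_bcg_components`` / ``remove_components`` -- ICA
  decomposition with automated artifact-component selection using the three
  classic criteria (cardiac-locked time course, harmonic spectrum,
  polarity-inverted topography).
* ``bcg_combined`` -- AAS-ICA and OBS-ICA.
* ``projic`` -- AAS/OBS applied to selected independent-component time
  series before remixing to channel space.
* ``ife_alpha`` -- ICA feature extraction: keep only alpha-related
  components (EC-block reactivity, ~10-Hz spectral peak, posterior
  topography) and reconstruct from those alone.

Artifact epochs for AAS/OBS span R + delay - 0.25*RR to R + delay + 0.75*RR
(median RR); where consecutive epochs overlap, ownership is truncated at
the midpoint so every sample is corrected by exactly one cycle's template.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import signal as sps

from .core_io import Recording, EventTrain, LR_PAIRS, AP_PAIRS, POSTERIOR, RPEAK
from .spectral import epoch_spectrum, band_power, alpha_peak_cog

__all__ = ["CorrectionReport", "ICADecomposition", "ga_aas", "bcg_aas",
           "bcg_obs", "fit_ica", "score_bcg_components", "remove_components",
           "bcg_combined", "projic", "ife_alpha", "score_alpha_components",
           "apply_method", "METHODS"]

METHODS = ("none", "aas", "obs", "ica", "obs-ica", "aas-ica",
           "projic-aas", "projic-obs", "ife")


@dataclass
class CorrectionReport:
    """Provenance of one correction run."""

    method: str
    params: dict
    reduction_db: dict = dc_field(default_factory=dict)  # per-channel, at cardiac fundamental
    removed: list = dc_field(default_factory=list)
    retained: list = dc_field(default_factory=list)
    warnings: list = dc_field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps({
            "method": self.method, "params": self.params,
            "reduction_db": self.reduction_db, "removed": self.removed,
            "retained": self.retained, "warnings": self.warnings}, indent=2)


# ---------------------------------------------------------------------------
# epoch extraction shared by AAS and OBS
# ---------------------------------------------------------------------------

def _cycle_layout(rpeaks: np.ndarray, delay_s: float, fs: float,
                  n_samples: int) -> tuple[np.ndarray, int, np.ndarray]:
    """Epoch starts, length, and ownership bounds for cardiac cycles.

    Epochs run from R + delay - 0.25*RR to R + delay + 0.75*RR with RR the
    median R-R interval; cycles not fully inside the record are dropped.
    Ownership bounds truncate overlapping neighbors at their midpoint.
    """
    rpeaks = np.asarray(rpeaks, dtype=np.int64)
    if len(rpeaks) < 2:
        raise ValueError("need at least 2 R peaks")
    rr = int(round(np.median(np.diff(rpeaks))))
    delay = int(round(delay_s * fs))
    pre, post = int(round(0.25 * rr)), int(round(0.75 * rr))
    L = pre + post
    starts = rpeaks + delay - pre
    keep = (starts >= 0) & (starts + L <= n_samples)
    starts = starts[keep]
    if len(starts) < 2:
        raise ValueError("fewer than 2 complete cardiac cycles in the record")
    bounds = np.empty((len(starts), 2), dtype=np.int64)
    bounds[:, 0] = starts
    bounds[:, 1] = starts + L
    for i in range(len(starts) - 1):
        if starts[i + 1] < starts[i] + L:  # overlap: split at midpoint
            mid = (starts[i + 1] + starts[i] + L) // 2
            bounds[i, 1] = mid
            bounds[i + 1, 0] = mid
    return starts, L, bounds


def _sliding_mean(E: np.ndarray, window: int) -> np.ndarray:
    """Centered sliding mean over the cycle axis (axis -2), edge-truncated."""
    n = E.shape[-2]
    cs = np.cumsum(E, axis=-2)
    half = window // 2
    out = np.empty_like(E)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        s = cs[..., hi - 1, :] - (cs[..., lo - 1, :] if lo > 0 else 0)
        out[..., i, :] = s / (hi - lo)
    return out


def _subtract_owned(data: np.ndarray, estimate: np.ndarray, starts: np.ndarray,
                    bounds: np.ndarray) -> np.ndarray:
    """Subtract per-cycle artifact estimates within each cycle's owned span."""
    out = data.copy()
    for i, s in enumerate(starts):
        lo, hi = bounds[i]
        out[:, lo:hi] -= estimate[:, i, lo - s:hi - s]
    return out


def _fundamental_db(before: np.ndarray, after: np.ndarray, fs: float,
                    rpeaks: np.ndarray, labels) -> dict:
    """Per-channel artifact power reduction (dB) at the cardiac fundamental."""
    f0 = fs / np.median(np.diff(rpeaks))
    out = {}
    for i, lab in enumerate(labels):
        f, pb = sps.periodogram(before[i], fs)
        _, pa = sps.periodogram(after[i], fs)
        sel = (f >= 0.8 * f0) & (f <= 1.2 * f0)
        b, a = pb[sel].sum(), pa[sel].sum()
        out[lab] = float(10 * np.log10(b / a)) if a > 0 and b > 0 else float("inf")
    return out


# ---------------------------------------------------------------------------
# AAS
# ---------------------------------------------------------------------------

def ga_aas(rec: Recording, tr_events: np.ndarray | None = None,
           window_volumes: int = 5) -> tuple[Recording, CorrectionReport]:
    """Gradient-artifact AAS: sliding-window mean template per TR segment.

    The template for each TR segment is the mean of the ``window_volumes``
    nearest segments (centered window, truncated at the record edges) and
    is subtracted per channel.  TR markers must be regularly spaced (within
    one sample).
    """
    tr = np.asarray(tr_events if tr_events is not None else rec.get_events("TR"),
                    dtype=np.int64)
    report = CorrectionReport("ga-aas", {"window_volumes": window_volumes})
    if len(tr) < 2:
        raise ValueError("need at least 2 TR markers")
    d = np.diff(tr)
    if np.ptp(d) > 1:
        raise ValueError("irregular TR spacing (beyond 1 sample): cannot align")
    L = int(d[0])
    keep = tr[tr + L <= rec.n_samples]
    if len(keep) < window_volumes:
        report.warnings.append(
            f"only {len(keep)} volumes for a {window_volumes}-volume window; "
            "edge-truncated windows used")
    idx = keep[:, None] + np.arange(L)
    E = rec.data[:, idx]                        # (ch, vol, L)
    templates = _sliding_mean(E, window_volumes)
    bounds = np.column_stack([keep, keep + L])
    out = _subtract_owned(rec.data, templates, keep, bounds)
    return rec.copy_with(out), report


def bcg_aas(rec: Recording, rpeaks: np.ndarray, delay_s: float = 0.21,
            window_cycles: int = 21, scale: bool = False,
            report_reduction: bool = False) -> tuple[Recording, CorrectionReport]:
    """BCG AAS: sliding-window mean template over aligned cardiac cycles.

    Cycles span R + delay - 0.25*RR to R + delay + 0.75*RR; the per-cycle
    template is the unweighted mean of the ``window_cycles`` nearest cycles
    (optionally least-squares rescaled to each cycle when ``scale``).
    Samples outside every cycle's owned span are untouched.
    """
    starts, L, bounds = _cycle_layout(rpeaks, delay_s, rec.fs, rec.n_samples)
    idx = starts[:, None] + np.arange(L)
    E = rec.data[:, idx]
    T = _sliding_mean(E, window_cycles)
    if scale:
        num = np.sum(E * T, axis=-1, keepdims=True)
        den = np.sum(T * T, axis=-1, keepdims=True)
        T = T * np.where(den > 0, num / den, 1.0)
    out = _subtract_owned(rec.data, T, starts, bounds)
    rep = CorrectionReport("aas", {"delay_s": delay_s,
                                   "window_cycles": window_cycles, "scale": scale})
    if report_reduction:
        rep.reduction_db = _fundamental_db(rec.data, out, rec.fs, rpeaks,
                                           rec.channel_labels)
    return rec.copy_with(out), rep


# ---------------------------------------------------------------------------
# OBS
# ---------------------------------------------------------------------------

def bcg_obs(rec: Recording, rpeaks: np.ndarray, delay_s: float = 0.21,
            n_pcs: int = 4, report_reduction: bool = False
            ) -> tuple[Recording, CorrectionReport]:
    """Optimal basis set BCG correction.

    Per channel, the matrix of aligned artifact epochs is decomposed by
    PCA; the basis (mean waveform plus the top ``n_pcs`` principal
    components) is least-squares fitted to every epoch and the fit is
    subtracted.  ``n_pcs = 0`` is the identity transform.
    """
    rep = CorrectionReport("obs", {"delay_s": delay_s, "n_pcs": n_pcs})
    if n_pcs == 0:
        return rec.copy_with(rec.data.copy()), rep
    starts, L, bounds = _cycle_layout(rpeaks, delay_s, rec.fs, rec.n_samples)
    if len(starts) < n_pcs + 1:
        raise ValueError(f"{len(starts)} cycles cannot support {n_pcs} PCs")
    idx = starts[:, None] + np.arange(L)
    est = np.empty((rec.n_channels, len(starts), L))
    for c in range(rec.n_channels):
        E = rec.data[c][idx]                    # (cycles, L)
        mean_wave = E.mean(axis=0)
        D = E - mean_wave
        _, _, Vt = np.linalg.svd(D, full_matrices=False)
        B = np.column_stack([mean_wave, Vt[:n_pcs].T])   # (L, n_pcs+1)
        coef, *_ = np.linalg.lstsq(B, E.T, rcond=None)
        est[c] = (B @ coef).T
    out = _subtract_owned(rec.data, est, starts, bounds)
    if report_reduction:
        rep.reduction_db = _fundamental_db(rec.data, out, rec.fs, rpeaks,
                                           rec.channel_labels)
    return rec.copy_with(out), rep


# ---------------------------------------------------------------------------
# ICA
# ---------------------------------------------------------------------------

@dataclass
class ICADecomposition:
    """An ICA unmixing of a multichannel recording.

    ``sources = W @ (data - mean)``; reconstruction is
    ``A @ sources + mean`` which reproduces the input within numerical
    tolerance when no components are dropped.
    """

    W: np.ndarray                 # unmixing, components x channels
    A: np.ndarray                 # mixing, channels x components
    sources: np.ndarray           # components x samples
    mean: np.ndarray              # per-channel mean removed before unmixing
    channel_labels: list
    fs: float
    scores: dict = dc_field(default_factory=dict)
    selected_bcg: list = dc_field(default_factory=list)
    selected_alpha: list = dc_field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.W.shape[0]

    def reconstruct(self, include=None, exclude=None,
                    sources: np.ndarray | None = None) -> np.ndarray:
        S = self.sources if sources is None else sources
        comps = np.arange(self.n_components)
        if include is not None:
            comps = np.asarray(sorted(include), dtype=int)
        elif exclude is not None:
            comps = np.array([c for c in comps if c not in set(exclude)], dtype=int)
        if np.any(comps < 0) or np.any(comps >= self.n_components):
            raise IndexError("component index out of range")
        if len(comps) == 0:
            return np.tile(self.mean[:, None], (1, S.shape[1])) * 0.0
        return self.A[:, comps] @ S[comps] + self.mean[:, None]


def fit_ica(data, n_components: int | None = None, seed: int = 0,
            max_iter: int = 1000, tol: float = 1e-4,
            fit_decimate: int = 4) -> ICADecomposition:
    """FastICA decomposition of a Recording (or channels-x-samples array).

    Deterministic under a fixed seed.  If the data are rank-deficient the
    component count is reduced to the numerical rank with a warning.

    ``fit_decimate`` estimates the unmixing matrix on every k-th sample
    (safe after the 1-50 Hz band-pass, where a 1000-Hz recording is heavily
    oversampled) and then applies it to the full-rate data, so sources and
    reconstruction keep full length; set to 1 to fit on all samples.
    """
    from sklearn.decomposition import FastICA
    from sklearn.exceptions import ConvergenceWarning

    if isinstance(data, Recording):
        X, labels, fs = data.data, list(data.channel_labels), data.fs
    else:
        X = np.atleast_2d(np.asarray(data, dtype=float))
        labels, fs = [f"ch{i}" for i in range(X.shape[0])], 1.0
    n_ch = X.shape[0]
    if n_components is None:
        n_components = n_ch
    cov = np.cov(X)
    rank = int(np.linalg.matrix_rank(np.atleast_2d(cov)))
    if rank < n_components:
        warnings.warn(f"rank-deficient data (rank {rank}): reducing components "
                      f"from {n_components}")
        n_components = rank
    step = max(1, int(fit_decimate))
    Xfit = X[:, ::step] if step > 1 else X
    if Xfit.shape[1] < 20 * n_components ** 2:
        Xfit = X  # too few samples after decimation: fit on everything
    ica = FastICA(n_components=n_components, random_state=seed,
                  whiten="unit-variance", max_iter=max_iter, tol=tol)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        ica.fit(Xfit.T)
    W = ica.components_
    A = ica.mixing_
    # centre on the full-data mean (not the decimated-fit mean): A @ W ~ I
    # keeps the reconstruction exact and sources only shift by a tiny DC
    mean = X.mean(axis=1)
    S = W @ (X - mean[:, None])
    return ICADecomposition(W=W, A=A, sources=S, mean=mean,
                            channel_labels=labels, fs=fs)


def _pair_antisymmetry(a: np.ndarray, labels, pairs) -> float:
    """-sum(a_i * a_j) / (0.5 * sum(a_i^2 + a_j^2)) over homologous pairs.

    1 for perfect polarity inversion, -1 for perfect symmetry, ~0 when the
    paired weights are unrelated or concentrated off the pairs.
    """
    num = den = 0.0
    for li, lj in pairs:
        if li in labels and lj in labels:
            ai, aj = a[labels.index(li)], a[labels.index(lj)]
            num += -ai * aj
            den += 0.5 * (ai * ai + aj * aj)
    return num / den if den > 0 else 0.0


def score_bcg_components(ica: ICADecomposition, rpeaks: np.ndarray, fs: float,
                         n_perm: int = 199, seed: int = 0,
                         p_thresh: float = 0.01, harm_thresh: float = 2.0,
                         topo_thresh: float = 0.5) -> tuple[dict, list]:
    """Score every IC on the three BCG criteria and select artifact ICs.

    1. cardiac locking: RMS of the R-locked cycle average against a null of
       circularly shifted R trains (permutation p < ``p_thresh``);
    2. harmonic spectrum: periodogram mass within +-0.2*f0 of the first
       three cardiac harmonics over the mass at the half-harmonic
       neighbors (> ``harm_thresh``);
    3. topography: left-right or anterior-posterior polarity-inversion
       index of the mixing column (> ``topo_thresh``).

    A component is selected iff all three criteria pass.  Returns
    (scores dict of arrays, selected indices); also stored on ``ica``.
    """
    rng = np.random.default_rng(seed)
    rpeaks = np.asarray(rpeaks, dtype=np.int64)
    n = ica.sources.shape[1]
    rr = int(round(np.median(np.diff(rpeaks))))
    L = int(round(0.7 * rr))
    starts = rpeaks[(rpeaks >= 0) & (rpeaks + L <= n)]
    idx = starts[:, None] + np.arange(L)
    shifts = rng.integers(int(0.1 * n), int(0.9 * n), n_perm)
    f0 = fs / rr

    p_lock = np.empty(ica.n_components)
    harm_ratio = np.empty(ica.n_components)
    topo = np.empty(ica.n_components)
    for k in range(ica.n_components):
        s = ica.sources[k]
        obs = np.sqrt(np.mean(s[idx].mean(axis=0) ** 2))
        null = np.empty(n_perm)
        for j, sh in enumerate(shifts):
            sidx = (idx + sh) % n
            null[j] = np.sqrt(np.mean(s[sidx].mean(axis=0) ** 2))
        p_lock[k] = (1 + np.sum(null >= obs)) / (1 + n_perm)

        f, pxx = sps.periodogram(s, fs)
        hw = 0.2 * f0
        harm = sum(pxx[(f >= h * f0 - hw) & (f <= h * f0 + hw)].sum()
                   for h in (1, 2, 3))
        neigh = sum(pxx[(f >= h * f0 - hw) & (f <= h * f0 + hw)].sum()
                    for h in (1.5, 2.5, 3.5))
        harm_ratio[k] = harm / neigh if neigh > 0 else np.inf

        a = ica.A[:, k]
        topo[k] = max(_pair_antisymmetry(a, ica.channel_labels, LR_PAIRS),
                      _pair_antisymmetry(a, ica.channel_labels, AP_PAIRS))

    selected = [k for k in range(ica.n_components)
                if p_lock[k] < p_thresh and harm_ratio[k] > harm_thresh
                and topo[k] > topo_thresh]
    scores = {"p_lock": p_lock, "harmonic_ratio": harm_ratio,
              "topo_antisymmetry": topo}
    ica.scores.update(scores)
    ica.selected_bcg = selected
    return scores, selected


def remove_components(ica: ICADecomposition, indices) -> Recording:
    """Reconstruct the recording from all components not in ``indices``."""
    indices = list(indices)
    if any(i < 0 or i >= ica.n_components for i in indices):
        raise IndexError(f"component index out of range 0..{ica.n_components - 1}")
    data = ica.reconstruct(exclude=indices)
    return Recording(list(ica.channel_labels), ica.fs, data, [],
                     {"kind": f"ica-cleaned (removed {sorted(indices)})"})


# ---------------------------------------------------------------------------
# combined and PROJIC methods
# ---------------------------------------------------------------------------

def bcg_combined(rec: Recording, rpeaks: np.ndarray, first: str = "OBS",
                 delay_s: float = 0.21, window_cycles: int = 21,
                 n_pcs: int = 4, ica_seed: int = 0,
                 score_kwargs: dict | None = None
                 ) -> tuple[Recording, CorrectionReport]:
    """AAS-ICA / OBS-ICA: channel-space correction, then ICA removal.

    The first stage runs AAS or OBS as configured; ICA is then fitted to
    the corrected data, BCG components are selected automatically and
    removed.  With zero components selected the result equals the first
    stage alone.
    """
    first = first.upper()
    if first == "AAS":
        stage1, rep1 = bcg_aas(rec, rpeaks, delay_s, window_cycles)
    elif first == "OBS":
        stage1, rep1 = bcg_obs(rec, rpeaks, delay_s, n_pcs)
    else:
        raise ValueError("first stage must be AAS or OBS")
    ica = fit_ica(stage1, seed=ica_seed)
    _, selected = score_bcg_components(ica, rpeaks, rec.fs,
                                       **(score_kwargs or {}))
    if selected:
        cleaned = remove_components(ica, selected)
        out = rec.copy_with(cleaned.data)
    else:
        out = stage1
    rep = CorrectionReport(f"{first.lower()}-ica",
                           {"stage1": rep1.params, "ica_seed": ica_seed},
                           removed=selected)
    rep.warnings += rep1.warnings
    if not selected:
        rep.warnings.append("no BCG components selected: result equals "
                            f"{first} alone")
    return out, rep


def projic(rec: Recording, rpeaks: np.ndarray, inner: str = "AAS",
           ica: ICADecomposition | None = None, selected=None,
           delay_s: float = 0.21, window_cycles: int = 21, n_pcs: int = 4,
           ica_seed: int = 0, score_kwargs: dict | None = None
           ) -> tuple[Recording, CorrectionReport]:
    """PROJIC: AAS/OBS on selected IC time series, then remix to channels.

    The inner correction runs only on the selected source time series
    (unselected sources are bit-identical); all sources are then remixed
    through the mixing matrix.  With an empty selection a warning is
    emitted and the input is returned unchanged.
    """
    if ica is None:
        ica = fit_ica(rec, seed=ica_seed)
    if selected is None:
        _, selected = score_bcg_components(ica, rpeaks, rec.fs,
                                           **(score_kwargs or {}))
    selected = sorted(selected)
    rep = CorrectionReport(f"projic-{inner.lower()}",
                           {"delay_s": delay_s, "window_cycles": window_cycles,
                            "n_pcs": n_pcs, "selected": selected})
    if not selected:
        warnings.warn("PROJIC: empty component selection, identity transform")
        rep.warnings.append("empty selection: identity")
        return rec.copy_with(rec.data.copy()), rep
    sub = Recording([f"ic{k}" for k in selected], rec.fs,
                    ica.sources[selected].copy())
    inner = inner.upper()
    if inner == "AAS":
        corrected, _ = bcg_aas(sub, rpeaks, delay_s, window_cycles)
    elif inner == "OBS":
        corrected, _ = bcg_obs(sub, rpeaks, delay_s, n_pcs)
    else:
        raise ValueError("inner correction must be AAS or OBS")
    S = ica.sources.copy()
    S[selected] = corrected.data
    data = ica.reconstruct(sources=S)
    return rec.copy_with(data), rep


# ---------------------------------------------------------------------------
# ICA feature extraction (IFE)
# ---------------------------------------------------------------------------

def score_alpha_components(ica: ICADecomposition, ec_onsets: np.ndarray,
                           eo_onsets: np.ndarray, fs: float,
                           ratio_thresh: float = 1.5,
                           posterior_thresh: float = 0.5) -> tuple[dict, list]:
    """Score ICs as alpha-related and select those passing all criteria.

    (a) EC-block / EO-block alpha (8-12 Hz) power ratio of the source time
    series above ``ratio_thresh``; (b) a spectral peak within 8-12 Hz
    (Savitzky-Golay smoothed source spectrum); (c) posterior share of the
    absolute mixing-column weights above ``posterior_thresh``.
    """
    n = ica.sources.shape[1]
    L = int(round(2.0 * fs))
    blocks = sorted([(int(s), "EC") for s in ec_onsets] +
                    [(int(s), "EO") for s in eo_onsets])
    spans = {"EC": [], "EO": []}
    bounds = [s for s, _ in blocks[1:]] + [n]
    for (s0, cond), s1 in zip(blocks, bounds):
        for k in range((s1 - s0) // L):
            spans[cond].append(s0 + k * L)
    ratios = np.empty(ica.n_components)
    peak_ok = np.zeros(ica.n_components, dtype=bool)
    post_share = np.empty(ica.n_components)
    post_set = set(POSTERIOR)
    for k in range(ica.n_components):
        s = ica.sources[k]
        def mean_alpha(starts):
            vals, spec_sum = [], None
            for st in starts:
                f, p = epoch_spectrum(s[st:st + L], fs)
                vals.append(band_power(f, p, 8.0, 12.0))
                spec_sum = p if spec_sum is None else spec_sum + p
            return np.mean(vals), f, spec_sum / len(starts)
        ec_p, f, _ = mean_alpha(spans["EC"])
        eo_p, _, _ = mean_alpha(spans["EO"])
        ratios[k] = ec_p / eo_p if eo_p > 0 else np.inf
        _, f_all, spec = mean_alpha(spans["EC"] + spans["EO"])
        desc = alpha_peak_cog(f_all, spec, search=(7.0, 13.0))
        peak_ok[k] = desc.ok and desc.peak_hz is not None and 8.0 <= desc.peak_hz <= 12.0
        a = np.abs(ica.A[:, k])
        post = sum(a[i] for i, lab in enumerate(ica.channel_labels)
                   if lab in post_set)
        post_share[k] = post / a.sum() if a.sum() > 0 else 0.0
    selected = [k for k in range(ica.n_components)
                if ratios[k] > ratio_thresh and peak_ok[k]
                and post_share[k] > posterior_thresh]
    scores = {"ec_eo_ratio": ratios, "alpha_peak_in_band": peak_ok,
              "posterior_share": post_share}
    ica.scores.update(scores)
    ica.selected_alpha = selected
    return scores, selected


def ife_alpha(ica: ICADecomposition, ec_onsets: np.ndarray,
              eo_onsets: np.ndarray, fs: float,
              ratio_thresh: float = 1.5, posterior_thresh: float = 0.5
              ) -> tuple[Recording, CorrectionReport]:
    """ICA feature extraction: reconstruct from retained alpha components.

    Raises when no component meets all retention criteria (review the
    thresholds or the decomposition in that case).
    """
    _, selected = score_alpha_components(ica, ec_onsets, eo_onsets, fs,
                                         ratio_thresh, posterior_thresh)
    if not selected:
        raise ValueError("IFE retained zero components; review the retention "
                         "thresholds or the ICA decomposition")
    data = ica.reconstruct(include=selected) - ica.mean[:, None]
    rec = Recording(list(ica.channel_labels), fs, data, [],
                    {"kind": f"ife (retained {selected})"})
    rep = CorrectionReport("ife", {"ratio_thresh": ratio_thresh,
                                   "posterior_thresh": posterior_thresh},
                           retained=selected)
    return rec, rep


# ---------------------------------------------------------------------------
# dispatcher used by the pipeline and CLI
# ---------------------------------------------------------------------------

def apply_method(rec: Recording, method: str, rpeaks: np.ndarray,
                 ec_onsets: np.ndarray | None = None,
                 eo_onsets: np.ndarray | None = None,
                 delay_s: float = 0.21, window_cycles: int = 21,
                 n_pcs: int = 4, ica_seed: int = 0
                 ) -> tuple[Recording, CorrectionReport]:
    """Run one named BCG handling strategy on a (GA-corrected) recording."""
    method = method.lower()
    if method == "none":
        return rec.copy_with(rec.data.copy()), CorrectionReport("none", {})
    if method == "aas":
        return bcg_aas(rec, rpeaks, delay_s, window_cycles)
    if method == "obs":
        return bcg_obs(rec, rpeaks, delay_s, n_pcs)
    if method == "ica":
        ica = fit_ica(rec, seed=ica_seed)
        _, selected = score_bcg_components(ica, rpeaks, rec.fs, seed=ica_seed)
        rep = CorrectionReport("ica", {"ica_seed": ica_seed}, removed=selected)
        if not selected:
            rep.warnings.append("no BCG components selected: identity")
            return rec.copy_with(rec.data.copy()), rep
        out = remove_components(ica, selected)
        return rec.copy_with(out.data), rep
    if method in ("obs-ica", "aas-ica"):
        return bcg_combined(rec, rpeaks, first=method.split("-")[0].upper(),
                            delay_s=delay_s, window_cycles=window_cycles,
                            n_pcs=n_pcs, ica_seed=ica_seed)
    if method in ("projic-aas", "projic-obs"):
        return projic(rec, rpeaks, inner=method.split("-")[1].upper(),
                      delay_s=delay_s, window_cycles=window_cycles,
                      n_pcs=n_pcs, ica_seed=ica_seed)
    if method == "ife":
        if ec_onsets is None or eo_onsets is None:
            raise ValueError("IFE requires EC/EO block onsets")
        ica = fit_ica(rec, seed=ica_seed)
        return ife_alpha(ica, ec_onsets, eo_onsets, rec.fs)
    raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
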