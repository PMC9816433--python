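"""EEG-informed fMRI: alpha-power BOLD predictors, voxelwise GLM, permutation.

The predictor for one subject is the per-epoch occipital alpha absolute
power, with rejected epochs filled by neighbor interpolation, convolved
with a gamma hemodynamic response function, sampled at the TR grid and
mean-centered.  First-level inference is ordinary least squares per voxel
with polynomial drift nuisance columns and a one-sided (negative) contrast
on the alpha regressor, Bonferroni-corrected across voxels.  Group
inference is a sign-flipping max-statistic permutation of the one-sample t.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .spectral import BandScheme, TRADITIONAL_BANDS, epoch_spectrum, band_power

__all__ = ["Regressor", "GLMResult", "interpolate_rejected", "gamma_hrf",
           "build_predictor", "glm_fit", "group_permutation"]


@dataclass
class Regressor:
    """Alpha-power BOLD predictor and its provenance."""

    raw: np.ndarray              # per-epoch alpha power (after interpolation)
    interpolated: np.ndarray     # mask of epochs that were filled in
    predictor: np.ndarray        # convolved, TR-sampled, mean-centered
    channel: str


@dataclass
class GLMResult:
    """Per-voxel first-level results for the alpha regressor."""

    beta: np.ndarray
    t: np.ndarray
    p_unc: np.ndarray            # one-sided p for the requested contrast
    sig_mask: np.ndarray         # Bonferroni-corrected significance
    contrast: str                # 'less' or 'greater'
    dof: int


def _ols_t(Y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """OLS beta and t for the last design column, rows of Y at once."""
    pinv = np.linalg.pinv(X)
    betas = Y @ pinv.T
    resid = Y - betas @ X.T
    dof = Y.shape[1] - X.shape[1]
    sigma2 = (resid ** 2).sum(axis=1) / dof
    covx = np.linalg.inv(X.T @ X)[-1, -1]
    se = np.sqrt(sigma2 * covx)
    b = betas[:, -1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, b / se, 0.0)
    return b, t, dof


def interpolate_rejected(series: np.ndarray, rejected: np.ndarray) -> np.ndarray:
    """Replace rejected epochs by the mean of the nearest kept neighbors.

    A run of rejected epochs takes the mean of the nearest non-rejected
    value on each side; runs touching a boundary take the single nearest
    neighbor.  Raises if every epoch is rejected.
    """
    series = np.asarray(series, dtype=float).copy()
    rejected = np.asarray(rejected, dtype=bool)
    kept = np.flatnonzero(~rejected)
    if len(kept) == 0:
        raise ValueError("all epochs rejected; nothing to interpolate from")
    for i in np.flatnonzero(rejected):
        before = kept[kept < i]
        after = kept[kept > i]
        if len(before) and len(after):
            series[i] = 0.5 * (series[before[-1]] + series[after[0]])
        elif len(before):
            series[i] = series[before[-1]]
        else:
            series[i] = series[after[0]]
    return series


def gamma_hrf(dt: float, peak_s: float = 6.0, dispersion_s: float = 1.2,
              length_s: float = 32.0) -> np.ndarray:
    """Unit-sum gamma-density HRF kernel sampled at dt.

    Parameterized by the mode (``peak_s``) and the gamma scale
    (``dispersion_s``): shape = peak/scale + 1, so the density's mode falls
    at the configured peak.
    """
    if dt <= 0 or peak_s <= 0 or dispersion_s <= 0:
        raise ValueError("HRF parameters must be positive")
    shape = peak_s / dispersion_s + 1.0
    t = np.arange(0, length_s + dt / 2, dt)
    k = stats.gamma.pdf(t, a=shape, scale=dispersion_s)
    s = k.sum()
    if s <= 0:
        raise ValueError("degenerate HRF kernel")
    return k / s


def build_predictor(epochs, channel: str | None = None,
                    scheme: BandScheme = TRADITIONAL_BANDS,
                    hrf: np.ndarray | None = None, tr_s: float = 2.0,
                    n_volumes: int | None = None) -> Regressor:
    """Alpha-power regressor from an EpochSet.

    Per-epoch alpha absolute power on the chosen occipital channel (when
    ``channel`` is None, O1 or O2 is picked automatically as the one with
    the larger EC/EO alpha ratio), rejected epochs interpolated, convolved
    with the HRF kernel, truncated to the volume count and mean-centered.
    Epoch length must equal the TR so epochs map one-to-one onto volumes.
    """
    if abs(epochs.epoch_len / epochs.fs - tr_s) > 1e-9:
        raise ValueError("epoch length must equal the TR")
    lo, hi = scheme.band_edges("alpha")
    if channel is None:
        channel = _pick_occipital(epochs, scheme)
    c = epochs.channel_labels.index(channel)
    raw = np.empty(epochs.n_epochs)
    for i in range(epochs.n_epochs):
        f, p = epoch_spectrum(epochs.epochs[i, c], epochs.fs)
        raw[i] = band_power(f, p, lo, hi)
    filled = interpolate_rejected(raw, epochs.rejected)
    if hrf is None:
        hrf = gamma_hrf(tr_s)
    n_vol = n_volumes if n_volumes is not None else epochs.n_epochs
    if n_vol > epochs.n_epochs:
        raise ValueError("volume span exceeds the epoch span")
    # pad with the first value so the kernel starts in steady state
    # (a constant power series then yields an exactly constant predictor)
    pad = len(hrf) - 1
    conv = np.convolve(np.r_[np.full(pad, filled[0]), filled], hrf)
    pred = conv[pad:pad + n_vol]
    pred = pred - pred.mean()
    return Regressor(filled, epochs.rejected.copy(), pred, channel)


def _pick_occipital(epochs, scheme) -> str:
    from .spectral import ec_eo_alpha_ratio
    best, best_r = "O1", -np.inf
    for ch in ("O1", "O2"):
        if ch not in epochs.channel_labels:
            continue
        try:
            r = ec_eo_alpha_ratio(epochs, channels=(ch,), scheme=scheme)
        except ValueError:
            r = -np.inf
        if r > best_r:
            best, best_r = ch, r
    return best


def glm_fit(bold: np.ndarray, regressor: np.ndarray, drift_order: int = 2,
            alternative: str = "less", alpha: float = 0.05,
            prewhiten: bool = True, correction: str = "fdr") -> GLMResult:
    """Voxelwise GLM of BOLD on the alpha predictor plus polynomial drift.

    The design is [intercept, drift(1..order), predictor]; the t statistic
    and one-sided p refer to the predictor coefficient under the requested
    alternative (default 'less': beta < 0).  ``sig_mask`` applies a
    Bonferroni correction across voxels.

    With ``prewhiten`` (default) an AR(1) coefficient is estimated from the
    OLS residuals of each voxel and the model is refitted on the
    first-differenced (Cochrane-Orcutt) data, so the null t distribution is
    calibrated under temporally autocorrelated noise.

    ``correction`` selects the across-voxel multiplicity control for
    ``sig_mask``: Benjamini-Hochberg FDR (default, the standard voxelwise
    choice when cluster-based enhancement is not used) or Bonferroni.
    """
    bold = np.atleast_2d(np.asarray(bold, dtype=float))
    x = np.asarray(regressor, dtype=float)
    n = bold.shape[1]
    if len(x) != n:
        raise ValueError("regressor length must match the BOLD time dimension")
    tgrid = np.linspace(-1, 1, n)
    cols = [np.ones(n)] + [tgrid ** k for k in range(1, drift_order + 1)] + [x]
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError("rank-deficient design: predictor is collinear with "
                         "the intercept/drift columns")
    b, t, dof = _ols_t(bold, X)
    if prewhiten:
        pinv = np.linalg.pinv(X)
        resid = bold - (bold @ pinv.T) @ X.T
        num = (resid[:, 1:] * resid[:, :-1]).sum(axis=1)
        den = (resid ** 2).sum(axis=1)
        with np.errstate(invalid="ignore"):
            rho = np.clip(np.where(den > 0, num / den, 0.0), -0.95, 0.95)
        b = np.empty(bold.shape[0])
        t = np.empty(bold.shape[0])
        # batch voxels on a coarse rho grid: one transformed design per bin
        bins = np.round(rho, 2)
        for r in np.unique(bins):
            sel = bins == r
            Xw = X[1:] - r * X[:-1]
            Yw = bold[sel, 1:] - r * bold[sel, :-1]
            b[sel], t[sel], dof = _ols_t(Yw, Xw)
    if alternative == "less":
        p = stats.t.cdf(t, dof)
    elif alternative == "greater":
        p = stats.t.sf(t, dof)
    else:
        raise ValueError("alternative must be 'less' or 'greater'")
    if correction == "fdr":
        sig = stats.false_discovery_control(p) < alpha
    elif correction == "bonferroni":
        sig = p < alpha / bold.shape[0]
    else:
        raise ValueError("correction must be 'fdr' or 'bonferroni'")
    return GLMResult(beta=b, t=t, p_unc=p, sig_mask=sig,
                     contrast=alternative, dof=dof)


def group_permutation(subject_betas: np.ndarray, n_perm: int = 1000,
                      alternative: str = "less", alpha: float = 0.05,
                      seed: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Sign-flipping max-statistic permutation of the one-sample t.

    ``subject_betas`` is subjects x voxels.  Under the null the per-subject
    effects are symmetric around zero, so each permutation flips subject
    signs and records the extreme voxelwise t; the familywise-corrected p
    of a voxel is the fraction of permutations whose extreme statistic is
    at least as extreme as its observed t.  When ``n_perm`` covers all
    2^n_subjects sign patterns the enumeration is exhaustive.

    Returns (corrected p per voxel, significance mask at ``alpha``).
    """
    B = np.atleast_2d(np.asarray(subject_betas, dtype=float))
    ns, nv = B.shape
    if ns < 6:
        raise ValueError("group permutation needs at least 6 subjects")
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations: corrected p is coarse")

    def tstat(M):
        m = M.mean(axis=0)
        sd = M.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(sd > 0, m / (sd / np.sqrt(ns)), 0.0)

    t_obs = tstat(B)
    exhaustive = n_perm >= 2 ** ns
    if exhaustive:
        signs_iter = ((np.array([(k >> i) & 1 for i in range(ns)]) * 2 - 1)
                      for k in range(2 ** ns))
        total = 2 ** ns
    else:
        rng = np.random.default_rng(seed)
        def gen():
            yield np.ones(ns, dtype=int)  # identity permutation included
            for _ in range(n_perm - 1):
                yield rng.choice([-1, 1], ns)
        signs_iter = gen()
        total = n_perm
    extremes = np.empty(total)
    for k, s in enumerate(signs_iter):
        tp = tstat(B * s[:, None])
        extremes[k] = tp.min() if alternative == "less" else tp.max()
    if alternative == "less":
        p_corr = np.array([(extremes <= t).sum() for t in t_obs]) / total
    else:
        p_corr = np.array([(extremes >= t).sum() for t in t_obs]) / total
    return p_corr, p_corr < alpha
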