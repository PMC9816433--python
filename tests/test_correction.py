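"""Artifact correction: AAS/OBS oracles, ICA recovery and selection, PROJIC, IFE."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment
from scipy.signal import periodogram

from bcg_preserve.core_io import Recording, EventTrain
from bcg_preserve.correction import (ga_aas, bcg_aas, bcg_obs, fit_ica,
                                     score_bcg_components, remove_components,
                                     bcg_combined, projic, ife_alpha,
                                     score_alpha_components)
from bcg_preserve.synthetic import (SimulationConfig, assemble_subject,
                                    gen_bcg_artifact)
from bcg_preserve.preprocess import bandpass, epoch
from bcg_preserve.spectral import epoch_spectrum, band_power, ec_eo_alpha_ratio
from conftest import make_recording


def fundamental_power(x, fs, f0):
    f, p = periodogram(x, fs)
    return p[(f >= 0.8 * f0) & (f <= 1.2 * f0)].sum()


# ---------------------------------------------------------------------------
# gradient AAS
# ---------------------------------------------------------------------------

class TestGaAas:
    def test_periodic_artifact_cancelled_exactly(self):
        cfg = SimulationConfig(seed=0, duration_s=60.0)
        tr = np.arange(0, cfg.n_samples, 2000)
        from bcg_preserve.synthetic import gen_gradient_artifact
        ga = gen_gradient_artifact(cfg, tr, clean_rms_uv=10.0)
        rec = make_recording(ga, cfg.fs, labels=list(cfg.channels))
        out, _ = ga_aas(rec, tr)
        core = out.data[:, 2000:-2000]
        assert np.sqrt(np.mean(core ** 2)) < 1e-8 * np.sqrt(np.mean(ga ** 2))

    def test_eeg_template_leakage_bounded(self):
        """Sliding mean of w volumes leaks ~1/sqrt(w) of the EEG RMS."""
        cfg = SimulationConfig(seed=1, duration_s=60.0)
        rec, gt = assemble_subject(cfg)
        eeg = rec.pick(list(cfg.channels))
        contaminated = gt.clean.data + gt.ga
        out, _ = ga_aas(eeg.copy_with(contaminated))
        err = out.data - gt.clean.data
        rel = np.sqrt(np.mean(err ** 2)) / np.sqrt(np.mean(gt.clean.data ** 2))
        assert rel < 1.2 / np.sqrt(5)

    def test_few_volumes_edge_truncation_warns(self):
        rec = make_recording(np.tile(np.sin(np.arange(2000) / 50), 3)[None, :],
                             1000.0)
        out, rep = ga_aas(rec, np.array([0, 2000, 4000]), window_volumes=5)
        assert any("edge-truncated" in w for w in rep.warnings)
        assert np.max(np.abs(out.data)) < 1e-10  # still exact for periodic input

    def test_irregular_tr_spacing_errors(self):
        rec = make_recording(np.zeros((1, 10_000)), 1000.0)
        with pytest.raises(ValueError, match="irregular"):
            ga_aas(rec, np.array([0, 2000, 4100]))


# ---------------------------------------------------------------------------
# BCG AAS
# ---------------------------------------------------------------------------

def bcg_only_recording(seed=0, duration=120.0, jitter=0.0, rr_jitter=0.0):
    cfg = SimulationConfig(seed=seed, duration_s=duration, bcg_jitter=jitter,
                           rr_jitter_s=rr_jitter)
    rpeaks = np.arange(500, cfg.n_samples - 1000, int(cfg.rr_mean_s * cfg.fs))
    art = gen_bcg_artifact(cfg, rpeaks)
    rec = Recording(list(cfg.channels), cfg.fs, art)
    return cfg, rec, rpeaks, art


class TestBcgAas:
    def test_jitter_free_artifact_cancelled(self):
        cfg, rec, rpeaks, art = bcg_only_recording()
        out, _ = bcg_aas(rec, rpeaks)
        core = slice(20_000, -20_000)
        res = np.sqrt(np.mean(out.data[:, core] ** 2))
        assert res < 0.01 * np.sqrt(np.mean(art[:, core] ** 2))

    def test_amplitude_jitter_fundamental_reduced(self):
        cfg, rec, rpeaks, art = bcg_only_recording(jitter=0.1)
        out, _ = bcg_aas(rec, rpeaks)
        f0 = cfg.fs / np.median(np.diff(rpeaks)) * 1.0
        f0 = 1.0 / cfg.rr_mean_s
        before = fundamental_power(art[5], cfg.fs, f0)
        after = fundamental_power(out.data[5], cfg.fs, f0)
        assert after <= 0.2 * before

    def test_alpha_power_closer_to_clean_in_most_epochs(self):
        cfg = SimulationConfig(seed=2, duration_s=120.0)
        rec, gt = assemble_subject(cfg)
        contaminated = gt.clean.data + gt.bcg  # no GA: isolate the BCG effect
        rec_c = Recording(list(cfg.channels), cfg.fs, contaminated)
        out, _ = bcg_aas(rec_c, gt.rpeaks)
        o1 = list(cfg.channels).index("O1")
        L = int(2 * cfg.fs)
        wins = 0
        n_ep = cfg.n_samples // L
        for i in range(n_ep):
            s = slice(i * L, (i + 1) * L)
            p_clean = band_power(*epoch_spectrum(gt.clean.data[o1][s], cfg.fs), 8, 13)
            p_dirty = band_power(*epoch_spectrum(contaminated[o1][s], cfg.fs), 8, 13)
            p_corr = band_power(*epoch_spectrum(out.data[o1][s], cfg.fs), 8, 13)
            if abs(p_corr - p_clean) <= abs(p_dirty - p_clean):
                wins += 1
        assert wins / n_ep >= 0.9

    def test_fundamental_never_increased(self):
        for seed in (0, 1, 2):
            cfg, rec, rpeaks, art = bcg_only_recording(seed=seed, duration=60.0,
                                                       jitter=0.1)
            out, _ = bcg_aas(rec, rpeaks)
            f0 = 1.0 / cfg.rr_mean_s
            for c in (0, 9, 17):
                assert (fundamental_power(out.data[c], cfg.fs, f0)
                        <= fundamental_power(rec.data[c], cfg.fs, f0))

    def test_too_few_rpeaks_errors(self):
        rec = make_recording(np.zeros((1, 10_000)), 1000.0)
        with pytest.raises(ValueError):
            bcg_aas(rec, np.array([500]))


# ---------------------------------------------------------------------------
# OBS
# ---------------------------------------------------------------------------

class TestObs:
    @staticmethod
    def rank_k_artifact(n_cycles=120, L=900, k=4, seed=0, fs=1000.0):
        """Artifact epochs drawn from a fixed rank-k waveform basis."""
        rng = np.random.default_rng(seed)
        t = np.arange(L) / fs
        basis = np.stack([np.sin(2 * np.pi * (3 + 2 * j) * t) * np.hanning(L)
                          for j in range(k)])
        rpeaks = np.arange(300, n_cycles * L, L)
        data = np.zeros((2, rpeaks[-1] + L + 500))
        delay = int(0.21 * fs)
        for r in rpeaks:
            coefs = rng.normal(0, 30, k)
            seg = coefs @ basis
            data[:, r + delay - 225:r + delay - 225 + L] += seg
        return Recording(["a", "b"], fs, data), rpeaks, data.copy()

    def test_rank4_artifact_suppressed(self):
        rec, rpeaks, art = self.rank_k_artifact(k=4)
        out, _ = bcg_obs(rec, rpeaks, n_pcs=4)
        core = slice(5000, -5000)
        assert (np.mean(out.data[:, core] ** 2)
                < 0.01 * np.mean(art[:, core] ** 2))

    def test_rank1_artifact_with_four_pcs(self):
        rec, rpeaks, art = self.rank_k_artifact(k=1, seed=1)
        out, _ = bcg_obs(rec, rpeaks, n_pcs=4)
        core = slice(5000, -5000)
        assert (np.mean(out.data[:, core] ** 2)
                < 1e-4 * np.mean(art[:, core] ** 2))

    def test_clean_eeg_distortion_bounded_by_projection(self):
        """On clean EEG + rank-1 artifact, distortion ~ projection onto basis."""
        rec, rpeaks, art = self.rank_k_artifact(k=1, seed=2)
        rng = np.random.default_rng(3)
        clean = rng.normal(0, 10, rec.data.shape)
        mixed = Recording(rec.channel_labels, rec.fs, rec.data + clean)
        out, _ = bcg_obs(mixed, rpeaks, n_pcs=4)
        err = out.data - clean
        core = slice(5000, -5000)
        # distortion is the projection of the EEG onto the fitted basis
        # (mean + 4 sample PCs, which partially overfit the epoch noise):
        # bounded well below the EEG power, and far above zero
        ratio = np.mean(err[:, core] ** 2) / np.mean(clean[:, core] ** 2)
        assert 0.0 < ratio < 0.10

    def test_zero_pcs_is_identity(self):
        rec, rpeaks, _ = self.rank_k_artifact(n_cycles=30)
        out, _ = bcg_obs(rec, rpeaks, n_pcs=0)
        np.testing.assert_array_equal(out.data, rec.data)

    def test_insufficient_cycles_errors(self):
        rec = make_recording(np.zeros((1, 5000)), 1000.0)
        with pytest.raises(ValueError):
            bcg_obs(rec, np.array([500, 1400, 2300]), n_pcs=4)


# ---------------------------------------------------------------------------
# ICA
# ---------------------------------------------------------------------------

def three_source_mixture(seed=0, fs=250.0, duration=60.0):
    """Alpha burst + BCG train + 1/f noise through a random full-rank mixing."""
    rng = np.random.default_rng(seed)
    n = int(fs * duration)
    t = np.arange(n) / fs
    env = (np.sin(2 * np.pi * t / 20) > 0).astype(float)
    alpha = env * np.sin(2 * np.pi * 10 * t + rng.uniform(0, 6))
    cfg = SimulationConfig(seed=seed, duration_s=duration, fs=fs)
    rpeaks = np.arange(int(0.5 * fs), n - int(fs), int(0.9 * fs))
    bcg = gen_bcg_artifact(cfg, rpeaks)[10]
    from bcg_preserve.synthetic import _one_over_f
    pink = _one_over_f(n, fs, 1.0, 1.0, rng)
    S = np.vstack([alpha / alpha.std(), bcg / bcg.std(), pink / pink.std()])
    A = rng.normal(size=(6, 3))
    return A @ S, S, rpeaks


def matched_correlations(S_est, S_true):
    k = S_true.shape[0]
    C = np.zeros((S_est.shape[0], k))
    for i in range(S_est.shape[0]):
        for j in range(k):
            C[i, j] = abs(np.corrcoef(S_est[i], S_true[j])[0, 1])
    ri, ci = linear_sum_assignment(-C)
    return C[ri, ci]


class TestICA:
    def test_three_source_recovery(self):
        X, S, _ = three_source_mixture(seed=0)
        ica = fit_ica(X, n_components=3, seed=0, fit_decimate=1)
        cors = matched_correlations(ica.sources, S)
        assert cors.mean() >= 0.95

    def test_reconstruction_identity(self):
        X, _, _ = three_source_mixture(seed=1)
        ica = fit_ica(X, n_components=X.shape[0], seed=0, fit_decimate=1)
        err = np.abs(ica.reconstruct() - X).max() / np.abs(X).max()
        assert err < 1e-6

    def test_seed_determinism(self):
        X, _, _ = three_source_mixture(seed=2)
        W1 = fit_ica(X, n_components=3, seed=5, fit_decimate=1).W
        W2 = fit_ica(X, n_components=3, seed=5, fit_decimate=1).W
        np.testing.assert_array_equal(W1, W2)

    def test_rank_deficient_reduces_components(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(2, 8000))
        X = np.vstack([base, base.sum(axis=0, keepdims=True)])
        with pytest.warns(UserWarning, match="rank"):
            ica = fit_ica(X, seed=0, fit_decimate=1)
        assert ica.n_components == 2


class TestComponentScoring:
    def test_bcg_component_selected_alpha_not(self, prepped_subject, subject_ica):
        cfg, rec, gt, filt = prepped_subject
        ica = subject_ica
        scores, selected = score_bcg_components(ica, gt.rpeaks, cfg.fs, seed=0)
        # identify the components by correlation with the known latent signals
        t5 = list(cfg.channels).index("T5")
        bcg_corr = [abs(np.corrcoef(s, gt.bcg[t5])[0, 1]) for s in ica.sources]
        bcg_comp = int(np.argmax(bcg_corr))
        ascores, alpha_sel = score_alpha_components(
            ica, rec.get_events("EC_ONSET"), rec.get_events("EO_ONSET"), cfg.fs)
        assert bcg_comp in selected
        assert len(alpha_sel) >= 1
        alpha_comp = alpha_sel[int(np.argmax(
            [ascores["ec_eo_ratio"][k] for k in alpha_sel]))]
        assert alpha_comp not in selected
        assert scores["p_lock"][alpha_comp] >= 0.01 or \
            scores["harmonic_ratio"][alpha_comp] <= 2.0

    def test_shuffled_rpeaks_not_cardiac_locked(self, prepped_subject, subject_ica):
        cfg, rec, gt, filt = prepped_subject
        rng = np.random.default_rng(0)
        fake = np.sort(rng.choice(cfg.n_samples - 1000, len(gt.rpeaks),
                                  replace=False))
        scores, selected = score_bcg_components(subject_ica, fake, cfg.fs, seed=1)
        assert np.median(scores["p_lock"]) > 0.2
        assert selected == []


class TestRemoveComponents:
    def test_remove_none_reproduces_input(self, prepped_subject, subject_ica):
        _, _, _, filt = prepped_subject
        out = remove_components(subject_ica, [])
        err = np.abs(out.data - filt.data).max() / np.abs(filt.data).max()
        assert err < 1e-6

    def test_remove_all_gives_zero(self, subject_ica):
        out = remove_components(subject_ica,
                                list(range(subject_ica.n_components)))
        assert np.allclose(out.data, 0.0)

    def test_out_of_range_errors(self, subject_ica):
        with pytest.raises(IndexError):
            remove_components(subject_ica, [99])

    def test_removing_bcg_recovers_clean_source(self):
        X, S, _ = three_source_mixture(seed=4)
        ica = fit_ica(X, n_components=3, seed=0, fit_decimate=1)
        bcg_idx = int(np.argmax([abs(np.corrcoef(s, S[1])[0, 1])
                                 for s in ica.sources]))
        out = remove_components(ica, [bcg_idx])
        # the alpha source must survive in the cleaned mixture
        alpha_corr = max(abs(np.corrcoef(out.data[c], S[0])[0, 1])
                         for c in range(out.n_channels))
        assert alpha_corr >= 0.9


class TestCombinedAndProjic:
    def test_aas_ica_with_no_selection_equals_aas(self):
        cfg, rec, rpeaks, _ = bcg_only_recording(seed=3, duration=60.0,
                                                 jitter=0.1)
        noisy = rec.copy_with(
            rec.data + np.random.default_rng(0).normal(0, 5, rec.data.shape))
        aas_only, _ = bcg_aas(noisy, rpeaks)
        combined, rep = bcg_combined(
            noisy, rpeaks, first="AAS",
            score_kwargs={"p_thresh": 0.0})  # impossible threshold: select none
        np.testing.assert_allclose(combined.data, aas_only.data)
        assert any("equals" in w for w in rep.warnings)
        assert rep.params["stage1"]["window_cycles"] == 21

    def test_projic_all_components_aas_equals_channel_aas(self):
        cfg = SimulationConfig(seed=5, duration_s=60.0)
        rec, gt = assemble_subject(cfg)
        data = gt.clean.data + gt.bcg
        data = data - data.mean(axis=1, keepdims=True)
        noisy = Recording(list(cfg.channels), cfg.fs, data)
        ica = fit_ica(noisy, seed=0)
        chan, _ = bcg_aas(noisy, gt.rpeaks)
        proj, _ = projic(noisy, gt.rpeaks, inner="AAS", ica=ica,
                         selected=list(range(ica.n_components)))
        scale = np.abs(chan.data).max()
        assert np.abs(proj.data - chan.data).max() / scale < 1e-6

    def test_projic_unselected_sources_untouched(self, prepped_subject,
                                                 subject_ica):
        cfg, rec, gt, filt = prepped_subject
        ica = subject_ica
        before = ica.sources.copy()
        projic(filt, gt.rpeaks, inner="AAS", ica=ica, selected=[0])
        np.testing.assert_array_equal(ica.sources, before)

    def test_projic_selected_periodic_source_cancelled(self):
        cfg, rec, rpeaks, art = bcg_only_recording(seed=6, duration=60.0)
        rng = np.random.default_rng(1)
        noise = rng.normal(0, 5, rec.data.shape)
        mix = rec.copy_with(rec.data + noise)
        ica = fit_ica(mix, seed=0)
        t5 = 14
        # the artifact spans several spatial components; select all of them
        sel = [k for k, s in enumerate(ica.sources)
               if abs(np.corrcoef(s, art[t5])[0, 1]) > 0.1
               or max(abs(np.corrcoef(s, art[c])[0, 1]) for c in (0, 9)) > 0.1]
        out, _ = projic(mix, rpeaks, inner="AAS", ica=ica, selected=sel)
        f0 = 1.0 / cfg.rr_mean_s
        assert (fundamental_power(out.data[t5], cfg.fs, f0)
                < 0.2 * fundamental_power(mix.data[t5], cfg.fs, f0))

    def test_projic_empty_selection_is_identity_with_warning(self,
                                                             prepped_subject,
                                                             subject_ica):
        cfg, rec, gt, filt = prepped_subject
        with pytest.warns(UserWarning, match="empty"):
            out, _ = projic(filt, gt.rpeaks, ica=subject_ica, selected=[])
        np.testing.assert_array_equal(out.data, filt.data)


class TestIFE:
    def test_single_alpha_component_retained(self, prepped_subject,
                                             subject_ica):
        cfg, rec, gt, filt = prepped_subject
        out, rep = ife_alpha(subject_ica, rec.get_events("EC_ONSET"),
                             rec.get_events("EO_ONSET"), cfg.fs)
        assert 1 <= len(rep.retained) <= 3
        # the retained reconstruction must carry the task reactivity
        eps = epoch(Recording(list(cfg.channels), cfg.fs, out.data,
                              [e for e in rec.events if "ONSET" in e.label]),
                    2.0)
        ratio = ec_eo_alpha_ratio(eps)
        assert ratio == pytest.approx(gt.ec_eo_ratio, rel=0.25)

    def test_bcg_component_not_retained(self, prepped_subject, subject_ica):
        cfg, rec, gt, filt = prepped_subject
        t5 = list(cfg.channels).index("T5")
        bcg_comp = int(np.argmax([abs(np.corrcoef(s, gt.bcg[t5])[0, 1])
                                  for s in subject_ica.sources]))
        assert bcg_comp not in subject_ica.selected_alpha

    def test_zero_retained_raises(self, prepped_subject, subject_ica):
        cfg, rec, gt, filt = prepped_subject
        with pytest.raises(ValueError, match="zero components"):
            ife_alpha(subject_ica, rec.get_events("EC_ONSET"),
                      rec.get_events("EO_ONSET"), cfg.fs,
                      ratio_thresh=1e9)


def test_every_method_preserves_shape(prepped_subject):
    from bcg_preserve.correction import apply_method
    cfg, rec, gt, filt = prepped_subject
    for method in ("none", "aas", "obs"):
        out, _ = apply_method(filt, method, gt.rpeaks)
        assert out.data.shape == filt.data.shape
        assert out.channel_labels == filt.channel_labels
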