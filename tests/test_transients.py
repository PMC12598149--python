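"""Transient detection tests: staged rules, brute-force oracle, validation."""

import numpy as np
import pytest

from caburst import synthetic as syn
from caburst.preprocess import DeconvParams, DeconvResult, condition_trace, deconvolve
from caburst.transients import (
    DetectionParams,
    NoiseEstimate,
    TransientEvent,
    detect_transients,
    estimate_noise,
    validate_transients,
)


def brute_force_detect(s, f, params, sigma):
    """Independent literal implementation of detection rules (i)-(v)."""
    s = np.asarray(s, float)
    f = np.asarray(f, float)
    sm = params.align_smooth_frames
    if sm > 1:
        f = np.convolve(f, np.ones(sm) / sm, mode="same")
    sigma_eff = sigma / np.sqrt(sm)
    if s.max() <= 0:
        return []
    above = s > params.deconv_frac * s.max()
    # (ii) runs
    cands = []
    i = 0
    while i < len(s):
        if above[i]:
            j = i
            while j + 1 < len(s) and above[j + 1]:
                j += 1
            run = np.arange(i, j + 1)
            best = run[0]
            for k in run:
                if s[k] > s[best]:
                    best = k
            cands.append((best, s[best]))
            i = j + 1
        else:
            i += 1
    # (iii) align, collapse duplicates
    aligned = {}
    for frame, damp in cands:
        lo, hi = max(frame - params.align_halfwidth_frames, 0), min(
            frame + params.align_halfwidth_frames + 1, len(f)
        )
        best = lo
        for k in range(lo, hi):
            if f[k] > f[best]:
                best = k
        famp = f[best]
        if best in aligned:
            aligned[best] = (max(aligned[best][0], famp), max(aligned[best][1], damp))
        else:
            aligned[best] = (famp, damp)
    # (iv) amplitude
    events = [
        (p, fa, da)
        for p, (fa, da) in sorted(aligned.items())
        if fa >= params.amp_n_sigma * sigma_eff
    ]
    # (v) moving filter
    out = []
    for p, fa, da in events:
        mx = max(
            d2 for p2, _, d2 in events if abs(p2 - p) <= params.movfilt_window_frames
        )
        if da >= params.movfilt_rel_amp * mx:
            out.append(p)
    return out


class TestEstimateNoise:
    def test_white_noise_recovered(self):
        ok = 0
        for seed in range(200):
            est = estimate_noise(
                np.random.default_rng(seed).normal(0, 1, 6000)
            ).sigma
            ok += 0.9 <= est <= 1.1
        assert ok >= 190

    def test_constant_trace_zero(self):
        assert estimate_noise(np.full(500, 3.3)).sigma == 0

    def test_robust_to_sparse_transients(self, indicator, quiet_noise):
        rng = np.random.default_rng(11)
        base = rng.normal(0, 0.2, 6000)
        spk = np.sort(rng.uniform(0, 590, 20))
        kern_trace, _ = syn.render_trace(
            spk, indicator, quiet_noise, 10.0, 600.0, np.random.default_rng(0)
        )
        est_with = estimate_noise(base + kern_trace).sigma
        est_free = estimate_noise(base).sigma
        assert abs(est_with - est_free) / est_free < 0.15

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            estimate_noise(np.zeros(50))


class TestDetectTransients:
    def test_zero_deconv_no_events(self):
        dec = DeconvResult(C=np.zeros(200), s=np.zeros(200), gamma=0.85)
        out = detect_transients(
            dec, np.zeros(200), DetectionParams(), NoiseEstimate(1.0)
        )
        assert out == []

    def test_staged_rules_on_constructed_trace(self):
        # major transient at frame 100 and a small nearby blip at frame 107
        n = 200
        s = np.zeros(n)
        s[100] = 1.0
        s[107] = 0.05
        f = np.zeros(n)
        f[98:103] = [0.2, 0.7, 1.0, 0.5, 0.1]
        f[107:110] = [0.1, 0.3, 0.1]
        p_strict = DetectionParams(
            deconv_frac=0.1, amp_n_sigma=0.0, align_smooth_frames=1
        )
        ev = detect_transients(
            DeconvResult(f, s, 0.85), f, p_strict, NoiseEstimate(0.01)
        )
        # the blip fails the deconvolved-fraction threshold (stage i)
        assert [e.peak_frame for e in ev] == [100]
        p_loose = DetectionParams(
            deconv_frac=0.01, amp_n_sigma=0.0, align_smooth_frames=1
        )
        ev2 = detect_transients(
            DeconvResult(f, s, 0.85), f, p_loose, NoiseEstimate(0.01)
        )
        # now the blip passes stage (i) but the moving filter removes it
        assert [e.peak_frame for e in ev2] == [100]
        assert 95 <= ev2[0].peak_frame <= 105

    def test_matches_brute_force_oracle_on_random_instances(self):
        params = DetectionParams()
        for seed in range(200):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(30, 201))
            s = np.maximum(rng.normal(0, 0.2, n), 0)
            s[rng.random(n) < 0.05] += rng.exponential(1.0)
            f = rng.normal(0, 0.3, n)
            f[s > 0.2] += 1.0
            sigma = 0.3
            impl = [
                e.peak_frame
                for e in detect_transients(
                    DeconvResult(f, s, 0.85), f, params, NoiseEstimate(sigma)
                )
            ]
            assert impl == brute_force_detect(s, f, params, sigma)

    def test_noise_free_recovers_spike_count_exactly(self, indicator, quiet_noise):
        spk = np.array([10.0, 20.0, 21.0, 30.0, 100.0, 100.5])
        F, _ = syn.render_trace(
            spk, indicator, quiet_noise, 10.0, 120.0, np.random.default_rng(0)
        )
        dec = deconvolve(F, DeconvParams(sparsity_penalty=0.0), 10.0)
        ev = detect_transients(dec, F, DetectionParams(), NoiseEstimate(0.0))
        assert len(ev) == len(spk)

    def test_threshold_monotonicity(self, indicator):
        noise = syn.NoiseParams(white_sd_dff=0.2)
        rng = np.random.default_rng(4)
        spikes, _ = syn.sample_burst_train(
            syn.PRESETS["TI-280"], np.random.default_rng(8)
        )
        F, Fneu = syn.render_trace(spikes, indicator, noise, 10.0, 600.0, rng)
        f = condition_trace(F, Fneu, 0.7, 600, 10)
        dec = deconvolve(f, DeconvParams(), 10.0)
        ne = estimate_noise(f)
        for grid, key in [
            ([0.02, 0.05, 0.1, 0.2, 0.4], "deconv_frac"),
            ([1.0, 2.0, 3.0, 4.0, 6.0], "amp_n_sigma"),
        ]:
            counts = [
                len(
                    detect_transients(
                        dec, f, DetectionParams(**{key: v}), ne
                    )
                )
                for v in grid
            ]
            assert counts == sorted(counts, reverse=True)

    def test_alignment_invariant(self, indicator):
        noise = syn.NoiseParams(white_sd_dff=0.2)
        rng = np.random.default_rng(9)
        spikes, _ = syn.sample_burst_train(
            syn.PRESETS["TI-280"], np.random.default_rng(12)
        )
        F, Fneu = syn.render_trace(spikes, indicator, noise, 10.0, 600.0, rng)
        f = condition_trace(F, Fneu, 0.7, 600, 10)
        dec = deconvolve(f, DeconvParams(), 10.0)
        params = DetectionParams()
        ev = detect_transients(dec, f, params, estimate_noise(f))
        f_sm = np.convolve(
            f, np.ones(params.align_smooth_frames) / params.align_smooth_frames,
            mode="same",
        )
        h = params.align_halfwidth_frames
        # candidate frames: stage (i)-(ii) of the detector, recomputed here
        above = dec.s > params.deconv_frac * dec.s.max()
        idx = np.flatnonzero(above)
        breaks = np.flatnonzero(np.diff(idx) > 1)
        runs = np.split(idx, breaks + 1)
        cands = [run[np.argmax(dec.s[run])] for run in runs]
        for e in ev:
            # the peak must be the smoothed-fluorescence argmax of some
            # candidate's alignment window
            ok = False
            for c in cands:
                if abs(e.peak_frame - c) <= h:
                    lo, hi = max(c - h, 0), min(c + h + 1, f.size)
                    if f_sm[e.peak_frame] == f_sm[lo:hi].max():
                        ok = True
                        break
            assert ok


class TestValidateTransients:
    def test_exact_template_validated(self, validation_template):
        f = np.zeros(200)
        k_peak = int(np.argmax(validation_template))
        f[60 - k_peak : 60 - k_peak + validation_template.size] = validation_template
        ev = [TransientEvent(0, 60, 6.0, 1.0, 1.0)]
        out = validate_transients(
            ev, f, validation_template, DetectionParams(), NoiseEstimate(0.05)
        )
        assert out[0].validated

    def test_event_on_pure_noise_rejected(self, validation_template):
        rejected = 0
        for seed in range(200):
            f = np.random.default_rng(seed).normal(0, 0.2, 400)
            ev = [TransientEvent(0, 200, 20.0, float(f[200]), 1.0)]
            out = validate_transients(
                ev, f, validation_template, DetectionParams(), NoiseEstimate(0.2)
            )
            rejected += not out[0].validated
        assert rejected >= 190

    def test_empty_event_list(self, validation_template):
        out = validate_transients(
            [], np.zeros(100), validation_template, DetectionParams(),
            NoiseEstimate(0.1),
        )
        assert out == []

    def test_out_of_bounds_event_rejected(self, validation_template):
        with pytest.raises(ValueError):
            validate_transients(
                [TransientEvent(0, 500, 50.0, 1.0, 1.0)],
                np.zeros(100),
                validation_template,
                DetectionParams(),
                NoiseEstimate(0.1),
            )
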