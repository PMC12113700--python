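import numpy as np
import pytest

from cereb_band_psd.core import BEHAVIORS, QC_OK, STRUCTURES
from cereb_band_psd.pipeline import build_band_table, reduced_config
from cereb_band_psd.preprocessing import extract_traces, preprocess_channels
from cereb_band_psd.spectral import band_auc, band_table, periodogram
from cereb_band_psd.synthetic import (
    CohortDesign,
    EpisodeParams,
    default_duration_params,
    generate_cohort,
    generate_powerlaw_noise,
    generate_session,
    powerlaw_band_fraction,
    rat_intercept,
    reduced_design,
    schedule_behaviors,
)
from conftest import REDUCED_MEDIANS, null_reduced_design
from oracles import powerlaw_fraction


class TestPowerlawNoise:
    def test_white_noise_flat_band_aucs(self):
        # alpha = 0: equal-width band AUCs agree within 5% (relative),
        # averaged over a few seeds to beat single-periodogram noise.
        aucs = np.zeros(3)
        for seed in range(4):
            x = generate_powerlaw_noise(2**16, 10_000.0, 0.0, 1.0, seed=seed)
            psd = periodogram(x, 10_000.0)
            aucs += [band_auc(psd, lo, lo + 500) for lo in (1000.0, 1500.0, 2000.0)]
        aucs /= 4
        assert np.ptp(aucs) / aucs.mean() < 0.05

    def test_alpha3_band_fraction_matches_integral(self):
        # Closed-form oracle: (300^-2 - 500^-2) / (300^-2 - 3000^-2).
        want = powerlaw_fraction(3.0, (300, 500), (300, 3000))
        assert want == pytest.approx(0.6465, abs=5e-4)
        fracs = [
            band_table(periodogram(generate_powerlaw_noise(50_000, 10_000.0, 3.0, 1.0, s), 10_000.0))[0].fraction
            for s in range(50)
        ]
        assert np.mean(fracs) == pytest.approx(want, abs=0.01)
        assert powerlaw_band_fraction(3.0, (300, 500), (300, 3000)) == pytest.approx(want)

    def test_band_power_normalization(self):
        powers = [
            band_auc(periodogram(generate_powerlaw_noise(2**15, 10_000.0, 3.2, 2.5, s), 10_000.0), 300, 3000, closed_right=True)
            for s in range(30)
        ]
        assert np.mean(powers) == pytest.approx(2.5, rel=0.05)

    def test_same_seed_bit_identical(self):
        a = generate_powerlaw_noise(4096, 10_000.0, 3.2, 1.0, seed=123)
        b = generate_powerlaw_noise(4096, 10_000.0, 3.2, 1.0, seed=123)
        assert np.array_equal(a, b)

    def test_zero_mean(self):
        x = generate_powerlaw_noise(2**14, 10_000.0, 2.0, 1.0, seed=1)
        assert abs(x.mean()) < 1e-6 * x.std()

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_samples=1),
            dict(total_power=0.0),
            dict(total_power=-1.0),
            dict(alpha=-0.5),
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        base = dict(n_samples=1024, fs=10_000.0, alpha=1.0, total_power=1.0, seed=0)
        base.update(kwargs)
        with pytest.raises(ValueError):
            generate_powerlaw_noise(
                base["n_samples"], base["fs"], base["alpha"], base["total_power"], base["seed"]
            )


DEFAULT_PARAMS = {b: p for (cond, b), p in default_duration_params().items() if cond == "base"}


class TestScheduleBehaviors:
    def test_all_behaviors_present_100_seeds(self):
        for seed in range(100):
            sched = schedule_behaviors(600.0, DEFAULT_PARAMS, seed, gap_mean=0.5)
            assert sched.behaviors == set(BEHAVIORS)

    def test_default_eligibility(self):
        # Protocol-scale defaults: every behavior offers >= 5 episodes of
        # >= 5 s, in at least 99% of sessions.
        rng = np.random.default_rng(202)
        ok = 0
        n = 200
        for seed in range(n):
            duration = float(rng.uniform(500, 800))
            sched = schedule_behaviors(duration, DEFAULT_PARAMS, seed, gap_mean=0.5)
            if all(
                sum(1 for e in sched.for_behavior(b) if e.duration >= 5.0) >= 5 for b in BEHAVIORS
            ):
                ok += 1
        assert ok >= 0.99 * n

    def test_degenerate_duration(self):
        sched = schedule_behaviors(0.1, DEFAULT_PARAMS, 0, gap_mean=0.5)
        assert len(sched) <= 1
        sched.validate(duration=0.1)

    def test_total_time_bounded(self):
        for seed in range(50):
            sched = schedule_behaviors(120.0, DEFAULT_PARAMS, seed, gap_mean=0.2)
            assert sched.total_time() <= 120.0 + 1e-6

    def test_non_overlap_and_order(self):
        sched = schedule_behaviors(300.0, DEFAULT_PARAMS, 5, gap_mean=0.0)
        eps = sched.episodes
        for a, b in zip(eps, eps[1:]):
            assert b.onset_s >= a.offset_s - 1e-9

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            schedule_behaviors(0.0, DEFAULT_PARAMS, 0)
        with pytest.raises(ValueError):
            schedule_behaviors(100.0, {"resting": EpisodeParams(-1.0, 0.3)}, 0)
        with pytest.raises(ValueError):
            schedule_behaviors(100.0, {"resting": EpisodeParams(5.0, 0.3, rate=0.0)}, 0)


class TestCohortDesign:
    def test_defaults_valid(self):
        d = CohortDesign()
        assert d.gain("experimental", 1, "grooming") == 1.8
        assert d.gain("experimental", 3, "grooming") == 1.0
        assert d.gain("control", 1, "grooming") == 1.0
        assert d.coupling("grooming") < 0 < d.coupling("sniffing")
        assert d.coupling("resting") == 0.0

    def test_w1_duration_shifts(self):
        d = CohortDesign()
        base = d.episode_params("control", 1, "resting").median_s
        shifted = d.episode_params("experimental", 1, "resting").median_s
        assert shifted > base
        assert d.episode_params("experimental", 2, "resting").median_s == base

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_control=0),
            dict(weeks=0),
            dict(spectral_exponent=-1.0),
            dict(session_duration=(100.0, 90.0)),
            dict(session_duration=(100.0, 200.0)),  # outside protocol range
            dict(band_gain={("experimental", 1, "grooming"): 0.0}),
        ],
    )
    def test_invalid_designs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CohortDesign(**kwargs)

    def test_reduced_design_relaxes_protocol_duration(self):
        d = reduced_design()
        assert d.session_duration == (80.0, 120.0)
        assert d.fs == 2000.0

    def test_rat_ids_layout(self):
        d = CohortDesign(n_control=2, n_experimental=3)
        ids = d.rat_ids()
        assert ids[0] == ("C01", "control")
        assert ids[-1] == ("E03", "experimental")
        assert len(ids) == 5


class TestGenerateSession:
    def test_determinism(self):
        d = reduced_design(seed=11)
        a = generate_session(d, "E02", "experimental", 3)
        b = generate_session(d, "E02", "experimental", 3)
        assert a.episodes.episodes == b.episodes.episodes
        for s in STRUCTURES:
            assert np.array_equal(a.channels[s], b.channels[s])

    def test_channels_share_one_schedule(self):
        d = reduced_design(seed=12)
        s = generate_session(d, "C01", "control", 1)
        assert set(s.channels) == set(STRUCTURES)
        assert len({len(c) for c in s.channels.values()}) == 1
        s.validate()

    def test_invalid_group_week_rejected(self):
        d = reduced_design()
        with pytest.raises(ValueError):
            generate_session(d, "X01", "sham", 1)
        with pytest.raises(ValueError):
            generate_session(d, "E01", "experimental", 5)

    def test_rat_intercept_shared_and_seeded(self):
        d = reduced_design(seed=3, rat_sd=0.3)
        assert rat_intercept(d, "E05") == rat_intercept(d, "E05")
        assert rat_intercept(d, "E05") != rat_intercept(d, "E06")
        assert rat_intercept(reduced_design(rat_sd=0.0), "E05") == 1.0

    def test_null_design_applies_no_scaling(self):
        # With g=1, kappa=0, rat_sd=0 the envelope is unity, so the only
        # difference from an effect design with the same seed lies inside
        # scaled episodes.
        null = null_reduced_design(31, mains_amp=0.0)
        boosted = null_reduced_design(
            31, mains_amp=0.0, band_gain={("experimental", 1, b): 6.0 for b in BEHAVIORS}
        )
        a = generate_session(null, "E01", "experimental", 1)
        b = generate_session(boosted, "E01", "experimental", 1)
        assert a.episodes.episodes == b.episodes.episodes
        fs = null.fs
        diff = a.channels["IO"] != b.channels["IO"]
        in_episode = np.zeros(a.n_samples, dtype=bool)
        for ep in a.episodes:
            in_episode[int(round(ep.onset_s * fs)) : int(round(ep.offset_s * fs))] = True
        assert not diff[~in_episode].any()
        assert diff[in_episode].any()

    def test_artifact_free_clean_sessions(self):
        d = null_reduced_design(17)  # artifact_rate = 0
        sessions = [generate_session(d, "E01", "experimental", w) for w in (1, 2)]
        _, counts = build_band_table(sessions, reduced_config(diagnostics=False))
        assert counts["excluded_saturation"] == 0
        assert counts["excluded_excursion"] == 0
        assert sessions[0].artifacts == []

    def test_gain_recovery_monte_carlo(self):
        # Injected 1.8x grooming gain recovered from the band AUC ratio
        # within 10% over >= 50 sessions.
        gain = 1.8
        kwargs = dict(
            band_gain={("experimental", 1, "grooming"): gain},
            duration_coupling={},
            rat_sd=0.0,
            duration_params=default_duration_params(medians=REDUCED_MEDIANS, log_sd=0.45, w1_shifts={}),
        )
        cfg = reduced_config()
        means = {"experimental": [], "control": []}
        for i in range(26):
            for group in ("experimental", "control"):
                d = reduced_design(seed=9000 + i, **kwargs)
                rat = f"{'E' if group == 'experimental' else 'C'}{i + 1:02d}"
                s = generate_session(d, rat, group, 1)
                channels = preprocess_channels(s, low=cfg.bp_low, high=cfg.bp_high, notch_base=None)
                traces = extract_traces(s, "grooming", trace_len=1.0, max_traces=5, channels=channels)
                for tr in traces:
                    psd = periodogram(tr.samples, s.fs)
                    means[group].append(band_auc(psd, *d.effect_band))
        ratio = np.mean(means["experimental"]) / np.mean(means["control"])
        assert ratio == pytest.approx(gain, rel=0.10)

    def test_artifact_bookkeeping_matches_injection(self):
        # Excluded traces correspond exactly to injected artifacts (clean
        # background otherwise): flagged <-> overlaps an artifact window.
        d = null_reduced_design(23, artifact_rate=8.0)
        cfg = reduced_config()
        flagged_total = 0
        for week in (1, 2, 3, 4):
            s = generate_session(d, "E01", "experimental", week)
            channels = preprocess_channels(s, low=cfg.bp_low, high=cfg.bp_high, notch_base=None)
            for behavior in BEHAVIORS:
                import warnings as _w

                with _w.catch_warnings():
                    _w.simplefilter("ignore")
                    traces = extract_traces(
                        s, behavior, trace_len=1.0, max_traces=5,
                        channels=channels, include_flagged=True,
                    )
                for tr in traces:
                    arts = [a for a in s.artifacts if a.structure == tr.structure]
                    # flagged traces must overlap an artifact (with margin for
                    # filter ringing around saturation steps)
                    overlaps_loose = any(
                        a.t_start - 0.1 < tr.window[1] and a.t_end + 0.1 > tr.window[0]
                        for a in arts
                    )
                    # traces containing an artifact center must be flagged
                    contains_center = any(
                        tr.window[0] <= 0.5 * (a.t_start + a.t_end) < tr.window[1] for a in arts
                    )
                    if tr.qc != QC_OK:
                        flagged_total += 1
                        assert overlaps_loose
                    if contains_center:
                        assert tr.qc != QC_OK
        assert flagged_total > 0  # the scenario actually exercised the rules


class TestGenerateCohort:
    def test_layout_and_count(self):
        d = null_reduced_design(2, n_control=2, n_experimental=2, weeks=2)
        sessions = list(generate_cohort(d))
        assert len(sessions) == 8
        assert [(s.rat_id, s.week) for s in sessions[:2]] == [("C01", 1), ("C01", 2)]

    def test_group_restriction(self):
        d = null_reduced_design(2, n_control=2, n_experimental=2, weeks=2)
        sessions = list(generate_cohort(d, groups=("experimental",)))
        assert {s.group for s in sessions} == {"experimental"}
        assert len(sessions) == 4
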