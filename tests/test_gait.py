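"""Gait battery: compliance, per-paw parameters, support decomposition,
base of support, NSSP classification and run summaries."""

import itertools

import numpy as np
import pytest

from phenocage.gait import (FootfallRecord, GaitRun, NSSP_PATTERNS, PAWS,
                            SUPPORT_CATEGORIES, base_of_support,
                            compliance_filter, nssp_percent, paw_parameters,
                            run_summary, support_fractions)


def make_run(paw_seq, interval=0.25, stand=0.15, step_cm=1.5, start=0.0,
             lateral=None, animal="g0"):
    lateral = lateral or {"RF": -9.0, "LF": 9.0, "RH": -11.0, "LH": 11.0}
    falls = []
    x = 0.0
    t = start
    for paw in paw_seq:
        x += step_cm
        y = lateral[paw]
        falls.append(FootfallRecord(
            paw=paw, contact=t, release=t + stand, heel=(x * 10, y),
            third_toe=(x * 10 + 70.0, y), toe1=(x * 10 + 70, y - 25),
            toe5=(x * 10 + 70, y + 25), toe2=(x * 10 + 70, y - 15),
            toe4=(x * 10 + 70, y + 15), intensities=np.full(5, 100.0),
            position_cm=x))
        t += interval
    return GaitRun(animal_id=animal, footfalls=falls)


def random_schedule(rng, n_min=6, n_max=16):
    falls = []
    for _ in range(rng.integers(n_min, n_max)):
        c = rng.uniform(0, 5)
        falls.append(FootfallRecord(
            paw=PAWS[rng.integers(4)], contact=c, release=c + rng.uniform(0.05, 0.9),
            heel=(0.0, 0.0), third_toe=(1.0, 0.0), position_cm=float(len(falls))))
    return GaitRun(animal_id="r", footfalls=falls)


class TestCompliance:
    def test_fast_monotone_run_kept(self):
        run = make_run(["RF", "RH", "LF", "LH"] * 5, interval=0.45)  # ~9.2 s
        assert run.duration < 10
        kept, report = compliance_filter([run])
        assert len(kept) == 1 and report["compliant"].all()

    def test_ten_second_run_is_excluded(self):
        # 20 steps, last release exactly at 10.0 s: the bound is strict
        run = make_run(["RF", "RH", "LF", "LH"] * 5, interval=0.51842105263, stand=0.15)
        falls = run.footfalls
        falls[-1].release = falls[0].contact + 10.0
        run = GaitRun(animal_id="g0", footfalls=falls)
        assert run.duration == pytest.approx(10.0)
        kept, _ = compliance_filter([run])
        assert kept == []

    def test_direction_reversal_excluded_with_reason(self):
        run = make_run(["RF", "RH", "LF", "LH"] * 3)
        for f in run.footfalls[6:]:
            f.position_cm = run.footfalls[5].position_cm - (f.contact + 1)
        kept, report = compliance_filter([run])
        assert kept == []
        assert report["reason"].iloc[0] == "bidirectional"

    def test_animals_with_few_compliant_runs_reported(self):
        runs = [make_run(["RF", "RH", "LF", "LH"] * 4, animal="a"),
                make_run(["RF", "RH", "LF", "LH"] * 4, animal="b"),
                make_run(["RF", "RH", "LF", "LH"] * 4, animal="b"),
                make_run(["RF", "RH", "LF", "LH"] * 4, animal="b")]
        _, report = compliance_filter(runs)
        assert report.attrs["animals_below_min_runs"] == ["a"]


class TestPawParameters:
    def test_print_length_from_geometry(self):
        run = make_run(["RF"] * 4)
        f = run.footfalls[0]
        f.heel, f.third_toe = (0.0, 0.0), (0.0, 30.0)
        df = paw_parameters(run, px_per_mm=10.0)
        assert df["print_length_mm"].iloc[0] == pytest.approx(3.0)

    def test_paw_parallel_to_body_axis_has_zero_angle(self):
        run = make_run(["RF", "RH", "LF", "LH"])
        df = paw_parameters(run)
        np.testing.assert_allclose(df["paw_angle_deg"], 0.0, atol=1e-9)

    def test_angle_folds_to_pm_90(self):
        run = make_run(["RF"] * 4)
        f = run.footfalls[0]
        f.heel, f.third_toe = (0.0, 0.0), (-10.0, 1.0)  # pointing backwards
        ang = paw_parameters(run)["paw_angle_deg"].iloc[0]
        assert -90 <= ang <= 90

    def test_stand_cycle_swing_arithmetic(self):
        falls = [
            FootfallRecord(paw="RF", contact=1.0, release=1.3, heel=(0, 0),
                           third_toe=(1, 0), position_cm=1.0),
            FootfallRecord(paw="RF", contact=1.5, release=1.8, heel=(0, 0),
                           third_toe=(1, 0), position_cm=2.0),
        ]
        df = paw_parameters(GaitRun(animal_id="x", footfalls=falls))
        assert df["stand_s"].iloc[0] == pytest.approx(0.3)
        assert df["step_cycle_s"].iloc[0] == pytest.approx(0.5)
        assert df["swing_s"].iloc[0] == pytest.approx(0.2)
        assert np.isnan(df["step_cycle_s"].iloc[1])  # last contact: no cycle

    def test_missing_toe_landmark_flags_metric(self):
        falls = [FootfallRecord(paw="LH", contact=0.0, release=0.2, heel=(0, 0),
                                third_toe=(1, 0), position_cm=0.0)]
        df = paw_parameters(GaitRun(animal_id="x", footfalls=falls))
        assert np.isnan(df["toe_spread_mm"].iloc[0])
        assert np.isfinite(df["print_length_mm"].iloc[0])


class TestSupport:
    def test_all_four_down_throughout(self):
        falls = [FootfallRecord(paw=p, contact=0.0, release=2.0, heel=(0, 0),
                                third_toe=(1, 0), position_cm=i)
                 for i, p in enumerate(PAWS)]
        out = support_fractions(GaitRun(animal_id="x", footfalls=falls))
        assert out["four"] == pytest.approx(100.0)

    def test_perfect_trot_is_all_diagonal(self):
        # diagonal pairs (RF+LH, LF+RH) alternating with no overlap
        falls = []
        for k in range(4):
            t = k * 0.2
            pair = ("RF", "LH") if k % 2 == 0 else ("LF", "RH")
            for p in pair:
                falls.append(FootfallRecord(paw=p, contact=t, release=t + 0.2,
                                            heel=(0, 0), third_toe=(1, 0),
                                            position_cm=k))
        out = support_fractions(GaitRun(animal_id="x", footfalls=falls),
                                method="event")
        assert out["diagonal"] == pytest.approx(100.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_fractions_partition_run_time(self, seed):
        run = random_schedule(np.random.default_rng(seed))
        for method in ("discrete", "event"):
            out = support_fractions(run, method=method)
            assert sum(out.values()) == pytest.approx(100.0, abs=1e-9)

    def test_discretization_converges_to_event_oracle(self):
        rng = np.random.default_rng(42)
        errs = {0.01: [], 0.001: []}
        for _ in range(20):
            run = random_schedule(rng)
            exact = support_fractions(run, method="event")
            for dt in errs:
                approx = support_fractions(run, dt=dt)
                errs[dt].append(max(abs(approx[c] - exact[c])
                                    for c in SUPPORT_CATEGORIES))
        assert np.mean(errs[0.001]) < np.mean(errs[0.01])
        assert max(errs[0.001]) < 0.3


class TestBaseOfSupport:
    def test_symmetric_offsets(self):
        run = make_run(["RH", "LH"] * 4,
                       lateral={"RF": -5, "LF": 5, "RH": -5, "LH": 5})
        front, hind = base_of_support(run)
        assert hind == pytest.approx(10.0)
        assert np.isnan(front)  # no front-paw alternation in this run

    def test_zero_offset(self):
        run = make_run(["RF", "LF"] * 3, lateral=dict.fromkeys(PAWS, 0.0))
        front, _ = base_of_support(run)
        assert front == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_pairing(self, seed):
        rng = np.random.default_rng(seed)
        run = random_schedule(rng, 8, 14)
        for f in run.footfalls:
            f.heel = (f.heel[0], float(rng.uniform(-20, 20)))
        front, hind = base_of_support(run)
        for pair, got in ((("RF", "LF"), front), (("RH", "LH"), hind)):
            prints = sorted((f for f in run.footfalls if f.paw in pair),
                            key=lambda f: f.contact)
            ws = [abs(a.heel[1] - b.heel[1]) for a, b in zip(prints, prints[1:])
                  if a.paw != b.paw]
            if ws:
                assert got == pytest.approx(np.mean(ws))
            else:
                assert np.isnan(got)


class TestNSSP:
    def test_pure_alternate_pattern_scores_100(self):
        run = make_run(["RF", "RH", "LF", "LH"] * 5)
        assert nssp_percent(run) == 100.0

    def test_single_paw_run_scores_0(self):
        run = make_run(["RF"] * 8)
        assert nssp_percent(run) == 0.0

    def test_fewer_than_four_steps_is_undefined(self):
        assert np.isnan(nssp_percent(make_run(["RF", "RH", "LF"])))

    def test_six_patterns_and_rotations_cover_all_permutations(self):
        # independent enumeration: every permutation of the four paws is a
        # starting-paw rotation of exactly one canonical pattern
        claimed = set()
        for pat in NSSP_PATTERNS.values():
            for i in range(4):
                claimed.add(pat[i:] + pat[:i])
        assert claimed == set(itertools.permutations(PAWS))
        assert len(NSSP_PATTERNS) == 6

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_window_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seq = [PAWS[i] for i in rng.integers(0, 4, 30)]
        run = make_run(seq)
        # oracle: brute-force window check against rotation membership
        normal = 0
        for i in range(len(seq) - 3):
            win = tuple(seq[i:i + 4])
            is_rot = any(win == pat[j:] + pat[:j]
                         for pat in NSSP_PATTERNS.values() for j in range(4))
            normal += is_rot
        assert nssp_percent(run) == pytest.approx(100 * normal / (len(seq) - 3))


class TestRunSummary:
    def test_cadence_arithmetic(self):
        run = make_run(["RF", "RH", "LF", "LH"] * 5, interval=0.25, stand=0.25)
        # 20 steps; duration = 19 intervals + final stand = 5.0 s
        assert run.duration == pytest.approx(5.0)
        out = run_summary(run)
        assert out["n_steps"] == 20
        assert out["cadence"] == pytest.approx(4.0)

    def test_per_animal_mean_is_idempotent_for_identical_runs(self):
        from phenocage.gait import animal_summary
        r1 = make_run(["RF", "RH", "LF", "LH"] * 4)
        r2 = make_run(["RF", "RH", "LF", "LH"] * 4)
        one = animal_summary([r1])
        two = animal_summary([r1, r2])
        for col in ("cadence", "nssp_pct", "stand_s_RF"):
            assert one[col].iloc[0] == pytest.approx(two[col].iloc[0])

    def test_per_animal_mean_matches_bruteforce(self):
        from phenocage.gait import animal_summary
        rng = np.random.default_rng(0)
        runs = [make_run(["RF", "RH", "LF", "LH"] * int(rng.integers(3, 6)),
                         interval=float(rng.uniform(0.2, 0.3))) for _ in range(3)]
        df = animal_summary(runs)
        brute = np.mean([run_summary(r)["cadence"] for r in runs])
        assert df["cadence"].iloc[0] == pytest.approx(brute)
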