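"""Random-trajectory null and strategy assignment."""

import math

import numpy as np
import pytest
import scipy.stats as st

from fishnav import (
    Trajectory,
    build_null,
    classify_trial,
    closest_model,
    generate_random_trajectory,
    sd_uniform,
)
from fishnav.arena import unit_vector
from fishnav.classify import NullDistribution, _null_means_for_headings
from fishnav.errors import ConfigurationError, ContractError
from fishnav.trajectory import (
    arc_length,
    interpolate_1000,
    mean_distance,
    truncate_to_length,
)


def _straight_traj(door, heading_deg, length, n=14):
    u = unit_vector(heading_deg)
    pts = door + np.linspace(0.0, length, n)[:, None] * u
    return Trajectory("s", "f", np.arange(n, dtype=float), pts)


class TestSdUniform:
    @pytest.mark.parametrize(
        "a,b,expected", [(0.0, 12.0, 3.4641), (5.0, 5.0, 0.0), (2.0, 4.0, 0.5774)]
    )
    def test_examples(self, a, b, expected):
        assert sd_uniform(a, b) == pytest.approx(expected, abs=1e-4)

    def test_inverted_interval_rejected(self):
        with pytest.raises(ContractError):
            sd_uniform(4.0, 2.0)


class TestGenerateRandomTrajectory:
    def test_seeded_determinism(self):
        a = generate_random_trajectory(38.6, (90, 15), np.random.default_rng(11))
        b = generate_random_trajectory(38.6, (90, 15), np.random.default_rng(11))
        np.testing.assert_array_equal(a, b)

    def test_length_exact(self):
        line = generate_random_trajectory(10.0, (0, 0), np.random.default_rng(0))
        assert arc_length(line) == pytest.approx(10.0, abs=1e-12)

    def test_heading_uniform_on_half_circle(self):
        rng = np.random.default_rng(2)
        headings = []
        for _ in range(10_000):
            line = generate_random_trajectory(5.0, (0, 0), rng)
            v = line[1] - line[0]
            headings.append(math.degrees(math.atan2(v[1], v[0])) % 360.0)
        headings = np.asarray(headings)
        assert headings.max() < 180.0
        ks = st.kstest(headings / 180.0, "uniform").statistic
        assert ks < 0.02

    def test_non_positive_length_rejected(self):
        with pytest.raises(ContractError):
            generate_random_trajectory(0.0, (0, 0), np.random.default_rng(0))


class TestBuildNull:
    def test_definitional_invariants(self, config, models_lateral, door_lateral):
        obs = _straight_traj(door_lateral, 70.0, 38.6)
        null = build_null(obs, models_lateral["PI"], n=2000, seed=4)
        assert null.a <= null.mu <= null.b
        assert null.sd_uniform == pytest.approx((null.b - null.a) / math.sqrt(12), abs=1e-12)
        assert null.sd_normal == pytest.approx(null.mean_distances.std(ddof=1), abs=1e-12)
        assert null.a <= null.q20 <= null.b
        assert null.mean_distances.size == 2000

    def test_seeded_determinism(self, models_lateral, door_lateral):
        obs = _straight_traj(door_lateral, 70.0, 38.6)
        n1 = build_null(obs, models_lateral["PI"], n=500, seed=9)
        n2 = build_null(obs, models_lateral["PI"], n=500, seed=9)
        np.testing.assert_array_equal(n1.mean_distances, n2.mean_distances)

    def test_matching_heading_gives_near_zero_distance(self, models_lateral, door_lateral):
        """A random line drawn at exactly the observed heading scores ~0."""
        obs = _straight_traj(door_lateral, 77.0, 38.6)
        d = _null_means_for_headings(
            interpolate_1000(obs.xy).points, obs.xy[0], 38.6, np.radians([77.0])
        )
        assert d[0] < 1e-9

    def test_fast_path_matches_explicit_route(self, models_lateral, door_lateral):
        """Vectorised sampler equals generate → crop → interpolate → score."""
        obs = _straight_traj(door_lateral, 100.0, 50.0, n=21)
        L = min(arc_length(obs.xy), models_lateral["PI"].total_length)
        obs_interp = interpolate_1000(truncate_to_length(obs.xy, L))
        for heading in (10.0, 77.0, 145.0):
            fast = _null_means_for_headings(
                obs_interp.points, obs.xy[0], L, np.radians([heading])
            )[0]
            line = obs.xy[0] + np.array([[0.0, 0.0], L * unit_vector(heading)])
            _, slow = mean_distance(obs.xy, line)
            assert fast == pytest.approx(slow, abs=1e-9)

    def test_invalid_n_rejected(self, models_lateral, door_lateral):
        obs = _straight_traj(door_lateral, 70.0, 38.6)
        with pytest.raises(ContractError):
            build_null(obs, models_lateral["PI"], n=0)


class TestClosestModel:
    def test_identity_with_apc(self, config, models_lateral):
        obs = models_lateral["APC"].polyline
        ranking = closest_model(obs, models_lateral, n_boot=50)
        assert ranking.best_strategy == "APC"
        assert ranking.best_distance == pytest.approx(0.0, abs=1e-9)

    def test_translated_pi_scores_its_offset(self, models_lateral):
        # shift perpendicular to the PI heading so PI stays the clear best
        obs = models_lateral["PI"].polyline + 2.0 * np.array(
            [math.cos(math.radians(135)), math.sin(math.radians(135))]
        )
        ranking = closest_model(obs, models_lateral, n_boot=50)
        assert ranking.best_strategy == "PI"
        assert ranking.best_distance == pytest.approx(2.0, abs=1e-6)

    def test_missing_model_rejected(self, models_lateral):
        with pytest.raises(ConfigurationError):
            closest_model(models_lateral["PI"].polyline, {"PI": models_lateral["PI"]})

    def test_contrasts_cover_all_pairs(self, models_lateral):
        ranking = closest_model(models_lateral["RR"].polyline, models_lateral, n_boot=50)
        assert len(ranking.contrasts) == 3
        # RR identical to itself: contrasts involving RR are decisively signed
        for c in ranking.contrasts:
            if "RR" in (c.strategy_a, c.strategy_b):
                assert c.significant


def _dummy_null(mu, sd_u, sd_n=None, q20=None):
    half = sd_u * math.sqrt(12) / 2.0
    a, b = mu - half, mu + half
    return NullDistribution(
        mean_distances=np.array([a, mu, b]),
        mu=mu,
        a=a,
        b=b,
        sd_uniform=sd_u,
        sd_normal=sd_n if sd_n is not None else sd_u,
        q20=q20 if q20 is not None else mu - sd_u,
        seed=0,
        length=38.6,
    )


class TestClassifyTrial:
    def test_clear_winner_labelled(self, models_lateral, door_lateral):
        obs = _straight_traj(door_lateral, 45.0, 38.6)
        res = classify_trial(obs, models_lateral, _dummy_null(30.0, 8.0))
        assert res.label == res.best_strategy == "PI"
        assert res.threshold == pytest.approx(22.0)

    def test_near_null_labelled_random(self, models_lateral, door_lateral):
        obs = _straight_traj(door_lateral, 2.0, 38.6)  # 43 deg off the nearest model
        null = _dummy_null(10.0, 4.0)  # threshold 6 cm
        res = classify_trial(obs, models_lateral, null)
        assert res.best_distance >= res.threshold
        assert res.label == "RANDOM"

    def test_degenerate_null_reduces_to_mu(self, models_lateral, door_lateral):
        obs = _straight_traj(door_lateral, 45.0, 38.6)
        res = classify_trial(obs, models_lateral, _dummy_null(30.0, 0.0))
        assert res.threshold == pytest.approx(30.0)
        assert res.label == "PI"

    def test_unknown_rule_rejected(self, models_lateral, door_lateral):
        obs = _straight_traj(door_lateral, 45.0, 38.6)
        with pytest.raises(ContractError):
            classify_trial(obs, models_lateral, _dummy_null(30.0, 8.0), rule="sd_magic")

    @pytest.mark.parametrize("rule,expected_threshold", [
        ("sd_uniform", 22.0), ("sd_normal", 25.0), ("q20", 21.0),
    ])
    def test_rules_use_their_thresholds(self, models_lateral, door_lateral, rule, expected_threshold):
        obs = _straight_traj(door_lateral, 45.0, 38.6)
        null = _dummy_null(30.0, 8.0, sd_n=5.0, q20=21.0)
        res = classify_trial(obs, models_lateral, null, rule=rule)
        assert res.threshold == pytest.approx(expected_threshold)

    def test_decision_monotone_in_distance(self, models_lateral, door_lateral):
        """Moving the observed path closer to a model never flips model → RANDOM."""
        null = _dummy_null(30.0, 8.0)
        labels = []
        for offset in (25.0, 15.0, 5.0, 0.0):
            obs_pts = models_lateral["PI"].polyline + offset * unit_vector(135.0)
            obs = Trajectory("m", "f", [0.0, 1.0], obs_pts)
            labels.append(classify_trial(obs, models_lateral, null).label)
        seen_model = False
        for lab in labels:  # ordered by decreasing distance
            if lab == "PI":
                seen_model = True
            assert not (seen_model and lab == "RANDOM")
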