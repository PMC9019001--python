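"""Multi-pollinator composition: visit shares, H_tot, RI_tot, crossovers, hooks."""

import numpy as np
import pytest

from pollinator_ri import (
    CommunityScenario,
    DomainError,
    GuildMember,
    crossover_frequencies,
    focal_visit_shares,
    heterospecific_share,
    isolation_one,
    isolation_total,
    linear_preference,
    total_heterospecific_share,
    visit_proportion,
)

TOL = 1e-10


def guild(*specs):
    return tuple(GuildMember(rho, kappa, phi, f"p{k + 1}") for k, (rho, kappa, phi) in enumerate(specs))


class TestFocalVisitShares:
    def test_identical_visit_proportions_give_phi(self):
        sc = CommunityScenario(0.4, guild((0.3, 0.0, 0.5), (0.3, 0.2, 0.5)))
        assert focal_visit_shares(sc) == pytest.approx([0.5, 0.5], abs=TOL)

    def test_single_visitor_takes_all(self):
        sc = CommunityScenario(0.4, guild((0.3, 0.0, 1.0), (0.8, 0.0, 0.0)))
        assert focal_visit_shares(sc) == pytest.approx([1.0, 0.0], abs=TOL)

    def test_two_pollinator_example(self):
        sc = CommunityScenario(0.5, guild((0.8, 0.0, 0.5), (0.0, 0.0, 0.5)))
        assert focal_visit_shares(sc)[0] == pytest.approx(9.0 / 14.0, abs=TOL)

    def test_sums_to_one(self):
        sc = CommunityScenario(0.3, guild((0.6, 0.1, 0.2), (-0.4, 0.0, 0.5), (0.0, -0.5, 0.3)))
        assert focal_visit_shares(sc).sum() == pytest.approx(1.0, abs=TOL)

    def test_nobody_visits_focal_raises(self):
        sc = CommunityScenario(0.5, guild((-1.0, 0.0, 0.5), (-1.0, 0.0, 0.5)))
        with pytest.raises(DomainError, match="no pollinator"):
            focal_visit_shares(sc)


class TestTotalHeterospecificShare:
    def test_single_member_reduces_to_one_pollinator(self):
        sc = CommunityScenario(0.5, guild((0.8, 0.0, 1.0)))
        assert total_heterospecific_share(sc) == pytest.approx(0.1, abs=TOL)

    @pytest.mark.parametrize(
        "rho2, expected", [(0.0, 3.4 / 14.0), (-0.8, 0.18)]
    )
    def test_two_pollinator_examples(self, rho2, expected):
        sc = CommunityScenario(0.5, guild((0.8, 0.0, 0.5), (rho2, 0.0, 0.5)))
        assert total_heterospecific_share(sc) == pytest.approx(expected, abs=TOL)

    @pytest.mark.parametrize("n", [1, 2, 5])
    def test_identical_guild_reduces_to_one_pollinator(self, n):
        members = guild(*[(0.4, -0.2, 1.0 / n)] * n)
        sc = CommunityScenario(0.3, members)
        assert total_heterospecific_share(sc) == pytest.approx(
            heterospecific_share(0.3, 0.4, -0.2), abs=TOL
        )
        assert isolation_total(sc) == pytest.approx(isolation_one(0.3, 0.4, -0.2), abs=TOL)


class TestIsolationTotal:
    def test_null_guild_gives_zero(self):
        sc = CommunityScenario(0.4, guild((0.0, 0.0, 0.3), (0.0, 0.0, 0.7)))
        assert isolation_total(sc) == pytest.approx(0.0, abs=TOL)

    @pytest.mark.parametrize(
        "rho2, expected", [(0.0, 0.34615384615384615), (-0.8, 0.47058823529411764)]
    )
    def test_two_pollinator_examples(self, rho2, expected):
        sc = CommunityScenario(0.5, guild((0.8, 0.0, 0.5), (rho2, 0.0, 0.5)))
        assert isolation_total(sc) == pytest.approx(expected, abs=TOL)

    def test_opposed_preference_beats_indifference_at_half(self):
        """A pollinator avoiding the focal plant contributes almost no visits
        to it, so RI is higher than with an indifferent second pollinator."""
        against = CommunityScenario(0.5, guild((0.8, 0.0, 0.5), (-0.8, 0.0, 0.5)))
        indifferent = CommunityScenario(0.5, guild((0.8, 0.0, 0.5), (0.0, 0.0, 0.5)))
        assert isolation_total(against) > isolation_total(indifferent)


class TestAdditivity:
    def test_constancy_only_H_is_linear_in_visit_share(self):
        """With no preference anywhere, H_tot is the phi-weighted average of
        the members' H values, exactly."""
        f = 0.5
        H1 = heterospecific_share(f, 0.0, 0.8)
        H2 = heterospecific_share(f, 0.0, 0.0)
        for phi1 in np.linspace(0.0, 1.0, 201):
            sc = CommunityScenario(f, guild((0.0, 0.8, phi1), (0.0, 0.0, 1.0 - phi1)))
            assert total_heterospecific_share(sc) == pytest.approx(
                phi1 * H1 + (1.0 - phi1) * H2, abs=1e-12
            )

    def test_preference_pulls_H_below_linear_mixture(self):
        f = 0.5
        H1 = heterospecific_share(f, 0.8, 0.0)
        H2 = heterospecific_share(f, 0.0, 0.0)
        for phi1 in np.linspace(0.05, 0.95, 50):
            sc = CommunityScenario(f, guild((0.8, 0.0, phi1), (0.0, 0.0, 1.0 - phi1)))
            assert total_heterospecific_share(sc) < phi1 * H1 + (1.0 - phi1) * H2

    def test_deviation_grows_with_preference_difference(self):
        f, phi1 = 0.5, 0.5
        deviations = []
        for rho2 in (0.4, 0.0, -0.8):
            H1 = heterospecific_share(f, 0.8, 0.0)
            H2 = heterospecific_share(f, rho2, 0.0)
            sc = CommunityScenario(f, guild((0.8, 0.0, phi1), (rho2, 0.0, 1.0 - phi1)))
            deviations.append(abs(total_heterospecific_share(sc) - (phi1 * H1 + (1 - phi1) * H2)))
        assert deviations[0] < deviations[1] < deviations[2]


class TestCrossoverFrequencies:
    A = guild((0.8, 0.0, 0.5), (-0.8, 0.0, 0.5))
    B = guild((0.8, 0.0, 0.5), (0.0, 0.0, 0.5))

    def test_identical_scenarios_have_no_isolated_crossing(self):
        assert crossover_frequencies(self.A, self.A) == []

    def test_strong_against_vs_indifferent_single_crossing(self):
        crossings = crossover_frequencies(self.A, self.B)
        assert len(crossings) == 1
        assert 0.6 < crossings[0] <= 0.67

    def test_crossing_matches_dense_direct_evaluation(self):
        """Locate the sign change by dense direct evaluation of the visit,
        movement and RI equations, bypassing the scan+bisection machinery."""

        def ri_tot(f, rho2):
            psi1, psi2 = visit_proportion(f, 0.8), visit_proportion(f, rho2)
            v1 = 0.5 * psi1 / (0.5 * psi1 + 0.5 * psi2)
            H = v1 * heterospecific_share(f, 0.8, 0.0) + (1 - v1) * heterospecific_share(f, rho2, 0.0)
            return 1.0 - 2.0 * H / (H + (1.0 - f))

        fs = np.linspace(1e-4, 1.0 - 1e-4, 200_001)
        diff = np.array([ri_tot(f, -0.8) - ri_tot(f, 0.0) for f in fs])
        (idx,) = np.nonzero(np.sign(diff[:-1]) * np.sign(diff[1:]) < 0)
        assert len(idx) == 1
        lo, hi = fs[idx[0]], fs[idx[0] + 1]
        crossings = crossover_frequencies(self.A, self.B)
        assert lo - 1e-6 <= crossings[0] <= hi + 1e-6

    def test_argument_order_does_not_move_the_crossing(self):
        ab = crossover_frequencies(self.A, self.B)
        ba = crossover_frequencies(self.B, self.A)
        assert ba == pytest.approx(ab, abs=1e-6)

    def test_accepts_scenarios_as_templates(self):
        sa = CommunityScenario(0.3, self.A)
        sb = CommunityScenario(0.9, self.B)
        assert crossover_frequencies(sa, sb) == pytest.approx(
            crossover_frequencies(self.A, self.B), abs=1e-9
        )


class TestPreferenceHook:
    def test_constant_hook_matches_scalar(self):
        for f in np.linspace(0.05, 0.95, 20):
            hooked = CommunityScenario(f, (GuildMember(lambda _: 0.8, 0.0, 1.0),))
            scalar = CommunityScenario(f, (GuildMember(0.8, 0.0, 1.0),))
            assert isolation_total(hooked) == pytest.approx(isolation_total(scalar), abs=TOL)

    def test_zero_hook_gives_zero_ri_everywhere(self):
        for f in np.linspace(0.05, 0.95, 20):
            sc = CommunityScenario(f, (GuildMember(lambda _: 0.0, 0.0, 1.0),))
            assert isolation_total(sc) == pytest.approx(0.0, abs=TOL)

    def test_linear_hook_crosses_zero_at_half(self):
        hook = linear_preference(0.5)
        sc = CommunityScenario(0.5, (GuildMember(hook, 0.0, 1.0),))
        assert isolation_total(sc) == pytest.approx(0.0, abs=TOL)
        below = isolation_total(CommunityScenario(0.3, (GuildMember(hook, 0.0, 1.0),)))
        above = isolation_total(CommunityScenario(0.7, (GuildMember(hook, 0.0, 1.0),)))
        assert below < 0 < above

    def test_out_of_range_hook_raises_at_evaluation(self):
        member = GuildMember(lambda f: 2.0, 0.0, 1.0, "bad")
        with pytest.raises(DomainError, match="hook"):
            isolation_total(CommunityScenario(0.5, (member,)))

    def test_linear_hook_strength_validated(self):
        with pytest.raises(DomainError):
            linear_preference(1.5)


class TestScenarioValidation:
    def test_visit_shares_must_sum_to_one(self):
        with pytest.raises(DomainError, match="sum to 1"):
            CommunityScenario(0.5, guild((0.0, 0.0, 0.4), (0.0, 0.0, 0.4)))

    def test_empty_guild_rejected(self):
        with pytest.raises(DomainError, match="at least one"):
            CommunityScenario(0.5, ())

    def test_with_frequency_preserves_guild(self):
        sc = CommunityScenario(0.5, guild((0.2, 0.1, 1.0)))
        assert sc.with_frequency(0.25).guild == sc.guild
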