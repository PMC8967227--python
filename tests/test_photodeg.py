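"""Tier-2 electron-transfer energetics, kinetics, and composite scoring."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pestiscreen import (
    Compound,
    LinearModel,
    MixtureSummary,
    PairResult,
    Sensitizer,
    composite_score,
    fit_linear,
    logk_from_barrier,
    marcus_barrier,
    mixture_average,
    percentile_rank,
    predict_dg,
)
from pestiscreen.errors import ParameterError, ValidationError

EV = 23.0605


class TestPredictDg:
    def test_unit_conversion_identity_model(self):
        c = Compound(id="c", e_homo=-6.0, e_lumo=0.0, log_d=0.0)
        s = Sensitizer(id="s", cdom_class="q", e_somo=-5.0)  # gap = 1 eV
        model = LinearModel(slope=EV, intercept=0.0)
        assert predict_dg(c, s, model) == pytest.approx(EV)

    def test_zero_gap(self):
        c = Compound(id="c", e_homo=-5.0, e_lumo=0.0, log_d=0.0)
        s = Sensitizer(id="s", cdom_class="q", e_somo=-5.0)
        model = LinearModel(slope=EV, intercept=0.0)
        assert predict_dg(c, s, model) == pytest.approx(0.0)

    def test_refit_recovers_generating_coefficients(self):
        """Noiseless pairs generated from a line refit to it exactly."""
        rng = np.random.default_rng(0)
        gaps = rng.uniform(-1, 2, 40)
        dgs = 10.0 * gaps - 5.0
        fit = fit_linear(gaps, dgs)
        assert fit.slope == pytest.approx(10.0, abs=1e-9)
        assert fit.intercept == pytest.approx(-5.0, abs=1e-9)


class TestMarcusBarrier:
    @pytest.mark.parametrize("dg,lam,expected", [
        (0.0, 20.0, 5.0),       # lambda/4
        (-20.0, 20.0, 0.0),     # activationless point
        (10.0, 40.0, 15.625),   # (50)^2/160
    ])
    def test_closed_form(self, dg, lam, expected):
        assert marcus_barrier(dg, lam) == pytest.approx(expected)

    def test_nonpositive_lambda_rejected(self):
        with pytest.raises(ParameterError):
            marcus_barrier(0.0, 0.0)

    @given(lam=st.floats(min_value=1.0, max_value=100.0),
           dg=st.floats(min_value=-150, max_value=150),
           eps=st.floats(min_value=0.01, max_value=50))
    def test_convex_with_vertex_at_minus_lambda(self, lam, dg, eps):
        """Barrier is non-negative, zero only at dg = -lambda, and grows
        symmetrically on both sides of the vertex (normal and inverted
        regions)."""
        b = marcus_barrier(dg, lam)
        assert b >= 0.0
        assert marcus_barrier(-lam, lam) == pytest.approx(0.0)
        left = marcus_barrier(-lam - eps, lam)
        right = marcus_barrier(-lam + eps, lam)
        assert left == pytest.approx(right, rel=1e-9)
        assert left > 0


class TestLogkFromBarrier:
    def test_linear_region(self):
        model = LinearModel(slope=-0.5, intercept=12.0)
        assert logk_from_barrier(5.0, model, cap=99.0) == pytest.approx(9.5)

    def test_diffusion_cap_engages(self):
        model = LinearModel(slope=-0.5, intercept=12.0)
        assert logk_from_barrier(0.0, model, cap=9.7) == pytest.approx(9.7)

    @given(b1=st.floats(min_value=0, max_value=50),
           b2=st.floats(min_value=0, max_value=50))
    def test_monotone_nonincreasing(self, b1, b2):
        model = LinearModel(slope=-0.5, intercept=12.0)
        lo, hi = sorted((b1, b2))
        assert (logk_from_barrier(lo, model, 9.7)
                >= logk_from_barrier(hi, model, 9.7))


def _pair(cid, dg, logk):
    return PairResult(compound_id=cid, sensitizer_id="s", gap=0.0,
                      dg_et0=dg, dg_barrier=1.0, log_k=logk)


class TestMixtureAverage:
    def test_constant_pairs(self):
        summ = mixture_average([_pair("c", 4.0, 9.0)] * 3)
        assert summ.mean_dg_et0 == pytest.approx(4.0)
        assert summ.mean_log_k == pytest.approx(9.0)
        assert summ.n_pairs == 3

    def test_arithmetic_mean(self):
        summ = mixture_average([_pair("c", 0.0, 8.0), _pair("c", 10.0, 9.0)])
        assert summ.mean_dg_et0 == pytest.approx(5.0)

    def test_empty_and_mixed_ids_rejected(self):
        with pytest.raises(ValidationError):
            mixture_average([])
        with pytest.raises(ValidationError):
            mixture_average([_pair("a", 0, 8), _pair("b", 0, 8)])


class TestPercentileRank:
    def test_unique_maximum_scores_100(self):
        assert percentile_rank([1.0, 2.0, 3.0, 4.0], 4.0) == pytest.approx(100.0)

    def test_median_scores_50(self):
        assert percentile_rank([1, 2, 3, 4, 5], 3.0) == pytest.approx(50.0)

    def test_below_all_scores_0(self):
        assert percentile_rank([1, 2, 3], -10.0) == pytest.approx(0.0)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValidationError):
            percentile_rank([], 1.0)

    @given(values=st.lists(st.floats(min_value=-100, max_value=100), min_size=1,
                           max_size=40),
           x=st.floats(min_value=-200, max_value=200))
    def test_counting_oracle(self, values, x):
        """For an external query the rank equals the counting formula
        (#below + half the ties) / n."""
        expected = 100.0 * (
            sum(1 for v in values if v < x)
            + 0.5 * sum(1 for v in values if v == x)
        ) / len(values)
        got = percentile_rank(values, x, exclude_self=False)
        assert got == pytest.approx(expected)


class TestCompositeScore:
    def _summaries(self, dgs, logks):
        return [
            MixtureSummary(compound_id=f"c{i}", mean_dg_et0=d,
                           mean_log_k=k, n_pairs=3)
            for i, (d, k) in enumerate(zip(dgs, logks))
        ]

    def test_best_on_both_axes_scores_100(self):
        rng = np.random.default_rng(1)
        dgs = list(rng.uniform(0, 20, 9)) + [-5.0]   # lowest dg wins
        lks = list(rng.uniform(7, 9, 9)) + [9.6]     # highest logk wins
        scores = composite_score(self._summaries(dgs, lks))
        assert scores[-1].score == pytest.approx(100.0)

    def test_mean_rule(self):
        # engineered so compound 0 is 40th on log k, 60th on dg
        dgs = [2.0, 1.0, 3.0, 4.0, 5.0]
        lks = [8.3, 8.1, 8.2, 8.4, 8.5]
        scores = composite_score(self._summaries(dgs, lks))
        s0 = scores[0]
        assert s0.score == pytest.approx(0.5 * (s0.pct_log_k + s0.pct_dg))

    def test_single_compound_rejected(self):
        with pytest.raises(ValidationError, match="population"):
            composite_score(self._summaries([1.0], [8.0]))

    def test_invariant_under_monotone_transform(self):
        """Rank-based scoring ignores any strictly increasing rescaling of
        the kinetic axis."""
        rng = np.random.default_rng(2)
        dgs = rng.uniform(-5, 25, 50)
        lks = rng.uniform(6, 10, 50)
        base = composite_score(self._summaries(dgs, lks))
        warped = composite_score(self._summaries(dgs, np.exp(lks / 3.0)))
        for a, b in zip(base, warped):
            assert a.score == pytest.approx(b.score)

    def test_matches_sorted_rank_oracle(self):
        """Scores agree with an independent midrank computation."""
        from scipy.stats import rankdata

        rng = np.random.default_rng(3)
        dgs = rng.uniform(-5, 25, 50)
        lks = rng.uniform(6, 10, 50)
        scores = composite_score(self._summaries(dgs, lks))
        # midrank against the other n-1 members: (rank - 1) / (n - 1)
        pct_k = 100.0 * (rankdata(lks) - 1) / (len(lks) - 1)
        pct_d = 100.0 * (rankdata(-dgs) - 1) / (len(dgs) - 1)
        for i, s in enumerate(scores):
            assert s.score == pytest.approx(0.5 * (pct_k[i] + pct_d[i]))
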