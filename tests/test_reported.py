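"""The reported-lifespan distribution: densities, survivorship, hazards, life tables."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import integrate

from lastseen import (
    Gompertz,
    ReportedLaw,
    Weibull,
    discrete_hazards,
    double_recovery_probability,
    reported_interval_fractions,
)

from conftest import STUDY_MODELS, model_id

EULER_GAMMA = 0.57721566490153286


def exp1_series(x: float, terms: int = 60) -> float:
    """Exponential integral E1 by its convergent series (independent oracle)."""
    s = -EULER_GAMMA - math.log(x)
    for k in range(1, terms + 1):
        s += (-1) ** (k + 1) * x**k / (k * math.factorial(k))
    return s


class TestExponentialClosedForms:
    """For a unit-exponential real law the reported law has E1 closed forms."""

    law = ReportedLaw(Weibull(m0=0, b=1, c=1))

    def test_density_is_exponential_integral(self):
        assert self.law.pdf(1.0) == pytest.approx(exp1_series(1.0), abs=1e-8)
        assert self.law.pdf(0.5) == pytest.approx(exp1_series(0.5), abs=1e-8)

    def test_survival_closed_form(self):
        # s_Y(y) = exp(-y) - y * E1(y)
        for y in (0.5, 1.0, 2.0):
            expected = math.exp(-y) - y * exp1_series(y)
            assert self.law.survival(y) == pytest.approx(expected, abs=1e-8)


def test_validation():
    with pytest.raises(ValueError):
        ReportedLaw(Weibull(), truncation=0.0)
    with pytest.raises(ValueError):
        ReportedLaw(Weibull(), tol=-1.0)
    law = ReportedLaw(Weibull(m0=0, b=1, c=2))
    with pytest.raises(ValueError):
        law.pdf(0.0)  # density diverges logarithmically at the onset
    with pytest.raises(ValueError):
        law.survival(-1.0)


def test_survival_at_onset_is_one():
    for model in (Weibull(m0=0.2, b=1, c=2), Gompertz(m0=0, theta=0.2, lam=0.5)):
        assert ReportedLaw(model).survival(0.0) == 1.0


@pytest.mark.parametrize("model", STUDY_MODELS, ids=model_id)
def test_reported_density_decreasing_and_below_real_survival(model):
    """f_Y is strictly decreasing; the reported lifespan is stochastically
    smaller than the real one, so s_Y <= s_X everywhere."""
    law = ReportedLaw(model)
    mean = model.mean_lifespan()
    grid = np.geomspace(1e-3 * mean, float(model.quantile(1 - 1e-3)), 25)
    f = np.asarray(law.pdf(grid))
    assert np.all(np.diff(f) < 0)
    assert np.asarray(law.pdf(0.5 * mean)) > np.asarray(law.pdf(mean))
    s_rep = np.asarray(law.survival(grid))
    s_real = np.asarray(model.survival(grid))
    assert np.all(s_rep <= s_real + 1e-12)


@pytest.mark.parametrize(
    "model",
    [Weibull(m0=0, b=1, c=2), Gompertz(m0=0.2, theta=0.2, lam=0.2)],
    ids=model_id,
)
def test_survival_matches_double_integral_oracle(model):
    """The single-integral survivorship equals the direct double integral
    of the reported density (order of integration exchanged)."""
    law = ReportedLaw(model)
    upper = float(model.quantile(1 - 1e-12))
    for y in (0.3, 1.0):
        direct, _ = integrate.quad(lambda u: law.pdf(u), y, upper, limit=200)
        assert law.survival(y) == pytest.approx(direct, abs=1e-6)


def test_hazard_is_density_over_survival():
    law = ReportedLaw(Gompertz(m0=0, theta=0.2, lam=0.2))
    y = np.array([0.1, 0.5, 1.0, 3.0])
    assert np.allclose(law.hazard(y), np.asarray(law.pdf(y)) / np.asarray(law.survival(y)), rtol=1e-8)


def test_hazard_tail_floor_reported():
    law = ReportedLaw(Weibull(m0=0, b=1, c=2))
    beyond = float(law.model.quantile(1 - 1e-12)) * 1.01  # survivorship < 1e-12
    with pytest.raises(RuntimeError):
        law.hazard(beyond)


def test_weibull_shallow_shape_reported_hazard_declines_with_age():
    """For c = 1.25 the reported mortality risk declines over the bulk of
    the distribution even though the real mortality risk increases."""
    model = Weibull(m0=0, b=1, c=1.25)
    law = ReportedLaw(model)
    assert law.hazard(0.1) > law.hazard(2.0)
    grid = np.linspace(1e-3 * model.mean_lifespan(), 1.0, 30)
    assert np.all(np.diff(law.hazard(grid)) < 0)
    assert np.all(np.diff(model.hazard(grid)) > 0)


def test_onset_mortality_overestimated_for_steep_shape():
    """Near the onset the reported hazard exceeds the real hazard (c = 3)."""
    model = Weibull(m0=0, b=1, c=3)
    law = ReportedLaw(model)
    assert law.hazard(0.05) > model.hazard(0.05)


@pytest.mark.parametrize(
    "make",
    [lambda m0: Weibull(m0=m0, b=1, c=2), lambda m0: Gompertz(m0=m0, theta=0.2, lam=0.2)],
    ids=["weibull", "gompertz"],
)
def test_onset_overestimation_grows_with_age_independent_mortality(make):
    """The early reported hazard increases with m0 across {0, 0.2, 0.5}."""
    hazards = []
    for m0 in (0.0, 0.2, 0.5):
        model = make(m0)
        y0 = 1e-3 * model.mean_lifespan()
        hazards.append(float(ReportedLaw(model).hazard(y0)))
    assert hazards[0] < hazards[1] < hazards[2]


def test_mean_reported_lifespan_is_half_the_real_mean():
    """E[Y] = E[X]/2: reporting is uniform over each individual's life."""
    for model in (Weibull(m0=0, b=1, c=2), Gompertz(m0=0.2, theta=0.2, lam=0.5)):
        law = ReportedLaw(model)
        upper = float(model.quantile(1 - 1e-12))
        mean_y, _ = integrate.quad(lambda y: y * law.pdf(y), 0, upper, limit=300)
        assert mean_y == pytest.approx(model.mean_lifespan() / 2, abs=1e-5)
        assert law.mean() == pytest.approx(model.mean_lifespan() / 2, rel=1e-12)


def test_tabulate_matches_pointwise_quadrature():
    """The fast cumulative-integration table agrees with adaptive quadrature."""
    law = ReportedLaw(Gompertz(m0=0, theta=0.2, lam=0.5))
    tab = law.tabulate(n_grid=8193)
    # compare in the bulk of the distribution; in the extreme tail (real
    # survivorship ~1e-11) only absolute accuracy is retained
    pick = np.linspace(200, 7000, 7, dtype=int)
    ages = tab["age"][pick]
    assert np.allclose(tab["pdf"][pick], np.asarray(law.pdf(ages)), rtol=1e-4, atol=1e-10)
    assert np.allclose(tab["survival"][pick], np.asarray(law.survival(ages)), rtol=1e-4, atol=1e-10)
    cdf = law.cdf_interpolator()
    assert float(cdf(np.array([0.0]))[0]) == pytest.approx(0.0, abs=1e-6)
    assert float(cdf(np.array([1e9]))[0]) == 1.0


class TestDiscreteHazards:
    def test_everyone_dies_in_first_interval(self):
        table = discrete_hazards([0.2, 0.7, 0.9], width=1.0)
        assert table.fractions.tolist() == [1.0]
        assert table.hazards.tolist() == [1.0]

    def test_life_table_recursion(self):
        table = discrete_hazards([0.5, 1.5], width=1.0)
        assert np.allclose(table.fractions, [0.5, 0.5])
        assert np.allclose(table.hazards, [0.5, 1.0])

    def test_validation(self):
        with pytest.raises(ValueError):
            discrete_hazards([], width=1.0)
        with pytest.raises(ValueError):
            discrete_hazards([1.0], width=0.0)
        with pytest.raises(ValueError):
            discrete_hazards([-1.0], width=1.0)

    def test_reported_first_interval_overestimated_worked_example(self):
        """Real fractions {0.5, 0.5}: the reported first-interval hazard is
        0.5/1 + 0.5/2 = 0.75, above the real first-interval hazard 0.5."""
        fy = reported_interval_fractions([0.5, 0.5])
        assert np.allclose(fy, [0.75, 0.25])
        assert fy[0] > discrete_hazards([0.5, 1.5], width=1.0).hazards[0]

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=8).filter(lambda f: sum(f) > 0))
    def test_first_interval_overestimation_any_real_distribution(self, raw):
        """f_Y(1) >= f_X(1) with equality iff all mass is in interval 1 —
        onset mortality is overestimated under any aging model."""
        f = np.asarray(raw) / sum(raw)
        fy = reported_interval_fractions(f)
        assert fy[0] >= f[0] - 1e-12
        assert fy.sum() == pytest.approx(1.0, abs=1e-9)
        if f[1:].sum() > 1e-9:
            assert fy[0] > f[0]
        else:
            assert fy[0] == pytest.approx(f[0], abs=1e-12)


def test_double_recovery_probability_bound():
    """At per-occasion recovery <= 10%, two recoveries have probability <= 1%,
    justifying the at-most-once reporting assumption."""
    assert double_recovery_probability(0.10) == pytest.approx(0.01)
    assert double_recovery_probability(0.10) <= np.nextafter(0.01, 1)  # 1 ulp for 0.1*0.1
    assert double_recovery_probability(0.03) == pytest.approx(0.0009)
    with pytest.raises(ValueError):
        double_recovery_probability(1.5)
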