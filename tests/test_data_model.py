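import math
from fractions import Fraction

import pytest
from hypothesis import given, settings, strategies as st

from micromle import (
    EnumerationDataset,
    FullyCensoredError,
    Observation,
    ParseError,
    PlatingScheme,
    ValidationError,
    censored_fraction,
    compute_loq,
    dataset_from_json,
    dataset_to_json,
    infer_mode,
    parse_interval_counts,
    parse_quantitative,
    read_csv,
    to_fitting_convention,
    write_csv,
)


@pytest.mark.parametrize("scheme,expected", [
    (PlatingScheme(25, 225), 10.0),                              # 1:10 homogenate
    (PlatingScheme(10, 90, extra_dilution_factor=10), 100.0),    # extra 10-fold
    (PlatingScheme(1, 9), 10.0),                                 # ratio invariance
    (PlatingScheme(25, 225, plated_volume=0.1), 100.0),          # smaller plating
])
def test_loq_from_plating_scheme(scheme, expected):
    assert compute_loq(scheme) == pytest.approx(expected)


@given(mass=st.floats(0.1, 1000), vol=st.floats(0.1, 1000),
       scale=st.floats(0.01, 100))
@settings(derandomize=True, max_examples=50)
def test_loq_is_homogeneous_in_homogenate_scale(mass, vol, scale):
    """Scaling sample mass and diluent volume together leaves the LOQ fixed."""
    a = compute_loq(PlatingScheme(mass, vol))
    b = compute_loq(PlatingScheme(mass * scale, vol * scale))
    assert a == pytest.approx(b, rel=1e-9)


@pytest.mark.parametrize("kwargs", [
    dict(sample_mass=0, diluent_volume=225),
    dict(sample_mass=25, diluent_volume=-1),
    dict(sample_mass=25, diluent_volume=225, plated_volume=0),
    dict(sample_mass=25, diluent_volume=225, extra_dilution_factor=0.5),
])
def test_invalid_plating_scheme_rejected(kwargs):
    with pytest.raises(ValidationError):
        PlatingScheme(**kwargs)


class TestParseQuantitative:
    def test_values_and_nd_become_exact_and_censored(self):
        ds = parse_quantitative([20, "ND", 300], loq=10)
        exact = sorted(o.value for o in ds.observations if o.kind == "exact")
        assert exact == pytest.approx([math.log10(20), math.log10(300)])
        (cens,) = [o for o in ds.observations if o.kind == "left_censored"]
        assert cens.upper == pytest.approx(1.0)
        assert cens.weight == 1
        assert ds.mode == "QN_3"

    def test_fully_censored_input_rejected(self):
        with pytest.raises(FullyCensoredError):
            parse_quantitative(["ND", "ND"], loq=10)

    def test_counts_and_mode_for_mixed_dataset(self):
        records = [50] * 10 + ["ND"] * 5
        ds = parse_quantitative(records, loq=10)
        assert (ds.n_detected, ds.m_censored) == (10, 5)
        assert ds.mode == "QN_3"
        assert censored_fraction(ds) == Fraction(1, 3)

    def test_no_nd_dispatches_to_qn1(self):
        ds = parse_quantitative([15, 200], loq=10)
        assert ds.mode == "QN_1"
        assert ds.m_censored == 0

    def test_detected_below_loq_is_a_contradiction(self):
        with pytest.raises(ValidationError, match="below the LOQ"):
            parse_quantitative([5, 20], loq=10)

    def test_garbage_token_is_a_parse_error(self):
        with pytest.raises(ParseError):
            parse_quantitative(["twenty"], loq=10)


class TestParseIntervalCounts:
    DECADES = [(10, 100), (100, 1000), (1000, 10**4), (10**4, 10**5), (10**5, 10**6)]

    def test_case1_shape(self):
        counts = (258, 368, 234, 44, 2)
        bins = [(lo, hi, c) for (lo, hi), c in zip(self.DECADES, counts)]
        ds = parse_interval_counts(bins, nd_count=214, loq=10)
        assert ds.total_weight == 1120
        assert ds.m_censored == 214
        assert ds.mode == "QN_4"

    def test_blank_cells_enter_as_zero_and_are_dropped(self):
        counts = (16, 2, 1, 0, 0)  # trailing blanks of a published row
        bins = [(lo, hi, c) for (lo, hi), c in zip(self.DECADES, counts)]
        ds = parse_interval_counts(bins, nd_count=81, loq=10)
        assert ds.total_weight == 100
        assert sum(1 for o in ds.observations if o.kind == "interval") == 3

    def test_no_nd_dispatches_to_qn2(self):
        ds = parse_interval_counts([(10, 100, 5)], nd_count=0, loq=10)
        assert ds.mode == "QN_2"
        assert ds.m_censored == 0

    def test_overlapping_bins_rejected(self):
        with pytest.raises(ValidationError, match="verlap"):
            parse_interval_counts([(10, 100, 3), (50, 500, 2)], 0, loq=10)

    def test_bin_below_loq_rejected(self):
        with pytest.raises(ValidationError, match="below the LOQ"):
            parse_interval_counts([(1, 10, 3)], 0, loq=10)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValidationError):
            parse_interval_counts([(10, 100, 0)], 5, loq=10)


class TestCensoredFraction:
    def test_exact_rationals_for_case_tables(self, cases):
        assert censored_fraction(cases[2]) == Fraction(1008, 1120) == Fraction(9, 10)
        assert censored_fraction(cases[4]) == Fraction(81, 100)

    def test_zero_when_nothing_censored(self):
        ds = parse_quantitative([15, 200], loq=10)
        assert censored_fraction(ds) == 0


@given(censored=st.booleans(), interval=st.booleans())
def test_mode_dispatch_biconditional(censored, interval):
    """Censored data <-> QN_3/QN_4; interval data <-> QN_2/QN_4."""
    mode = infer_mode(censored, interval)
    assert (mode in ("QN_3", "QN_4")) == censored
    assert (mode in ("QN_2", "QN_4")) == interval


def test_dataset_mode_must_match_shape():
    obs = (Observation.exact(1.5), Observation.left_censored(1.0, weight=2))
    with pytest.raises(ValidationError, match="inconsistent"):
        EnumerationDataset(obs, loq=10, mode="QN_1")


class TestFittingConvention:
    def test_midpoints_are_arithmetic_on_linear_scale(self):
        ds = parse_interval_counts([(10, 100, 3)], nd_count=2, loq=10)
        work = to_fitting_convention(ds)
        (exact,) = [o for o in work.observations if o.kind == "exact"]
        assert exact.value == pytest.approx(math.log10(55.0))
        assert exact.weight == 3

    def test_nd_bound_integer_is_loq_minus_one(self):
        ds = parse_interval_counts([(10, 100, 3)], nd_count=2, loq=10)
        work = to_fitting_convention(ds, nd_bound="integer")
        (cens,) = [o for o in work.observations if o.kind == "left_censored"]
        assert cens.upper == pytest.approx(math.log10(9.0))

    def test_identity_under_likelihood_and_loq_options(self, cases):
        work = to_fitting_convention(cases[1], "likelihood", "loq")
        assert work.observations == cases[1].observations


# ---------------------------------------------------------------------------
# serialization round trips

_observations = st.lists(
    st.one_of(
        st.builds(Observation.exact,
                  st.floats(1.0, 6.0), st.integers(1, 50)),
        st.builds(Observation.interval,
                  st.just(1.0), st.floats(2.0, 6.0), st.integers(1, 50)),
    ),
    min_size=1, max_size=8,
)


@given(obs=_observations, nd=st.integers(0, 100))
@settings(derandomize=True, max_examples=50)
def test_json_round_trip_is_bit_exact(obs, nd):
    if nd:
        obs = list(obs) + [Observation.left_censored(1.0, weight=nd)]
    has_i = any(o.kind == "interval" for o in obs)
    ds = EnumerationDataset(tuple(obs), 10.0, infer_mode(nd > 0, has_i), "prop")
    back = dataset_from_json(dataset_to_json(ds))
    assert back.observations == ds.observations
    assert back.loq == ds.loq and back.mode == ds.mode and back.label == ds.label


def test_interval_csv_round_trip_exact_for_decade_tables(tmp_path, cases):
    path = tmp_path / "case1.csv"
    write_csv(cases[1], path)
    back = read_csv(path)
    assert back.observations == cases[1].observations
    assert back.loq == cases[1].loq and back.mode == cases[1].mode


def test_quantitative_csv_round_trip(tmp_path):
    ds = parse_quantitative([20, 300, "ND", "ND", 55.5], loq=10)
    path = tmp_path / "q.csv"
    write_csv(ds, path)
    back = read_csv(path)
    assert back.m_censored == 2 and back.n_detected == 3
    for a, b in zip(back.observations, ds.observations):
        if a.kind == "exact":
            assert a.value == pytest.approx(b.value, abs=1e-12)
        else:
            assert a == b


def test_bundled_cases_match_published_counts(cases):
    totals = {1: 1120, 2: 1120, 3: 100, 4: 100}
    nds = {1: 214, 2: 1008, 3: 16, 4: 81}
    for i, ds in cases.items():
        assert ds.total_weight == totals[i]
        assert ds.m_censored == nds[i]
        assert ds.loq == 10.0
        assert ds.mode == "QN_4"
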