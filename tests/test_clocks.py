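"""Clock loading and linear DNAm-age evaluation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from epimobility import (
    BetaMatrix,
    ClockDefinition,
    FormatError,
    ValidationError,
    compute_dnam_age,
    load_beta_matrix,
    load_clock_definition,
)
from epimobility.clocks import save_clock_definition


def _write(tmp_path, text, name="clock.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestLoadClockDefinition:
    def test_intercept_only(self, tmp_path):
        clock = load_clock_definition(_write(tmp_path, "probe,coefficient\n(Intercept),50.0\n"))
        assert clock.m == 0 and clock.intercept == 50.0

    def test_read_back(self, tmp_path):
        p = _write(tmp_path, "probe,coefficient\n(Intercept),10\ncgA,2\ncgB,-1\n")
        clock = load_clock_definition(p)
        assert clock.m == 2
        assert clock.coefficients == {"cgA": 2.0, "cgB": -1.0}

    def test_tab_delimited(self, tmp_path):
        p = _write(tmp_path, "probe\tcoefficient\n(Intercept)\t10\ncgA\t2\n")
        assert load_clock_definition(p).coefficients == {"cgA": 2.0}

    @pytest.mark.parametrize(
        "body",
        [
            "(Intercept),10\ncgA,2\ncgA,3\n",  # duplicate probe
            "(Intercept),10\ncgA,abc\n",  # non-numeric coefficient
            "cgA,2\ncgB,-1\n",  # no intercept row
            "(Intercept),10\n(Intercept),11\ncgA,2\n",  # two intercepts
        ],
    )
    def test_format_errors(self, tmp_path, body):
        with pytest.raises(FormatError):
            load_clock_definition(_write(tmp_path, "probe,coefficient\n" + body))

    def test_round_trip_through_file(self, tmp_path, toy_clock):
        save_clock_definition(toy_clock, tmp_path / "c.csv")
        back = load_clock_definition(tmp_path / "c.csv", name="toy")
        assert back.intercept == toy_clock.intercept
        assert back.coefficients == toy_clock.coefficients

    def test_nonfinite_coefficient_rejected(self):
        with pytest.raises(ValidationError):
            ClockDefinition(name="bad", intercept=np.nan, coefficients={})


class TestComputeDnamAge:
    def test_intercept_only_clock(self, beta_frame):
        clock = ClockDefinition(name="c", intercept=50.0, coefficients={})
        res = compute_dnam_age(BetaMatrix.from_dataframe(beta_frame), clock)
        assert np.allclose(res.dnam_age, 50.0)

    def test_hand_arithmetic(self, toy_clock, beta_frame):
        res = compute_dnam_age(BetaMatrix.from_dataframe(beta_frame), toy_clock)
        # 10 + 2*0.5 - 1*0.2 + 0.5*0.8 = 11.2
        assert res.dnam_age[0] == pytest.approx(11.2, abs=1e-12)
        assert res.probes_missing == 0 and res.probes_used == 3

    def test_missing_probe_dropped_without_rescaling(self, toy_clock, beta_frame):
        res = compute_dnam_age(
            BetaMatrix.from_dataframe(beta_frame.drop(index="cgC")), toy_clock
        )
        assert res.dnam_age[0] == pytest.approx(10.8, abs=1e-12)
        assert res.probes_missing == 1 and res.missing_probe_ids == ["cgC"]

    def test_all_probes_absent_gives_intercept(self, toy_clock):
        betas = BetaMatrix.from_dataframe(
            pd.DataFrame({"s1": [0.3]}, index=["cgZZ"])
        )
        res = compute_dnam_age(betas, toy_clock)
        assert res.dnam_age[0] == toy_clock.intercept
        assert res.probes_missing == 3

    def test_nan_beta_drops_term_for_that_sample_only(self, toy_clock, beta_frame):
        frame = beta_frame.copy()
        frame.loc["cgC", "s1"] = np.nan
        res = compute_dnam_age(BetaMatrix.from_dataframe(frame), toy_clock)
        assert res.dnam_age[0] == pytest.approx(10.8, abs=1e-12)  # cgC term dropped
        assert res.dnam_age[1] == pytest.approx(10 + 0.2 - 0.4 + 0.3, abs=1e-12)

    def test_out_of_range_beta(self, toy_clock, beta_frame):
        frame = beta_frame.copy()
        frame.loc["cgA", "s1"] = 1.5
        with pytest.raises(ValidationError):
            compute_dnam_age(BetaMatrix.from_dataframe(frame), toy_clock)
        # warn policy computes anyway
        res = compute_dnam_age(BetaMatrix.from_dataframe(frame), toy_clock, on_invalid="warn")
        assert np.isfinite(res.dnam_age).all()

    def test_gz_beta_matrix_loads(self, tmp_path, beta_frame):
        path = tmp_path / "betas.csv.gz"
        beta_frame.to_csv(path, index_label="probe")
        assert load_beta_matrix(path).to_dataframe().equals(beta_frame.astype(float))


@given(
    a=st.floats(0, 1),
    betas1=st.lists(st.floats(0, 1), min_size=3, max_size=3),
    betas2=st.lists(st.floats(0, 1), min_size=3, max_size=3),
)
def test_linearity_in_betas(toy_clock, a, betas1, betas2):
    """Clock output is affine: mixing beta matrices mixes predictions."""

    def age(vals):
        frame = pd.DataFrame({"s": vals}, index=["cgA", "cgB", "cgC"])
        return compute_dnam_age(BetaMatrix.from_dataframe(frame), toy_clock).dnam_age[0]

    b1, b2 = np.array(betas1), np.array(betas2)
    mixed = age(a * b1 + (1 - a) * b2)
    assert mixed == pytest.approx(a * age(b1) + (1 - a) * age(b2), abs=1e-10)


@given(perm=st.permutations([0, 1, 2]))
def test_probe_order_invariance(toy_clock, beta_frame, perm):
    base = compute_dnam_age(BetaMatrix.from_dataframe(beta_frame), toy_clock).dnam_age
    shuffled = beta_frame.iloc[list(perm)]
    res = compute_dnam_age(BetaMatrix.from_dataframe(shuffled), toy_clock).dnam_age
    assert np.allclose(base, res, atol=1e-12)


def test_zero_coefficient_probe_is_inert(beta_frame):
    with_zero = ClockDefinition(
        name="z", intercept=10.0, coefficients={"cgA": 2.0, "cgB": -1.0, "cgC": 0.0}
    )
    without = ClockDefinition(name="w", intercept=10.0, coefficients={"cgA": 2.0, "cgB": -1.0})
    B = BetaMatrix.from_dataframe(beta_frame)
    assert np.allclose(
        compute_dnam_age(B, with_zero).dnam_age, compute_dnam_age(B, without).dnam_age
    )
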