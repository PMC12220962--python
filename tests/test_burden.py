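"""Exact Poisson intervals, burden estimates and genome conversions."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.optimize import brentq

from mutburden import (
    additional_mutations,
    estimate_burden,
    estimate_burden_table,
    poisson_ci,
    se_from_ci,
    spectrum_from_mutations,
)


def poisson_ci_bisection(count: int, level: float = 0.95) -> tuple[float, float]:
    """Independent oracle: solve the Poisson tail-sum equations by bisection."""
    tail = (1.0 - level) / 2.0
    if count == 0:
        low = 0.0
    else:
        low = brentq(lambda lam: sps.poisson.sf(count - 1, lam) - tail,
                     1e-12, 10 * count + 50, xtol=1e-12, rtol=1e-12)
    high = brentq(lambda lam: sps.poisson.cdf(count, lam) - tail,
                  1e-12, 10 * count + 200, xtol=1e-12, rtol=1e-12)
    return low, high


@pytest.mark.parametrize(
    "count,expected",
    [
        (0, (0.0, 3.6889)),
        (1, (0.0253, 5.5716)),
        (100, (81.36, 121.63)),
    ],
)
def test_poisson_ci_frozen_values(count, expected):
    lo, hi = poisson_ci(count, 0.95)
    assert lo == pytest.approx(expected[0], abs=5e-3)
    assert hi == pytest.approx(expected[1], abs=5e-3)
    if count == 0:
        assert hi == pytest.approx(-np.log(0.025), rel=1e-12)


@pytest.mark.parametrize("count", [0, 1, 2, 5, 16, 37, 100, 413, 1000])
def test_poisson_ci_matches_tail_sum_oracle(count):
    lo, hi = poisson_ci(count, 0.95)
    olo, ohi = poisson_ci_bisection(count, 0.95)
    assert lo == pytest.approx(olo, rel=1e-6, abs=1e-9)
    assert hi == pytest.approx(ohi, rel=1e-6)


def test_poisson_ci_endpoints_strictly_increase():
    lows, highs = zip(*(poisson_ci(n) for n in range(0, 200)))
    assert all(b > a for a, b in zip(lows[1:], lows[2:]))  # N >= 1
    assert all(b > a for a, b in zip(highs, highs[1:]))


def test_poisson_ci_coverage_is_conservative():
    rng = np.random.default_rng(11)
    lam = 10.0
    draws = rng.poisson(lam, size=2000)
    cover = sum(poisson_ci(int(n))[0] <= lam <= poisson_ci(int(n))[1] for n in draws)
    assert cover / 2000 >= 0.944


@pytest.mark.parametrize("bad", [-1, 2.5])
def test_poisson_ci_rejects_bad_counts(bad):
    with pytest.raises(ValueError):
        poisson_ci(bad)


def test_se_from_ci():
    # published liver-outlier interval endpoints
    assert se_from_ci(8.45e-7, 9.58e-7) == pytest.approx(2.8827e-8, rel=1e-4)
    # definitional: a +/-1.96-width interval has unit SE
    assert se_from_ci(0.0, 2 * 1.959964) == pytest.approx(1.0, rel=1e-6)
    assert se_from_ci(3.0, 3.0) == 0.0
    with pytest.raises(ValueError):
        se_from_ci(2.0, 1.0)


@pytest.mark.parametrize(
    "rate,G,expected",
    [
        (4.70e-8, 6.0e9, 282),
        (1.48e-7, 6.0e9, 888),
        (1.20e-7, 6.0e9, 720),
        (0.0, 6.0e9, 0),
        (-4.70e-8, 6.0e9, -282),
    ],
)
def test_additional_mutations_conversion(rate, G, expected):
    assert additional_mutations(rate, G) == expected


def _mut_rows(sample_id, contexts):
    return pd.DataFrame(
        {
            "sample_id": sample_id,
            "chrom": "chr1",
            "pos": np.arange(1, len(contexts) + 1),
            "ref": [c[2] for c in contexts],
            "alt": [c[4] for c in contexts],
            "context": contexts,
        }
    )


def test_estimate_burden_empty_and_composed():
    meta = {"sample_id": "S1", "duplex_bases": 1e9}
    empty = _mut_rows("S1", [])
    est = estimate_burden(meta, empty)
    assert est.count == 0 and est.rate == 0.0 and est.ci_low == 0.0

    ten = _mut_rows("S1", ["A[C>T]G"] * 10)
    est = estimate_burden(meta, ten)
    lo, hi = poisson_ci(10, 0.95)
    assert est.rate == pytest.approx(1.0e-8)
    assert est.ci_low == pytest.approx(lo / 1e9)
    assert est.ci_high == pytest.approx(hi / 1e9)
    assert est.se == pytest.approx(se_from_ci(lo / 1e9, hi / 1e9))


def test_mutations_per_genome_rounding():
    meta = {"sample_id": "S1", "duplex_bases": 3e9}
    est = estimate_burden(meta, _mut_rows("S1", ["A[C>T]G"] * 30), genome_equivalent=6e9)
    assert est.mutations_per_genome == 60


def test_estimate_burden_errors():
    with pytest.raises(ValueError, match="duplex_bases"):
        estimate_burden({"sample_id": "S1", "duplex_bases": 0}, _mut_rows("S1", []))
    with pytest.raises(ValueError, match="foreign"):
        estimate_burden(
            {"sample_id": "S1", "duplex_bases": 1e9}, _mut_rows("S2", ["A[C>T]G"])
        )


def test_estimate_burden_table_includes_zero_count_samples():
    meta = pd.DataFrame(
        {"sample_id": ["A", "B"], "duplex_bases": [1e9, 2e9]}
    )
    muts = _mut_rows("A", ["A[C>T]G"] * 4)
    table = estimate_burden_table(meta, muts)
    assert list(table["count"]) == [4, 0]
    assert table.loc[1, "rate"] == 0.0


def test_spectrum_binning_and_collapsing():
    spec = spectrum_from_mutations(_mut_rows("S", ["A[C>T]G"]))
    assert spec.total == 1
    assert spec.as_series()["A[C>T]G"] == 1

    # purine-centered record folds onto the pyrimidine channel
    spec = spectrum_from_mutations(_mut_rows("S", ["C[G>A]T"]))
    assert spec.as_series()["A[C>T]G"] == 1

    many = spectrum_from_mutations(_mut_rows("S", ["A[C>T]G", "T[T>G]T", "C[G>A]T"]))
    assert many.total == 3  # conservation without weights


def test_spectrum_weighting_preserves_total():
    contexts = ["A[C>T]G"] * 6 + ["T[T>C]A"] * 4
    w = np.ones(32)
    w[0] = 2.0  # up-weight ACA-type contexts (not present here) plus shifts
    spec = spectrum_from_mutations(_mut_rows("S", contexts), genome_context_weights=w)
    assert spec.total == pytest.approx(10.0)


def test_spectrum_malformed_context_names_record():
    with pytest.raises(ValueError, match="record 0"):
        spectrum_from_mutations(
            pd.DataFrame(
                {"sample_id": ["S"], "chrom": ["chr1"], "pos": [1],
                 "ref": ["C"], "alt": ["X"], "context": ["A[C>X]G"]}
            )
        )
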