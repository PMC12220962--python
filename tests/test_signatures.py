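"""Signature refitting: NNLS route, Bayesian route, diagnostics."""

import numpy as np
import pandas as pd
import pytest

from mutburden import (
    SignatureCatalogue,
    Spectrum96,
    fit_exposures_bayes,
    fit_exposures_regression,
    reconstruction_diagnostics,
)
from mutburden.contexts import CHANNELS_96


def _toy_catalogue(columns: dict[str, np.ndarray]) -> SignatureCatalogue:
    """Embed low-dimensional toy profiles into the 96-channel space."""
    mat = {}
    for name, w in columns.items():
        col = np.zeros(96)
        col[: len(w)] = w
        mat[name] = col / col.sum()
    return SignatureCatalogue(pd.DataFrame(mat, index=list(CHANNELS_96)))


def test_catalogue_validation():
    bad = pd.DataFrame({"S1": np.full(96, 1 / 96)}, index=list(CHANNELS_96))
    SignatureCatalogue(bad)  # valid
    with pytest.raises(ValueError, match="sum to 1"):
        SignatureCatalogue(bad * 0.8)
    neg = bad.copy()
    neg.iloc[0, 0] = -0.01
    with pytest.raises(ValueError, match="negative"):
        SignatureCatalogue(neg)


def test_exact_column_recovers_unit_exposure(catalogue):
    col = catalogue.matrix.iloc[:, 2].to_numpy()
    fit = fit_exposures_regression(Spectrum96(col * 5000), catalogue)
    assert fit.exposures.iloc[2] == pytest.approx(1.0, abs=1e-6)
    assert fit.residual == pytest.approx(0.0, abs=1e-8)
    assert fit.cosine == pytest.approx(1.0, abs=1e-8)


def test_single_signature_multinomial_recovery(catalogue):
    rng = np.random.default_rng(17)
    col = catalogue.matrix["SIG_THIOPURINE"].to_numpy()
    counts = rng.multinomial(10_000, col)
    fit = fit_exposures_regression(Spectrum96(counts), catalogue)
    assert fit.exposures["SIG_THIOPURINE"] >= 0.99


def test_orthogonal_spectrum_gets_zero_exposures():
    cat = _toy_catalogue({"A": np.array([1.0, 1.0]), "B": np.array([0.0, 2.0])})
    s = np.zeros(96)
    s[50:55] = 10.0  # mass where every signature is zero
    fit = fit_exposures_regression(Spectrum96(s), cat)
    assert (fit.exposures == 0).all()
    assert fit.cosine == 0.0


def test_nnls_matches_simplex_grid_oracle():
    """Two-signature 8-channel toy: the NNLS proportion agrees with an
    exhaustive grid search over the exposure simplex (step 0.001)."""
    rng = np.random.default_rng(23)
    c1 = np.array([5, 3, 1, 1, 0, 0, 0, 0], dtype=float)
    c2 = np.array([0, 0, 1, 1, 2, 4, 4, 2], dtype=float)
    cat = _toy_catalogue({"A": c1, "B": c2})
    truth = 0.7 * cat.matrix["A"].to_numpy() + 0.3 * cat.matrix["B"].to_numpy()
    counts = rng.multinomial(5000, truth)
    fit = fit_exposures_regression(Spectrum96(counts), cat, threshold=0.0)

    s = counts / counts.sum()
    C = cat.values
    grid = np.linspace(0, 1, 1001)
    dirs = np.outer(grid, C[:, 0]) + np.outer(1 - grid, C[:, 1])  # (1001, 96)
    scale = np.clip((dirs @ s) / np.einsum("ij,ij->i", dirs, dirs), 0, None)
    resid = np.linalg.norm(s[None, :] - scale[:, None] * dirs, axis=1)
    best = grid[int(np.argmin(resid))]
    assert fit.exposures["A"] == pytest.approx(best, abs=0.005)


def test_threshold_prunes_trace_signatures(catalogue):
    rng = np.random.default_rng(29)
    mix = np.array([0.02, 0.58, 0.0, 0.0, 0.4, 0.0])
    p = catalogue.values @ mix
    counts = rng.multinomial(20_000, p)
    fit = fit_exposures_regression(Spectrum96(counts), catalogue, threshold=0.05)
    assert fit.exposures["SIG_CLOCK_CPG"] == 0.0  # 2% component pruned
    assert fit.exposures.sum() == pytest.approx(1.0)
    assert fit.threshold == 0.05


def test_nnls_residual_is_locally_optimal(catalogue):
    rng = np.random.default_rng(31)
    mix = np.array([0.1, 0.4, 0.2, 0.0, 0.3, 0.0])
    counts = rng.multinomial(8000, catalogue.values @ mix)
    spectrum = Spectrum96(counts)
    fit = fit_exposures_regression(spectrum, catalogue, threshold=0.0)
    s = spectrum.normalized()
    C = catalogue.values
    # recover the raw-scale solution: exposures are normalized, so rescale
    # to the least-squares optimum along the fitted direction
    e_dir = fit.exposures.to_numpy()
    recon_dir = C @ e_dir
    t = (recon_dir @ s) / (recon_dir @ recon_dir)
    e_raw = e_dir * t
    base = np.linalg.norm(s - C @ e_raw)
    for j in range(len(e_raw)):
        for step in (0.01, -0.01):
            e_pert = e_raw.copy()
            e_pert[j] = max(0.0, e_pert[j] + step)
            assert np.linalg.norm(s - C @ e_pert) >= base - 1e-12


def test_bayes_two_signature_recovery(catalogue):
    rng = np.random.default_rng(37)
    sub = catalogue.subset(["SIG_PLATINUM_A", "SIG_THIOPURINE"])
    p = sub.values @ np.array([0.6, 0.4])
    counts = rng.multinomial(10_000, p)
    fit = fit_exposures_bayes(Spectrum96(counts), sub, seed=1)
    assert fit.exposures["SIG_PLATINUM_A"] == pytest.approx(0.6, abs=0.05)
    assert fit.exposures["SIG_THIOPURINE"] == pytest.approx(0.4, abs=0.05)
    assert (fit.rhat < 1.05).all()


def test_bayes_single_signature_catalogue(catalogue):
    sub = catalogue.subset(["SIG_CLOCK_FLAT"])
    counts = np.round(sub.values[:, 0] * 1000)
    fit = fit_exposures_bayes(Spectrum96(counts), sub)
    assert fit.exposures.iloc[0] == 1.0


def test_bayes_posterior_widens_with_fewer_counts(catalogue):
    rng = np.random.default_rng(41)
    sub = catalogue.subset(["SIG_PLATINUM_A", "SIG_THIOPURINE"])
    p = sub.values @ np.array([0.6, 0.4])
    big = fit_exposures_bayes(Spectrum96(rng.multinomial(10_000, p)), sub, seed=2)
    small = fit_exposures_bayes(Spectrum96(rng.multinomial(100, p)), sub, seed=2)
    assert small.draws[:, 0].std() > big.draws[:, 0].std()


def test_bayes_rejects_non_integer_counts(catalogue):
    with pytest.raises(ValueError, match="integer"):
        fit_exposures_bayes(Spectrum96(np.full(96, 0.5)), catalogue)


def test_reconstruction_diagnostics_conventions(catalogue):
    col = catalogue.matrix.iloc[:, 0]
    e = pd.Series(0.0, index=catalogue.names)
    e.iloc[0] = 1.0
    residual, cosine = reconstruction_diagnostics(Spectrum96(col * 100), catalogue, e)
    assert residual == pytest.approx(0.0, abs=1e-9)
    assert cosine == pytest.approx(1.0, abs=1e-9)
    with pytest.raises(ValueError):
        reconstruction_diagnostics(Spectrum96(np.zeros(96)), catalogue, e)
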