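"""Refitting 96-channel mutation spectra against a signature catalogue.

Two routes mirror common practice for attributing single-base-substitution
(SBS) mutational signatures to duplex-sequencing spectra:

* a non-negative multiple linear regression (NNLS) with iterative dropping
  of low-exposure signatures, and
* Bayesian inference under a multinomial likelihood with a flat Dirichlet
  prior on the exposure simplex, sampled by adaptive random-walk MCMC.

Both report per-signature proportions of mutations explained, plus
reconstruction diagnostics (residual L2 norm and cosine similarity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .contexts import CHANNELS_96
from .regression import split_rhat


class SignatureCatalogue:
    """A 96 x K matrix of signature channel probabilities.

    Parameters
    ----------
    matrix:
        DataFrame indexed by the 96 canonical channel labels, one column per
        signature; every column must be non-negative and sum to 1 within
        1e-6.
    """

    def __init__(self, matrix: pd.DataFrame):
        missing = [c for c in CHANNELS_96 if c not in matrix.index]
        if missing:
            raise ValueError(f"catalogue is missing channels: {missing[:3]}...")
        matrix = matrix.loc[list(CHANNELS_96)].astype(float)
        if (matrix.values < 0).any():
            raise ValueError("catalogue contains negative entries")
        sums = matrix.sum(axis=0)
        bad = sums[(sums - 1.0).abs() > 1e-6]
        if len(bad):
            raise ValueError(
                f"catalogue columns must sum to 1: {dict(bad.round(4))}"
            )
        self.matrix = matrix

    @property
    def names(self) -> list[str]:
        return list(self.matrix.columns)

    @property
    def values(self) -> np.ndarray:
        return self.matrix.values

    def __len__(self) -> int:
        return self.matrix.shape[1]

    def subset(self, names: list[str]) -> "SignatureCatalogue":
        return SignatureCatalogue(self.matrix[names])


@dataclass
class Spectrum96:
    """Counts (or weights) over the 96 canonical channels."""

    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (96,):
            raise ValueError("a spectrum must have exactly 96 channels")
        if (self.counts < 0).any():
            raise ValueError("spectrum channels must be non-negative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def normalized(self) -> np.ndarray:
        if self.total == 0:
            raise ValueError("cannot normalize an empty spectrum")
        return self.counts / self.total

    def as_series(self) -> pd.Series:
        return pd.Series(self.counts, index=list(CHANNELS_96), name="count")


@dataclass
class ExposureFit:
    """Per-signature exposure proportions and reconstruction diagnostics."""

    exposures: pd.Series
    residual: float
    cosine: float
    method: str
    threshold: float | None = None
    rhat: pd.Series | None = None
    draws: np.ndarray | None = field(default=None, repr=False)


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def reconstruction_diagnostics(
    spectrum: Spectrum96, catalogue: SignatureCatalogue, exposures: pd.Series
) -> tuple[float, float]:
    """Residual L2 norm and cosine similarity of a fit.

    Both are computed between the L1-normalized observed spectrum and the
    catalogue reconstruction ``C @ e``.
    """
    s = spectrum.normalized()
    e = exposures.reindex(catalogue.names).fillna(0.0).values
    recon = catalogue.values @ e
    return float(np.linalg.norm(s - recon)), _cosine(s, recon)


def fit_exposures_regression(
    spectrum: Spectrum96,
    catalogue: SignatureCatalogue,
    threshold: float = 0.05,
) -> ExposureFit:
    """Non-negative least-squares signature refit with iterative pruning.

    Minimizes ``|| s/||s||_1 - C e ||_2`` subject to ``e >= 0``, then
    repeatedly drops signatures whose exposure proportion falls below
    ``threshold`` and refits until the active set is stable. Exposure
    proportions are renormalized to sum to 1 over the retained signatures
    (all-zero fits are returned as all-zero).
    """
    if spectrum.total == 0:
        raise ValueError("cannot fit an empty spectrum")
    s = spectrum.normalized()
    active = list(catalogue.names)
    raw = np.zeros(len(active))
    while True:
        C = catalogue.matrix[active].values
        raw, _ = nnls(C, s)
        total = raw.sum()
        if total == 0:
            active = []
            break
        props = raw / total
        keep = [n for n, p in zip(active, props) if p >= threshold]
        if keep == active or not keep:
            active = keep
            break
        active = keep

    exposures = pd.Series(0.0, index=catalogue.names, name="exposure")
    recon = np.zeros(96)
    if active:
        C = catalogue.matrix[active].values
        raw, _ = nnls(C, s)
        if raw.sum() > 0:
            exposures[active] = raw / raw.sum()
        recon = C @ raw
    residual = float(np.linalg.norm(s - recon))
    return ExposureFit(
        exposures=exposures,
        residual=residual,
        cosine=_cosine(s, recon),
        method="nnls_regression",
        threshold=threshold,
    )


def _alr_to_simplex(z: np.ndarray) -> np.ndarray:
    """Additive log-ratio transform: z in R^{K-1} -> simplex point in R^K."""
    z_full = np.concatenate([z, np.zeros(z.shape[:-1] + (1,))], axis=-1)
    z_full -= z_full.max(axis=-1, keepdims=True)
    e = np.exp(z_full)
    return e / e.sum(axis=-1, keepdims=True)


def fit_exposures_bayes(
    spectrum: Spectrum96,
    catalogue: SignatureCatalogue,
    chains: int = 2,
    iterations: int = 4000,
    warmup: int = 2000,
    seed: int = 0,
) -> ExposureFit:
    """Bayesian multinomial signature refit.

    The observed channel counts are modeled as
    ``s ~ Multinomial(N, C e)`` with a flat Dirichlet(1, ..., 1) prior on the
    exposure vector ``e``. Sampling is adaptive random-walk Metropolis on the
    additive-log-ratio transform of ``e`` (the Dirichlet(1) prior contributes
    the log-Jacobian ``sum_k log e_k`` on that scale). Returns posterior-mean
    exposures, split-R-hat per signature, and the pooled posterior draws.
    """
    counts = spectrum.counts
    if not np.allclose(counts, np.round(counts)):
        raise ValueError("Bayesian refitting requires integer channel counts")
    if spectrum.total == 0:
        raise ValueError("cannot fit an empty spectrum")
    if warmup >= iterations:
        raise ValueError("warmup must be smaller than iterations")
    K = len(catalogue)
    names = catalogue.names
    if K == 1:
        exposures = pd.Series([1.0], index=names, name="exposure")
        residual, cosine = reconstruction_diagnostics(spectrum, catalogue, exposures)
        return ExposureFit(exposures, residual, cosine, "bayes_multinomial")

    C = catalogue.values
    s = counts

    def log_post(z: np.ndarray) -> np.ndarray:
        # z: (chains, K-1)
        e = _alr_to_simplex(z)
        p = np.clip(e @ C.T, 1e-300, None)  # (chains, 96)
        ll = (s[None, :] * np.log(p)).sum(axis=1)
        jac = np.log(np.clip(e, 1e-300, None)).sum(axis=1)
        return ll + jac

    rng = np.random.default_rng(np.random.SeedSequence((seed, 96)))
    z = rng.normal(0.0, 0.5, size=(chains, K - 1))
    lp = log_post(z)
    scale = np.full(K - 1, 0.2)
    kept = np.empty((chains, iterations - warmup, K), dtype=float)
    acc = np.zeros(K - 1)
    window = 0
    for it in range(iterations):
        for j in range(K - 1):
            prop = z.copy()
            prop[:, j] += rng.normal(0.0, scale[j], size=chains)
            lp_prop = log_post(prop)
            accept = np.log(rng.uniform(size=chains)) < lp_prop - lp
            z[accept] = prop[accept]
            lp[accept] = lp_prop[accept]
            acc[j] += accept.mean()
        window += 1
        if it < warmup and window == 50:
            rate = acc / window
            scale *= np.where(rate < 0.2, 0.7, np.where(rate > 0.4, 1.4, 1.0))
            acc[:] = 0.0
            window = 0
        if it >= warmup:
            kept[:, it - warmup] = _alr_to_simplex(z)

    pooled = kept.reshape(-1, K)
    exposures = pd.Series(pooled.mean(axis=0), index=names, name="exposure")
    rhat = pd.Series(
        [split_rhat(kept[:, :, k]) for k in range(K)], index=names, name="rhat"
    )
    residual, cosine = reconstruction_diagnostics(spectrum, catalogue, exposures)
    return ExposureFit(
        exposures=exposures,
        residual=residual,
        cosine=cosine,
        method="bayes_multinomial",
        rhat=rhat,
        draws=pooled,
    )


def synthetic_catalogue(n_flat: int = 2) -> SignatureCatalogue:
    """A synthetic six-signature catalogue for tests and simulation defaults.

    This is NOT COSMIC: it is a deterministic stand-in with the same layout.
    Two columns are flat-ish clock-like profiles (aging-style, loosely SBS1-
    and SBS5-like shapes: a CpG-heavy C>T column and a broad featureless
    column) and the rest are sharp, well-separated profiles occupying the
    substitution classes where the platinum- and thiopurine-associated
    signatures live. Real COSMIC v3.2 TSVs load through
    :func:`mutburden.io.read_catalogue` into the same container.
    """
    rng = np.random.default_rng(2024096)
    cols = {}

    # SBS1-like: C>T at NpCpG, i.e. channels x[C>T]G.
    w = np.full(96, 0.001)
    for i, ch in enumerate(CHANNELS_96):
        if "[C>T]" in ch and ch.endswith("G"):
            w[i] = 0.22
    cols["SIG_CLOCK_CPG"] = w / w.sum()

    # SBS5-like: broad, featureless.
    w = rng.dirichlet(np.full(96, 30.0))
    cols["SIG_CLOCK_FLAT"] = w

    # Platinum-like A: concentrated C>T with 5'-C preference.
    w = np.full(96, 1e-4)
    for i, ch in enumerate(CHANNELS_96):
        if "[C>T]" in ch and ch.startswith("C"):
            w[i] = 0.2
        elif "[C>A]" in ch and ch.startswith("C"):
            w[i] = 0.05
    cols["SIG_PLATINUM_A"] = w / w.sum()

    # Platinum-like B: broad C>A.
    w = np.full(96, 1e-4)
    for i, ch in enumerate(CHANNELS_96):
        if "[C>A]" in ch:
            w[i] = 0.06
    cols["SIG_PLATINUM_B"] = w / w.sum()

    # Thiopurine-like: T>A with 3'-C/G preference.
    w = np.full(96, 1e-4)
    for i, ch in enumerate(CHANNELS_96):
        if "[T>A]" in ch and ch[-1] in "CG":
            w[i] = 0.11
    cols["SIG_THIOPURINE"] = w / w.sum()

    # A sharp T>G profile to round out the simplex.
    w = np.full(96, 1e-4)
    for i, ch in enumerate(CHANNELS_96):
        if "[T>G]" in ch and ch.startswith("T"):
            w[i] = 0.24
    cols["SIG_TG_SHARP"] = w / w.sum()

    matrix = pd.DataFrame(cols, index=list(CHANNELS_96))
    return SignatureCatalogue(matrix)
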