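"""Synthetic duplex-sequencing cohorts with known ground truth.

The real cohorts behind chemotherapy-mutagenesis studies are restricted
access, so every downstream stage here is exercised on simulated cohorts
that reproduce the statistical structure the analysis assumes:

* per-sample true burden lambda_i = max(eps, intercept + slope*age_i +
  delta*1[exposed] + eta_i), with Normal(0, sigma_group^2) between-sample
  noise whose SD differs by exposure group;
* duplex bases B_i drawn uniformly from a configured range, and the
  observed mutation count N_i ~ Poisson(lambda_i * B_i);
* trinucleotide contexts drawn i.i.d. from a group-specific mixture of
  catalogue signatures over the 96 channels.

A mouse mode emulates a cyclic-dosing design (arms for 0-3 treatment
cycles, a fixed number of animals per arm) with per-cycle burden levels.
Everything is deterministic given the config seed; each sample consumes an
independent substream keyed by (seed, sample index).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .contexts import CHANNELS_96, parse_context
from .signatures import SignatureCatalogue, synthetic_catalogue

RATE_FLOOR = 1e-12

#: Default mouse per-cycle sperm burden levels (cycles 0..3): the treated
#: effect appears only after the third cycle.
MOUSE_SPERM_RATES = (7.435e-9, 7.435e-9, 7.435e-9, 3.029e-8)
MOUSE_PROGENITOR_RATES = (6.201e-8, 6.201e-8, 6.201e-8, 2.714e-7)
MOUSE_LIVER_RATES = (3.49e-8, 3.49e-8, 3.49e-8, 3.905e-7)

_VIRTUAL_CONTIGS = tuple(f"chr{i}" for i in range(1, 23))
_VIRTUAL_CONTIG_LENGTH = 200_000_000


@dataclass
class CohortConfig:
    """Full generative description of a synthetic cohort.

    Human defaults are illustrative study conditions: cohort sizes echo a
    36-exposed / 32-control design, ages Uniform(20, 65), duplex bases
    Uniform(1e9, 3e9), an age slope of 5e-10 mutations/base/year (a
    paternal-germline-like accumulation of ~1.5 mutations per haploid
    genome per year) and a chemotherapy shift of 9.62e-9 mutations/base
    with a more variable exposed group.
    """

    n_control: int = 32
    n_exposed: int = 36
    age_range: tuple[float, float] = (20.0, 65.0)
    intercept_rate: float = 2.0e-9
    age_slope: float = 5.0e-10
    group_shift: float = 9.62e-9
    sigma_control: float = 1.5e-9
    sigma_exposed: float = 8.0e-9
    duplex_bases_range: tuple[float, float] = (1.0e9, 3.0e9)
    signature_mix_control: tuple[float, ...] | None = None
    signature_mix_exposed: tuple[float, ...] | None = None
    genome_equivalent: float = 6.0e9
    seed: int = 0
    design: str = "human_cross_sectional"
    tissue: str = "sperm"
    rate_floor: float = RATE_FLOOR
    # mouse_cycles design
    mouse_n_per_arm: int = 2
    mouse_cycles: tuple[int, ...] = (0, 1, 2, 3)
    mouse_rates: tuple[float, ...] = MOUSE_SPERM_RATES

    def validate(self, catalogue: SignatureCatalogue) -> None:
        if self.design == "human_cross_sectional":
            if self.n_control <= 0 or self.n_exposed <= 0:
                raise ValueError("n_control and n_exposed must be positive")
        elif self.design == "mouse_cycles":
            if self.mouse_n_per_arm <= 0:
                raise ValueError("mouse_n_per_arm must be positive")
            if any(c < 0 or c > 3 for c in self.mouse_cycles):
                raise ValueError("mouse cycles must lie in 0..3")
            if len(self.mouse_rates) != 4:
                raise ValueError("mouse_rates must give a level for cycles 0..3")
        else:
            raise ValueError(f"unknown design {self.design!r}")
        for name in (
            "intercept_rate",
            "age_slope",
            "group_shift",
            "sigma_control",
            "sigma_exposed",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.age_range[0] > self.age_range[1]:
            raise ValueError("age_range min must not exceed max")
        if self.duplex_bases_range[0] > self.duplex_bases_range[1]:
            raise ValueError("duplex_bases_range min must not exceed max")
        for mix in (self.signature_mix_control, self.signature_mix_exposed):
            if mix is not None:
                if len(mix) != len(catalogue):
                    raise ValueError(
                        "signature mixture length does not match catalogue"
                    )
                if abs(sum(mix) - 1.0) > 1e-9 or any(p < 0 for p in mix):
                    raise ValueError("signature mixture must be a probability vector")


def _default_mixes(catalogue: SignatureCatalogue) -> tuple[np.ndarray, np.ndarray]:
    """Clock-like control mixture; exposed adds therapy-like signatures."""
    K = len(catalogue)
    control = np.zeros(K)
    exposed = np.zeros(K)
    control[:2] = (0.3, 0.7)
    exposed[: min(5, K)] = (0.2, 0.45, 0.2, 0.05, 0.1)[: min(5, K)]
    control /= control.sum()
    exposed /= exposed.sum()
    return control, exposed


@dataclass
class TrueState:
    """Ground truth stored alongside emitted tables for recovery tests."""

    table: pd.DataFrame  # sample_id, group, age, true_rate, cycles
    config: CohortConfig


def _sample_stream(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, index)))


def _emit_sample(
    rng: np.random.Generator,
    sample_id: str,
    subject_id: str,
    tissue: str,
    group: str,
    age: float,
    lam: float,
    bases: float,
    channel_probs: np.ndarray,
) -> tuple[dict, pd.DataFrame]:
    n = int(rng.poisson(lam * bases))
    channels = rng.choice(96, size=n, p=channel_probs)
    chroms = rng.choice(len(_VIRTUAL_CONTIGS), size=n)
    positions = rng.integers(1, _VIRTUAL_CONTIG_LENGTH + 1, size=n)
    recs = []
    for k in range(n):
        ctx = CHANNELS_96[channels[k]]
        _, ref, alt, _ = parse_context(ctx)
        recs.append(
            {
                "sample_id": sample_id,
                "chrom": _VIRTUAL_CONTIGS[chroms[k]],
                "pos": int(positions[k]),
                "ref": ref,
                "alt": alt,
                "context": ctx,
            }
        )
    meta = {
        "sample_id": sample_id,
        "subject_id": subject_id,
        "tissue": tissue,
        "group": group,
        "age": age,
        "duplex_bases": bases,
        "germline_reference": "self_sperm" if tissue == "sperm" else "other",
    }
    cols = ["sample_id", "chrom", "pos", "ref", "alt", "context"]
    return meta, pd.DataFrame(recs, columns=cols)


def simulate_cohort(
    config: CohortConfig, catalogue: SignatureCatalogue | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, TrueState]:
    """Generate a human cross-sectional cohort.

    Returns (sample metadata, mutation records, ground truth); byte-identical
    for identical config.
    """
    catalogue = catalogue or synthetic_catalogue()
    config.validate(catalogue)
    if config.design != "human_cross_sectional":
        return simulate_mouse_experiment(config, catalogue)

    mix_c, mix_e = _default_mixes(catalogue)
    if config.signature_mix_control is not None:
        mix_c = np.asarray(config.signature_mix_control, dtype=float)
    if config.signature_mix_exposed is not None:
        mix_e = np.asarray(config.signature_mix_exposed, dtype=float)
    probs = {
        "control": catalogue.values @ mix_c,
        "exposed": catalogue.values @ mix_e,
    }

    metas, tables, truths = [], [], []
    labels = [("control", config.n_control), ("exposed", config.n_exposed)]
    index = 0
    for group, n in labels:
        sigma = config.sigma_control if group == "control" else config.sigma_exposed
        shift = 0.0 if group == "control" else config.group_shift
        for k in range(n):
            rng = _sample_stream(config.seed, index)
            lo, hi = config.age_range
            age = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
            eta = rng.normal(0.0, sigma) if sigma > 0 else 0.0
            lam = max(
                config.rate_floor,
                config.intercept_rate + config.age_slope * age + shift + eta,
            )
            blo, bhi = config.duplex_bases_range
            bases = float(rng.uniform(blo, bhi)) if bhi > blo else float(blo)
            sid = f"{'C' if group == 'control' else 'E'}{k + 1:03d}"
            meta, table = _emit_sample(
                rng, sid, f"subj_{sid}", config.tissue, group, age, lam, bases,
                probs[group] / probs[group].sum(),
            )
            metas.append(meta)
            tables.append(table)
            truths.append(
                {"sample_id": sid, "group": group, "age": age,
                 "true_rate": lam, "cycles": pd.NA}
            )
            index += 1

    meta_df = pd.DataFrame(metas)
    mut_df = pd.concat(tables, ignore_index=True)
    truth = TrueState(pd.DataFrame(truths), replace(config))
    return meta_df, mut_df, truth


def simulate_mouse_experiment(
    config: CohortConfig, catalogue: SignatureCatalogue | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, TrueState]:
    """Generate a cyclic-dosing mouse experiment for one tissue.

    Arms are emitted for each requested cycle count (0..3) with
    ``mouse_n_per_arm`` animals each; ``mouse_rates[c]`` is the mean burden
    after c cycles, with group "control" for 0 cycles and "exposed"
    otherwise. Between-animal noise uses sigma_control / sigma_exposed by
    that grouping.
    """
    catalogue = catalogue or synthetic_catalogue()
    cfg = config if config.design == "mouse_cycles" else replace(config, design="mouse_cycles")
    cfg.validate(catalogue)

    mix_c, mix_e = _default_mixes(catalogue)
    if cfg.signature_mix_control is not None:
        mix_c = np.asarray(cfg.signature_mix_control, dtype=float)
    if cfg.signature_mix_exposed is not None:
        mix_e = np.asarray(cfg.signature_mix_exposed, dtype=float)

    metas, tables, truths = [], [], []
    index = 0
    age_weeks = 8 + 3 * max(cfg.mouse_cycles, default=0)  # nominal, unused downstream
    for cycle in cfg.mouse_cycles:
        group = "control" if cycle == 0 else "exposed"
        sigma = cfg.sigma_control if group == "control" else cfg.sigma_exposed
        mix = mix_c if group == "control" else mix_e
        probs = catalogue.values @ mix
        probs = probs / probs.sum()
        for k in range(cfg.mouse_n_per_arm):
            rng = _sample_stream(cfg.seed, index)
            eta = rng.normal(0.0, sigma) if sigma > 0 else 0.0
            lam = max(cfg.rate_floor, cfg.mouse_rates[cycle] + eta)
            blo, bhi = cfg.duplex_bases_range
            bases = float(rng.uniform(blo, bhi)) if bhi > blo else float(blo)
            sid = f"M{cycle}{k + 1:02d}"
            meta, table = _emit_sample(
                rng, sid, f"mouse_{sid}", cfg.tissue, group,
                age_weeks / 52.0, lam, bases, probs,
            )
            meta["cycles"] = cycle
            metas.append(meta)
            tables.append(table)
            truths.append(
                {"sample_id": sid, "group": group, "age": age_weeks / 52.0,
                 "true_rate": lam, "cycles": cycle}
            )
            index += 1

    meta_df = pd.DataFrame(metas)
    mut_df = pd.concat(tables, ignore_index=True)
    truth = TrueState(pd.DataFrame(truths), replace(cfg))
    return meta_df, mut_df, truth
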