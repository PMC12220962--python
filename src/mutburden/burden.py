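"""Per-sample somatic mutation burden with exact Poisson uncertainty.

Duplex sequencing interrogates B duplex bases per sample and calls N
single-molecule mutations, so the burden (mutations per base) is N/B with
Poisson counting error. Because N is often tiny (single digits in sperm),
uncertainty uses the exact equal-tailed Garwood interval rather than a
normal approximation, and standard errors for downstream weighting are
derived from the interval width. Burden differences are converted to
"mutations per genome" through a genome-equivalent base count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .contexts import TRINUC_32, channel_of, trinucleotide_of_channel
from .signatures import Spectrum96

#: Genome-equivalent base counts. The diploid human factor reproduces the
#: published somatic-tissue conversions; the haploid sperm factor and the
#: mouse factor are reverse-derived from printed per-genome counts (see the
#: methods note) and are configuration, not assertions.
GENOME_HUMAN_DIPLOID = 6.0e9
GENOME_HUMAN_HAPLOID = 2.91e9
GENOME_MOUSE_FACTOR = 6.8e9

Z_95 = 1.959964


@dataclass
class BurdenEstimate:
    """Mutation count, per-base rate, exact Poisson CI and conversions."""

    sample_id: str
    count: int
    duplex_bases: float
    rate: float
    ci_low: float
    ci_high: float
    se: float
    genome_equivalent: float
    mutations_per_genome: int
    level: float = 0.95


def poisson_ci(count: int, level: float = 0.95) -> tuple[float, float]:
    """Exact (Garwood) equal-tailed confidence interval for a Poisson mean.

    ``low = chi2_{(1-level)/2}(2N)/2`` (0 when N = 0) and
    ``high = chi2_{1-(1-level)/2}(2N+2)/2`` — equivalently the means whose
    tail probabilities at the observed count equal (1-level)/2.
    """
    if isinstance(count, float) and not float(count).is_integer():
        raise ValueError(f"count must be an integer, got {count}")
    count = int(count)
    if count < 0:
        raise ValueError("count must be non-negative")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    tail = (1.0 - level) / 2.0
    low = 0.0 if count == 0 else float(stats.chi2.ppf(tail, 2 * count) / 2.0)
    high = float(stats.chi2.ppf(1.0 - tail, 2 * count + 2) / 2.0)
    return low, high


def se_from_ci(low: float, high: float, level: float = 0.95) -> float:
    """Standard error implied by a symmetric-width reading of a CI.

    ``se = (high - low) / (2 z)`` with z the standard-normal quantile for the
    interval level (1.959964 at 95%) — the meta-analysis convention for
    recovering a weighting SE from reported interval endpoints.
    """
    if low < 0 or high < low:
        raise ValueError("require 0 <= low <= high")
    z = float(stats.norm.ppf(1.0 - (1.0 - level) / 2.0))
    return (high - low) / (2.0 * z)


def additional_mutations(delta_rate: float, genome_equivalent: float) -> int:
    """Convert a burden difference (per base) to whole mutations per genome.

    Rounds half away from zero, matching how per-genome counts are
    conventionally printed.
    """
    if genome_equivalent <= 0:
        raise ValueError("genome_equivalent must be positive")
    x = delta_rate * genome_equivalent
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def estimate_burden(
    meta: pd.Series | dict,
    mutations: pd.DataFrame,
    level: float = 0.95,
    genome_equivalent: float = GENOME_HUMAN_DIPLOID,
) -> BurdenEstimate:
    """Burden estimate for one sample from its mutation-call table.

    ``meta`` needs ``sample_id`` and ``duplex_bases``; every row of
    ``mutations`` must carry that sample_id (an empty table is a valid
    zero-mutation sample).
    """
    meta = dict(meta)
    sample_id = meta["sample_id"]
    B = float(meta["duplex_bases"])
    if B <= 0:
        raise ValueError(f"sample {sample_id}: duplex_bases must be positive")
    if len(mutations) and (mutations["sample_id"] != sample_id).any():
        foreign = sorted(set(mutations["sample_id"]) - {sample_id})
        raise ValueError(f"mutation rows for foreign sample_ids: {foreign}")
    N = int(len(mutations))
    lo, hi = poisson_ci(N, level)
    rate = N / B
    ci_low, ci_high = lo / B, hi / B
    return BurdenEstimate(
        sample_id=sample_id,
        count=N,
        duplex_bases=B,
        rate=rate,
        ci_low=ci_low,
        ci_high=ci_high,
        se=se_from_ci(ci_low, ci_high, level),
        genome_equivalent=genome_equivalent,
        mutations_per_genome=additional_mutations(rate, genome_equivalent),
        level=level,
    )


def estimate_burden_table(
    meta: pd.DataFrame,
    mutations: pd.DataFrame,
    level: float = 0.95,
    genome_equivalent: float = GENOME_HUMAN_DIPLOID,
) -> pd.DataFrame:
    """Vectorized :func:`estimate_burden` over a cohort.

    Returns one row per metadata sample (samples without calls get N = 0)
    with columns sample_id, count, duplex_bases, rate, ci_low, ci_high, se,
    mutations_per_genome.
    """
    by_sample = dict(tuple(mutations.groupby("sample_id"))) if len(mutations) else {}
    known = set(meta["sample_id"])
    foreign = set(by_sample) - known
    if foreign:
        raise ValueError(f"mutation rows for unknown sample_ids: {sorted(foreign)}")
    rows = []
    for _, m in meta.iterrows():
        muts = by_sample.get(m["sample_id"], mutations.iloc[0:0])
        est = estimate_burden(m, muts, level=level, genome_equivalent=genome_equivalent)
        rows.append(
            {
                "sample_id": est.sample_id,
                "count": est.count,
                "duplex_bases": est.duplex_bases,
                "rate": est.rate,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "se": est.se,
                "mutations_per_genome": est.mutations_per_genome,
            }
        )
    return pd.DataFrame(rows)


def spectrum_from_mutations(
    mutations: pd.DataFrame,
    genome_context_weights: np.ndarray | None = None,
) -> Spectrum96:
    """Bin mutation calls into the 96 canonical channels.

    Contexts are collapsed to the pyrimidine strand (purine-centered records
    reverse-complemented). If ``genome_context_weights`` is given — a
    32-vector of genome/analyzed trinucleotide abundance ratios indexed as
    :data:`mutburden.contexts.TRINUC_32` — each channel is scaled by its
    trinucleotide's ratio and the spectrum renormalized to the original
    total, correcting for uneven context coverage of the interrogated bases.
    """
    counts = np.zeros(96)
    for i, ctx in enumerate(mutations["context"]):
        try:
            counts[channel_of(ctx)] += 1
        except (ValueError, KeyError) as exc:
            sid = mutations.iloc[i].get("sample_id", "?")
            raise ValueError(
                f"record {i} (sample {sid}): bad context {ctx!r}"
            ) from exc
    if genome_context_weights is not None:
        w = np.asarray(genome_context_weights, dtype=float)
        if w.shape != (32,):
            raise ValueError("genome_context_weights must have length 32")
        if (w <= 0).any():
            raise ValueError("genome_context_weights must be positive")
        per_channel = np.array(
            [w[TRINUC_32.index(trinucleotide_of_channel(i))] for i in range(96)]
        )
        total = counts.sum()
        scaled = counts * per_channel
        if total > 0 and scaled.sum() > 0:
            counts = scaled * (total / scaled.sum())
    return Spectrum96(counts)
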