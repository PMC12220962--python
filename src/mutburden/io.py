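"""Table schemas, VCF export, configuration and the end-to-end pipeline.

TSV is the native interchange format (the upstream sequencing data are
restricted, so no alignment formats are handled). A minimal VCF 4.2 export
is provided for interoperability: CHROM/POS/REF/ALT plus the collapsed
trinucleotide context as a ``TRINUC`` INFO tag.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
import yaml

from . import __version__
from .burden import (
    GENOME_HUMAN_DIPLOID,
    GENOME_HUMAN_HAPLOID,
    GENOME_MOUSE_FACTOR,
    estimate_burden_table,
    spectrum_from_mutations,
)
from .contexts import parse_context
from .regression import RegressionSpec, fit_group_effect
from .signatures import (
    SignatureCatalogue,
    fit_exposures_regression,
    synthetic_catalogue,
)
from .simulate import CohortConfig, simulate_cohort, simulate_mouse_experiment
from .stats import modified_z_scores, welch_t_test

TISSUES = {"sperm", "saliva", "pbmc", "granulocyte", "liver", "kidney", "progenitor"}
GROUPS = {"control", "exposed"}
GERMLINE_REFS = {"self_sperm", "combined", "granulocyte", "other"}

SAMPLE_COLUMNS = [
    "sample_id",
    "subject_id",
    "tissue",
    "group",
    "age",
    "duplex_bases",
    "germline_reference",
]
MUTATION_COLUMNS = ["sample_id", "chrom", "pos", "ref", "alt", "context"]


def _row_error(path, idx: int, msg: str) -> ValueError:
    # +2: header line plus 1-based numbering
    return ValueError(f"{path}:{idx + 2}: {msg}")


def read_samples(path) -> pd.DataFrame:
    """Read and validate a sample-metadata TSV."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for idx, row in df.iterrows():
        if row["tissue"] not in TISSUES:
            raise _row_error(path, idx, f"unknown tissue {row['tissue']!r}")
        if row["group"] not in GROUPS:
            raise _row_error(path, idx, f"unknown group {row['group']!r}")
        if row["germline_reference"] not in GERMLINE_REFS:
            raise _row_error(
                path, idx, f"unknown germline_reference {row['germline_reference']!r}"
            )
        if not row["duplex_bases"] > 0:
            raise _row_error(path, idx, "duplex_bases must be positive")
        if row["age"] < 0:
            raise _row_error(path, idx, "age must be non-negative")
    dup = df["sample_id"].duplicated()
    if dup.any():
        raise _row_error(path, int(dup.idxmax()), "duplicate sample_id")
    return df


def write_samples(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_mutations(path) -> pd.DataFrame:
    """Read and validate a mutation-call TSV."""
    df = pd.read_csv(path, sep="\t")
    if len(df) == 0:
        return pd.DataFrame(columns=MUTATION_COLUMNS)
    missing = [c for c in MUTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for idx, row in df.iterrows():
        try:
            five, ref, alt, three = parse_context(row["context"])
        except ValueError as exc:
            raise _row_error(path, idx, str(exc)) from exc
        if row["ref"] == row["alt"]:
            raise _row_error(path, idx, "ref == alt")
        if row["pos"] < 1:
            raise _row_error(path, idx, "pos must be 1-based positive")
    return df


def write_mutations(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_catalogue(path) -> SignatureCatalogue:
    """Read a COSMIC-layout signature TSV (first column 'Type')."""
    df = pd.read_csv(path, sep="\t")
    first = df.columns[0]
    df = df.set_index(first)
    return SignatureCatalogue(df)


def write_catalogue(catalogue: SignatureCatalogue, path) -> None:
    out = catalogue.matrix.copy()
    out.index.name = "Type"
    out.to_csv(path, sep="\t")


def read_burdens(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_burdens(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def export_vcf(mutations: pd.DataFrame, path, sample_id: str | None = None) -> None:
    """Write one sample's calls as a minimal VCF 4.2 (uncompressed text)."""
    if sample_id is not None:
        mutations = mutations[mutations["sample_id"] == sample_id]
    header = pysam.VariantHeader()
    header.add_meta("source", f"mutburden {__version__}")
    header.info.add("TRINUC", 1, "String", "Pyrimidine-collapsed trinucleotide context")
    for contig in pd.unique(mutations["chrom"]):
        header.contigs.add(str(contig))
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        ordered = mutations.sort_values(["chrom", "pos"])
        for _, row in ordered.iterrows():
            rec = vcf.new_record(
                contig=str(row["chrom"]),
                start=int(row["pos"]) - 1,
                stop=int(row["pos"]),
                alleles=(row["ref"], row["alt"]),
            )
            rec.info["TRINUC"] = row["context"].replace(">", "-")
            vcf.write(rec)


def read_vcf(path, sample_id: str) -> pd.DataFrame:
    """Read a minimal VCF back into the mutation-record table shape."""
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            ctx = rec.info.get("TRINUC")
            rows.append(
                {
                    "sample_id": sample_id,
                    "chrom": rec.contig,
                    "pos": rec.pos,
                    "ref": rec.ref,
                    "alt": rec.alts[0],
                    "context": ctx.replace("-", ">") if ctx else "",
                }
            )
    return pd.DataFrame(rows, columns=MUTATION_COLUMNS)


@dataclass
class PipelineConfig:
    """Structured configuration for :func:`run_pipeline`."""

    outdir: str = "mutburden_out"
    seed: int = 0
    ci_level: float = 0.95
    genome_equivalents: dict = field(
        default_factory=lambda: {
            "human_diploid": GENOME_HUMAN_DIPLOID,
            "human_haploid": GENOME_HUMAN_HAPLOID,
            "mouse_factor": GENOME_MOUSE_FACTOR,
        }
    )
    simulate: bool = True
    cohort: dict = field(default_factory=dict)
    samples_path: str | None = None
    mutations_path: str | None = None
    catalogue_path: str | None = None
    regression: dict = field(default_factory=dict)
    signatures: dict = field(default_factory=lambda: {"enabled": True, "threshold": 0.05})
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Simulate (optionally) -> burden -> regression -> signatures -> stats.

    Writes all output tables plus a run manifest to ``config.outdir`` and
    returns the manifest. Validation failures raise with the stage name;
    MCMC non-convergence only sets a warning flag in the manifest.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "warnings": [],
    }

    catalogue = (
        read_catalogue(config.catalogue_path)
        if config.catalogue_path
        else synthetic_catalogue()
    )

    try:
        if config.simulate:
            cc = CohortConfig(**{**config.cohort, "seed": config.seed})
            if cc.design == "mouse_cycles":
                meta, muts, truth = simulate_mouse_experiment(cc, catalogue)
            else:
                meta, muts, truth = simulate_cohort(cc, catalogue)
            write_samples(meta, outdir / "samples.tsv")
            write_mutations(muts, outdir / "mutations.tsv")
            truth.table.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        else:
            if not (config.samples_path and config.mutations_path):
                raise ValueError("samples_path and mutations_path required")
            meta = read_samples(config.samples_path)
            muts = read_mutations(config.mutations_path)
    except Exception as exc:
        raise RuntimeError(f"stage 'input': {exc}") from exc

    try:
        G = config.genome_equivalents.get("human_diploid", GENOME_HUMAN_DIPLOID)
        burdens = estimate_burden_table(
            meta, muts, level=config.ci_level, genome_equivalent=G
        )
        write_burdens(burdens, outdir / "burdens.tsv")
        manifest["n_samples"] = int(len(burdens))
        manifest["total_mutations"] = int(burdens["count"].sum())
    except Exception as exc:
        raise RuntimeError(f"stage 'burden': {exc}") from exc

    try:
        spec = RegressionSpec(**{**config.regression, "seed": config.seed})
        summary, _ = fit_group_effect(burdens, meta, spec)
        report = {
            "parameters": {
                k: dataclasses.asdict(v) for k, v in summary.parameters.items()
            },
            "n_posterior_draws": summary.n_posterior_draws,
            "converged": summary.converged,
            "rhat_threshold": summary.rhat_threshold,
            "seed": summary.seed,
        }
        with open(outdir / "regression.json", "w") as fh:
            json.dump(report, fh, indent=2)
        manifest["regression_converged"] = summary.converged
        if not summary.converged:
            manifest["warnings"].append("regression MCMC did not converge")
    except Exception as exc:
        raise RuntimeError(f"stage 'regression': {exc}") from exc

    if config.signatures.get("enabled", True):
        try:
            threshold = float(config.signatures.get("threshold", 0.05))
            rows = []
            for sid, sub in muts.groupby("sample_id"):
                spectrum = spectrum_from_mutations(sub)
                if spectrum.total == 0:
                    continue
                fit = fit_exposures_regression(spectrum, catalogue, threshold)
                for name, prop in fit.exposures.items():
                    if prop > 0:
                        rows.append(
                            {
                                "sample_id": sid,
                                "signature": name,
                                "proportion": prop,
                                "method": fit.method,
                            }
                        )
            pd.DataFrame(
                rows, columns=["sample_id", "signature", "proportion", "method"]
            ).to_csv(outdir / "exposures.tsv", sep="\t", index=False)
        except Exception as exc:
            raise RuntimeError(f"stage 'signatures': {exc}") from exc

    try:
        joined = burdens.merge(meta[["sample_id", "group"]], on="sample_id")
        x = joined.loc[joined["group"] == "exposed", "rate"]
        y = joined.loc[joined["group"] == "control", "rate"]
        stats_report: dict = {}
        if len(x) >= 2 and len(y) >= 2:
            t = welch_t_test(x, y)
            stats_report["welch_exposed_vs_control"] = {
                "t": t.statistic, "df": t.df, "p": t.p_value,
            }
        if len(joined) >= 3:
            scores, flags = modified_z_scores(joined["rate"].to_numpy())
            stats_report["modified_z_outliers"] = [
                {"sample_id": sid, "z": float(z)}
                for sid, z, f in zip(joined["sample_id"], scores, flags)
                if f
            ]
        with open(outdir / "stats.json", "w") as fh:
            json.dump(stats_report, fh, indent=2)
    except Exception as exc:
        raise RuntimeError(f"stage 'stats': {exc}") from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
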