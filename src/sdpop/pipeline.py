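"""End-to-end pipeline: ingest → filters → windowed stats → null inference,
with optional clustering, driven by a YAML config.

Every stochastic stage takes its seed from the config; re-running with
the same config and inputs reproduces all result files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import (
    filter_samples,
    filter_variants,
    parse_region,
    read_outgroup_tsv,
    read_vcf,
    records_to_haplotypes,
    window_records_to_frame,
)
from .nulls import NullDistribution, empirical_p_windowset, simulate_null_distribution
from .popgen import maf_filter, window_partition, windowed_stats
from .simulate import DemographicModel

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    vcf: str
    regions: list  # region strings, 1-based inclusive
    outgroup_tsv: str | None = None
    window_size: int = 2000
    min_qual: float = 20.0
    indel_radius: int = 10
    max_missing: float = 0.10
    maf_threshold: float | None = None
    null_background_tsv: str | None = None
    null_model: str | None = None  # YAML demographic model config
    null_replicates: int = 1000
    tail: str = "negative"
    n_resample: int = 9999
    seed: int = 0
    cluster: bool = False
    out_dir: str = "sdpop_out"

    def __post_init__(self):
        if not self.regions:
            raise ValueError("at least one region required")
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")
        if not 0 <= self.max_missing < 1:
            raise ValueError("max_missing must be in [0, 1)")
        if self.seed is None:
            raise ValueError("seed is mandatory for stochastic stages")

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        return cls(**cfg)


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.__dict__, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig):
    """Run the full analysis; writes TSV/JSON results and a manifest.

    Returns a dict bundle with the window-stat DataFrame, the selection
    test results and output paths. Any stage failure aborts with the
    stage name in the exception message.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = {"outputs": []}

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

    for path in [config.vcf, config.outgroup_tsv, config.null_background_tsv,
                 config.null_model]:
        if path is not None and not Path(path).exists():
            raise FileNotFoundError(f"missing input file: {path}")

    records, samples = stage("ingest", read_vcf, config.vcf)
    records = stage("variant_filter", filter_variants, records,
                    config.min_qual, config.indel_radius)
    records, samples, dropped = stage("sample_filter", filter_samples,
                                      records, samples, config.max_missing)
    outgroup = read_outgroup_tsv(config.outgroup_tsv) if config.outgroup_tsv else None
    matrix = stage("haplotypes", records_to_haplotypes, records, samples, outgroup)
    if config.maf_threshold is not None:
        matrix = stage("maf_filter", maf_filter, matrix, config.maf_threshold)

    regions = [parse_region(r) for r in config.regions]
    windows = stage("windows", window_partition, regions, config.window_size)
    recs = stage("stats", windowed_stats, matrix, windows)
    stats_df = window_records_to_frame(recs)
    stats_path = out / "window_stats.tsv"
    stats_df.to_csv(stats_path, sep="\t", index=False)
    bundle["outputs"].append(str(stats_path))
    bundle["window_stats"] = stats_df

    results = {}
    null = None
    if config.null_background_tsv:
        bg = pd.read_csv(config.null_background_tsv, sep="\t", comment="#")
        null = NullDistribution("tajima_d", bg["tajima_d"].to_numpy(float),
                                "genome_background",
                                provenance=config.null_background_tsv)
    elif config.null_model:
        model = DemographicModel.from_config(config.null_model)
        nulls = stage("null_simulation", simulate_null_distribution, model,
                      config.null_replicates, 1, config.seed,
                      window_size=config.window_size)
        null = nulls["tajima_d"]
        np.savetxt(out / "null_tajima_d.tsv", null.values, header=null.provenance)
        bundle["outputs"].append(str(out / "null_tajima_d.tsv"))
    if null is not None:
        res = stage("selection_test", empirical_p_windowset,
                    stats_df["tajima_d"].to_numpy(float), null,
                    tail=config.tail, n_resample=config.n_resample,
                    seed=config.seed)
        results["tajima_d"] = res.__dict__
        bundle["selection_test"] = res

    if config.cluster:
        from .clustering import choose_k, haplotype_heterozygosity, haplotype_pca

        pca = stage("pca", haplotype_pca, matrix)
        cm = stage("choose_k", choose_k, pca.scores[:, : pca.n_informative],
                   seed=config.seed)
        assign = pd.DataFrame({
            "haplotype": [f"hap{i}" for i in range(matrix.n_haplotypes)],
            "population": matrix.populations,
            "cluster": cm.assignments,
        })
        assign.to_csv(out / "cluster_assignments.tsv", sep="\t", index=False)
        bundle["outputs"].append(str(out / "cluster_assignments.tsv"))
        results["clustering"] = {
            "k": int(cm.k),
            "heterozygosity": haplotype_heterozygosity(cm.assignments),
        }
        bundle["clusters"] = cm

    summary_path = out / "summary.json"
    with open(summary_path, "w") as fh:
        json.dump(results, fh, indent=2, default=float)
    bundle["outputs"].append(str(summary_path))

    manifest = {
        "sdpop_version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "n_samples": len(samples),
        "n_samples_dropped": len(dropped),
        "n_sites": int(matrix.n_sites),
        "n_windows": len(windows),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    bundle["outputs"].append(str(out / "manifest.json"))
    bundle["manifest"] = manifest
    bundle["results"] = results
    return bundle
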