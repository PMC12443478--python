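"""Figure-level orchestration: assemble the stage outputs into report tables.

Two panels mirror how burden experiments are reported: the NI panel turns
growth curves and lane tables into a per-construct neutrality-index table
with Welch/Bonferroni statistics against the vector control, and the omics
panel turns fold-change tables, category maps, partitions, and proteome
matrices into enrichment, classification, and composition report tables.
Every run writes a manifest (seed, thresholds, versions, output hashes) so
identical configs reproduce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .densitometry import percent_of_total, read_lanes_tsv
from .enrichment import (
    FoldChangeTable,
    between_condition_test,
    category_shift_test,
    classify_response,
    condition_correlation,
    partitioned_test,
    read_gmt,
    results_to_frame,
)
from .errors import ConfigError, ValidationError
from .growth import estimate_mgr, read_curves_csv
from .neutrality import neutrality_index, welch_test
from .proteome import (
    ProteomeMatrix,
    overexpression_fraction,
    per_protein_fc,
    total_correction,
    zero_filter,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_ni_panel", "run_omics_panel"]


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of a pipeline run."""

    out_dir: Path
    control: str = "Vector"
    fdr_threshold: float = 0.05
    min_size: int = 11
    od_floor: float = 0.05
    window_min: float = 120.0
    normalization: str = "raw"  # "raw" or "total-corrected" or "both"
    seed: int = 0
    curves_path: Path | None = None
    lanes_path: Path | None = None
    fc_path: Path | None = None
    gmt_path: Path | None = None
    partition_path: Path | None = None
    matrix_path: Path | None = None
    samples_path: Path | None = None
    target_protein: str | None = None
    conditions: tuple[str, ...] = ()
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.fdr_threshold <= 1:
            raise ConfigError(f"fdr_threshold {self.fdr_threshold} outside (0, 1]")
        if self.min_size < 1:
            raise ConfigError("min_size must be >= 1")
        if self.od_floor <= 0:
            raise ConfigError("od_floor must be > 0")
        if self.window_min <= 0:
            raise ConfigError("window_min must be > 0")
        if self.normalization not in ("raw", "total-corrected", "both"):
            raise ConfigError(f"unknown normalization {self.normalization!r}")
        object.__setattr__(self, "out_dir", Path(self.out_dir))
        for name in (
            "curves_path",
            "lanes_path",
            "fc_path",
            "gmt_path",
            "partition_path",
            "matrix_path",
            "samples_path",
        ):
            value = getattr(self, name)
            if value is not None:
                value = Path(value)
                object.__setattr__(self, name, value)
                if not value.exists():
                    raise ConfigError(f"{name} does not exist: {value}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        kwargs = {k: v for k, v in raw.items() if k in known}
        kwargs["extra"] = {k: v for k, v in raw.items() if k not in known}
        if "conditions" in kwargs and kwargs["conditions"] is not None:
            kwargs["conditions"] = tuple(kwargs["conditions"])
        return cls(**kwargs)


def _write_manifest(config: RunConfig, outputs: dict[str, Path]) -> Path:
    hashes = {}
    for name, path in outputs.items():
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        hashes[name] = digest
    manifest = {
        "burdenkit_version": __version__,
        "python": sys.version.split()[0],
        "seed": config.seed,
        "thresholds": {
            "fdr": config.fdr_threshold,
            "min_size": config.min_size,
            "od_floor": config.od_floor,
            "window_min": config.window_min,
        },
        "normalization": config.normalization,
        "outputs": hashes,
    }
    path = config.out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def run_ni_panel(config: RunConfig) -> pd.DataFrame:
    """Per-construct neutrality-index report from growth curves and lanes.

    MGR is estimated per replicate curve; %MGR pairs sample replicate i
    with control replicate i; %protein comes from percent-of-total per
    lane.  NI is the mean of per-replicate products.  Welch's t-test
    (Bonferroni m = number of non-control constructs) compares each
    construct's raw MGR replicates against the control's.
    """
    if config.curves_path is None or config.lanes_path is None:
        raise ConfigError("NI panel requires curves_path and lanes_path")
    config.out_dir.mkdir(parents=True, exist_ok=True)

    curves = read_curves_csv(config.curves_path)
    lanes = read_lanes_tsv(config.lanes_path)

    mgr_by_strain: dict[str, list[float]] = {}
    for curve in curves:
        res = estimate_mgr(
            curve, window_min=config.window_min, od_floor=config.od_floor
        )
        mgr_by_strain.setdefault(curve.strain, []).append(res.mgr)
    if config.control not in mgr_by_strain:
        raise ConfigError(
            f"control construct {config.control!r} absent from growth curves; "
            f"found {sorted(mgr_by_strain)}"
        )
    pct_by_strain: dict[str, list[float]] = {}
    for lane in sorted(lanes, key=lambda ln: (ln.strain, ln.replicate)):
        pct_by_strain.setdefault(lane.strain, []).append(percent_of_total(lane))

    control_mgr = mgr_by_strain[config.control]
    non_control = [s for s in mgr_by_strain if s != config.control]
    m = max(len(non_control), 1)

    rows = []
    for strain in sorted(mgr_by_strain):
        mgrs = mgr_by_strain[strain]
        n_pair = min(len(mgrs), len(control_mgr))
        pct_mgr = [100.0 * mgrs[i] / control_mgr[i] for i in range(n_pair)]
        pct_prot = pct_by_strain.get(strain)
        if pct_prot is None:
            raise ConfigError(f"construct {strain!r} has curves but no lanes")
        n = min(len(pct_mgr), len(pct_prot))
        record = neutrality_index(pct_mgr[:n], pct_prot[:n], construct=strain)
        if strain == config.control or len(mgrs) < 2 or len(control_mgr) < 2:
            p_adj = float("nan")
        else:
            _, p = welch_test(mgrs, control_mgr)
            p_adj = min(1.0, m * p)
        rows.append(
            {
                "construct": strain,
                "pct_mgr_mean": float(np.mean(record.pct_mgr)),
                "pct_mgr_sd": float(np.std(record.pct_mgr, ddof=1))
                if len(record.pct_mgr) > 1
                else 0.0,
                "pct_protein_mean": float(np.mean(record.pct_protein)),
                "pct_protein_sd": float(np.std(record.pct_protein, ddof=1))
                if len(record.pct_protein) > 1
                else 0.0,
                "ni_mean": record.ni_mean,
                "ni_sd": record.ni_sd,
                "n": record.n_replicates,
                "p_adj_vs_reference": p_adj,
            }
        )
    table = pd.DataFrame(rows)
    out = config.out_dir / "ni.tsv"
    table.to_csv(out, sep="\t", index=False, float_format="%.6g")
    _write_manifest(config, {"ni.tsv": out})
    logger.info("NI panel written: %s (%d constructs)", out, len(table))
    return table


def run_omics_panel(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Enrichment, classification, and proteome report tables.

    Produces, depending on the configured inputs: per-condition category
    enrichment (full + significant-only), per-gene response classification
    and between-condition tests for condition pairs, partition-stratified
    enrichment, and per-protein fold changes plus overexpression fractions
    under the configured normalization mode(s).
    """
    if config.fc_path is None and config.matrix_path is None:
        raise ConfigError("omics panel requires fc_path and/or matrix_path")
    if config.fc_path is not None and config.gmt_path is None:
        raise ConfigError("enrichment requires gmt_path alongside fc_path")
    config.out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    frames: dict[str, pd.DataFrame] = {}

    def emit(name: str, frame: pd.DataFrame) -> None:
        path = config.out_dir / name
        frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
        outputs[name] = path
        frames[name.removesuffix(".tsv")] = frame

    if config.fc_path is not None:
        table = FoldChangeTable.from_tsv(config.fc_path)
        cats = read_gmt(config.gmt_path)
        conditions = config.conditions or table.conditions
        for cond in conditions:
            if cond not in table.conditions:
                raise ValidationError(
                    f"condition {cond!r} not in table; available: {table.conditions}"
                )
            results = category_shift_test(table, cats, cond, min_size=config.min_size)
            frame = results_to_frame(results)
            emit(f"enrichment_{cond}.tsv", frame)
            sig = frame[frame["fdr"] < config.fdr_threshold] if len(frame) else frame
            emit(f"enrichment_{cond}_significant.tsv", sig)

        if len(conditions) >= 2:
            a, b = conditions[0], conditions[1]
            between = results_to_frame(
                between_condition_test(table, cats, a, b, min_size=config.min_size)
            )
            emit(f"between_{a}_vs_{b}.tsv", between)
            labels = classify_response(table, a, b, fdr_threshold=config.fdr_threshold)
            cls_frame = labels.reset_index()
            cls_frame.columns = ["gene_id", "response_class"]
            r = condition_correlation(table, a, b)
            cls_frame["pearson_r"] = r
            emit(f"classification_{a}_vs_{b}.tsv", cls_frame)

        if config.partition_path is not None:
            partition = {
                line.strip()
                for line in Path(config.partition_path).read_text().splitlines()
                if line.strip()
            }
            for cond in conditions:
                strat = partitioned_test(
                    table, cats, partition, cond, min_size=config.min_size
                )
                for label, results in strat.items():
                    emit(
                        f"enrichment_{cond}_{label}.tsv", results_to_frame(results)
                    )

    if config.matrix_path is not None:
        if config.samples_path is None:
            raise ConfigError("matrix_path requires samples_path")
        matrix = ProteomeMatrix.from_tsv(
            config.matrix_path, config.samples_path, config.target_protein
        )
        conds = matrix.conditions
        if len(conds) < 2:
            raise ValidationError("proteome analysis needs >= 2 conditions")
        ref, alt = conds[0], conds[1]
        modes = (
            ("raw", "total-corrected")
            if config.normalization == "both"
            else (config.normalization,)
        )
        for mode in modes:
            mat = matrix if mode == "raw" else total_correction(matrix, ref)
            filtered = zero_filter(mat)
            results = per_protein_fc(filtered, ref, alt)
            frame = pd.DataFrame(
                {
                    "protein_id": [x.protein_id for x in results],
                    "mean_log2fc": [x.mean_log2fc for x in results],
                    "p_value": [x.p_value for x in results],
                    "fdr": [x.fdr for x in results],
                }
            )
            emit(f"proteome_fc_{mode}.tsv", frame)
            if config.target_protein:
                frac = overexpression_fraction(mat, config.target_protein, alt)
                emit(
                    f"proteome_summary_{mode}.tsv",
                    pd.DataFrame(
                        {
                            "metric": ["overexpression_fraction_pct", "n_proteins_before", "n_proteins_after"],
                            "value": [frac, len(mat.intensities), len(filtered.intensities)],
                        }
                    ),
                )

    _write_manifest(config, outputs)
    logger.info("omics panel: %d tables written to %s", len(outputs), config.out_dir)
    return frames
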