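"""Pipeline configuration, orchestration, fixtures and report generation.

A run reads the annotation, expression tables and (optionally) a qPCR
plate, fits the dosage-expression and breakpoint models and writes every
stage output plus a machine-readable JSON report and a plain-text
summary under one output directory. Reports carry no timestamps, so a
re-run with identical inputs is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import (
    GeneCatalog,
    GeneModel,
    Region,
    RegionPartition,
    write_expression_tsv,
)
from .model import (
    DosageExpressionModel,
    DosageExpressionResults,
    QpcrBreakpointModel,
    QpcrBreakpointResults,
)
from .simulate import (
    _DEFAULT_REGION_SPANS,
    ExpressionSimConfig,
    QpcrSimConfig,
    DEFAULT_REGION_ORDER,
    simulate_expression_pair,
    simulate_qpcr_plate,
)

logger = logging.getLogger(__name__)

__all__ = [
    "REFERENCE_COUNTS",
    "PipelineConfig",
    "PipelineError",
    "RunReport",
    "run_pipeline",
    "make_fixtures",
    "build_reference_count_fixture",
    "default_chr11_partition",
]

# Per-region (expressed, up-regulated, down-regulated) gene counts of the
# reference differential-expression design; chromosome 11 split into long
# arm (11L), non-repeat short arm (11S-1) and repeat short arm (11S-2).
REFERENCE_COUNTS: dict[str, tuple[int, int, int]] = {
    "Chr1": (3386, 179, 145),
    "Chr2": (2763, 118, 103),
    "Chr3": (3016, 141, 95),
    "Chr4": (2047, 121, 78),
    "Chr5": (1952, 91, 70),
    "Chr6": (1927, 99, 76),
    "Chr7": (1789, 98, 94),
    "Chr8": (1557, 80, 84),
    "Chr9": (1332, 73, 48),
    "Chr10": (1223, 77, 62),
    "11L": (646, 60, 39),
    "11S-1": (448, 37, 23),
    "11S-2": (211, 73, 8),
    "Chr12": (1307, 64, 61),
}


def default_chr11_partition() -> RegionPartition:
    """The chromosome-11 region partition: 11S-1 / 11S-2 (5.4-12.1 Mb) / 11L."""
    return RegionPartition(
        [
            Region(rid, *_DEFAULT_REGION_SPANS[rid])
            for rid in ("11S-1", "11S-2", "11L")
        ]
    )


# up/down/neutral ratio multipliers for count-matched fixtures; all are
# dyadic rationals so variant = control * m round-trips exactly through
# text files and classification margins are unambiguous.
_UP_MULTIPLIERS = (2.0, 2.25, 2.5, 3.0, 4.0)
_DOWN_MULTIPLIERS = (0.5, 0.375, 0.25)
_NEUTRAL_MULTIPLIERS = (1.0, 0.75, 1.25, 1.5, 0.625, 1.75)


def build_reference_count_fixture(
    seed: int = 0,
    counts: dict[str, tuple[int, int, int]] | None = None,
) -> tuple[GeneCatalog, "pd.DataFrame", RegionPartition]:
    """Expression pair constructed to hit exact per-region up/down counts.

    For each region with (n_expressed, n_up, n_down), the first n_up genes
    get ratio multipliers >= 2, the next n_down get multipliers <= 0.5 and
    the rest fall strictly between; control values are random dyadic
    rationals (k/64) so every ratio is exact in floating point and across
    a TSV round-trip. Returns (catalog, expression frame, partition).
    """
    from .annotation import ExpressionPair

    counts = counts or REFERENCE_COUNTS
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    genes: list[GeneModel] = []
    records: dict[str, tuple[float, float]] = {}
    for region_id, (n, n_up, n_down) in counts.items():
        chrom, span_start, span_end = _DEFAULT_REGION_SPANS[region_id]
        starts = np.linspace(span_start, span_end - 200, n).astype(int)
        control_vals = rng.integers(1, 4096, size=n) / 64.0
        for i in range(n):
            gid = f"{region_id}_{i:05d}"
            genes.append(GeneModel(gid, chrom, int(starts[i]), int(starts[i]) + 150, "+"))
            if i < n_up:
                m = _UP_MULTIPLIERS[i % len(_UP_MULTIPLIERS)]
            elif i < n_up + n_down:
                m = _DOWN_MULTIPLIERS[i % len(_DOWN_MULTIPLIERS)]
            else:
                m = _NEUTRAL_MULTIPLIERS[i % len(_NEUTRAL_MULTIPLIERS)]
            c = float(control_vals[i])
            records[gid] = (c, c * m)

    catalog = GeneCatalog(genes)
    df = pd.DataFrame.from_dict(
        dict(records), orient="index", columns=["control", "variant"]
    )
    return catalog, df, default_chr11_partition()


# ---------------------------------------------------------------------------
# pipeline


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and input context."""


@dataclass
class PipelineConfig:
    """All inputs and parameters of one pipeline run."""

    annotation: str
    control: str
    variant: str
    out_dir: str
    partition: str | None = None
    qpcr_plate: str | None = None
    marker_order: str | None = None
    feature_filter: str = "gene"
    id_attribute: str = "ID"
    window: int = 100
    step: int = 1
    bin_width: float = 0.05
    cap: float = 5.0
    theta_up: float = 2.0
    theta_down: float = 0.5
    peak_tolerance: float = 0.10
    ks_mode: str = "expression"
    fisher_pairs: list[list[str]] | None = None
    region_order: list[str] | None = None
    candidate_levels: list[float] = field(default_factory=lambda: [1.0, 2.0])

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class RunReport:
    """Machine-readable record of a pipeline run (no timestamps)."""

    versions: dict
    config: dict
    record_counts: dict
    expression: dict
    breakpoint: dict | str
    outputs: dict

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _versions() -> dict:
    import scipy

    return {
        "dosagescan": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
    }


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute annotation -> ratio analysis -> region stats (-> qPCR).

    Writes all stage outputs, ``report.json`` and ``report.txt`` under
    ``config.out_dir``. Stage failures raise :class:`PipelineError`
    naming the stage.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    try:
        model = DosageExpressionModel.from_files(
            config.annotation,
            config.control,
            config.variant,
            partition_path=config.partition,
            feature_filter=config.feature_filter,
            id_attribute=config.id_attribute,
            window=config.window,
            step=config.step,
            bin_width=config.bin_width,
            cap=config.cap,
            theta_up=config.theta_up,
            theta_down=config.theta_down,
            peak_tolerance=config.peak_tolerance,
            ks_mode=config.ks_mode,
            fisher_pairs=(
                [tuple(p) for p in config.fisher_pairs]
                if config.fisher_pairs
                else None
            ),
            region_order=config.region_order,
        )
    except Exception as exc:
        raise PipelineError(f"stage annotation_io: {exc}") from exc
    logger.info(
        "annotation_io: %d genes, %d joined expression records",
        len(model.catalog), len(model.pair),
    )

    try:
        results = model.fit()
    except Exception as exc:
        raise PipelineError(f"stage dosage_analysis: {exc}") from exc
    outputs = results.save(out_dir)
    model.catalog.to_tsv(out_dir / "gene_catalog.tsv")
    outputs["gene_catalog"] = "gene_catalog.tsv"
    logger.info(
        "dosage_analysis: %d windows, %d regions",
        len(results.window_profile), len(results.histograms),
    )

    qpcr_section: dict | str = "not run"
    if config.qpcr_plate:
        marker_order = None
        if config.marker_order:
            marker_order = [
                line.strip()
                for line in open(config.marker_order)
                if line.strip()
            ]
        try:
            qmodel = QpcrBreakpointModel.from_csv(
                config.qpcr_plate,
                marker_order=marker_order,
                candidate_levels=tuple(config.candidate_levels),
            )
            qresults = qmodel.fit()
        except Exception as exc:
            raise PipelineError(f"stage qpcr: {exc}") from exc
        outputs.update(qresults.save(out_dir))
        qpcr_section = qresults.to_json_dict()
        logger.info("qpcr: %d markers", len(qresults.copy_profile.data))

    report = RunReport(
        versions=_versions(),
        config=asdict(config),
        record_counts={
            "genes_in_catalog": len(model.catalog),
            "expression_joined": len(model.pair),
            "excluded_control_only": model.pair.n_control_only,
            "excluded_variant_only": model.pair.n_variant_only,
            "defined_ratios": int(len(results.ratio_table.defined)),
            "windows": len(results.window_profile),
        },
        expression=results.to_json_dict(),
        breakpoint=qpcr_section,
        outputs=outputs,
    )
    (out_dir / "report.json").write_text(report.to_json() + "\n")
    text = results.summary()
    if config.qpcr_plate:
        text += "\n\n" + qresults.summary()
    (out_dir / "report.txt").write_text(text + "\n")
    return report


# ---------------------------------------------------------------------------
# canonical fixtures


def make_fixtures(out_dir, seed: int = 0) -> dict[str, dict]:
    """Write the canonical test fixtures and return their manifest.

    ``reference_counts/``    count-matched expression pair reproducing the reference
                   per-region up/down summary exactly;
    ``noiseless/`` full-dosage, zero-noise duplication simulation
                   (ratio exactly 2.0 throughout the repeat region);
    ``qpcr/``      21-marker plate with a 1x->2x step after marker 10.
    """
    out = Path(out_dir)
    manifest: dict[str, dict] = {}

    # --- count-matched fixture
    t1 = out / "reference_counts"
    t1.mkdir(parents=True, exist_ok=True)
    catalog, expr, partition = build_reference_count_fixture(seed)
    catalog.to_bed(t1 / "annotation.bed")
    write_expression_tsv(expr["control"], t1 / "control.tsv")
    write_expression_tsv(expr["variant"], t1 / "variant.tsv")
    partition.to_tsv(t1 / "regions.tsv")
    manifest["reference_counts"] = {
        "n_genes": len(catalog),
        "region_counts": {
            r: {"expressed": n, "up": u, "down": d}
            for r, (n, u, d) in REFERENCE_COUNTS.items()
        },
    }

    # --- noiseless duplication simulation
    nl = out / "noiseless"
    nl.mkdir(parents=True, exist_ok=True)
    sim_config = ExpressionSimConfig(
        pi_dosage=1.0,
        pi_compensated=0.0,
        background_up_fraction=0.0,
        background_down_fraction=0.0,
        noise_log_sd=0.0,
        seed=seed,
    )
    cat2, pair2, truth2 = simulate_expression_pair(sim_config)
    cat2.to_bed(nl / "annotation.bed")
    write_expression_tsv(pair2.data["control"], nl / "control.tsv")
    write_expression_tsv(pair2.data["variant"], nl / "variant.tsv")
    truth2.partition.to_tsv(nl / "regions.tsv")
    with open(nl / "truth.json", "w") as fh:
        json.dump(
            {
                "duplicated_regions": sorted(truth2.duplicated_regions),
                "multiplier_counts": {
                    str(k): int(v)
                    for k, v in truth2.multipliers.value_counts().items()
                },
            },
            fh,
            indent=2,
        )
    manifest["noiseless"] = {
        "n_genes": len(cat2),
        "duplicated_regions": sorted(truth2.duplicated_regions),
    }

    # --- qPCR plate
    qp = out / "qpcr"
    qp.mkdir(parents=True, exist_ok=True)
    qconfig = QpcrSimConfig(seed=seed)
    plate, qtruth = simulate_qpcr_plate(qconfig)
    plate.to_csv(qp / "plate.csv")
    (qp / "marker_order.txt").write_text("\n".join(plate.marker_order) + "\n")
    with open(qp / "truth.json", "w") as fh:
        json.dump(
            {
                "breakpoint_after_index": qtruth.breakpoint_after_index,
                "copy_levels": list(qtruth.copy_levels),
            },
            fh,
            indent=2,
        )
    manifest["qpcr"] = {
        "n_markers": qconfig.n_markers,
        "breakpoint_after_index": qconfig.breakpoint_after_index,
    }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
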