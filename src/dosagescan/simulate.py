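"""Synthetic expression pairs and qPCR plates with known ground truth.

The experimental design being emulated: one control and one variant RNA-seq
library (no replicates), ~23,604 expressed genes across 12 rice
chromosomes, a duplicated segment on the short arm of chromosome 11
(5.4-12.1 Mb, region "11S-2") whose genes carry a 2x copy-number
multiplier with some probability, genome-wide background up/down
trans-effects, and multiplicative log-normal FPKM noise. The qPCR
simulator produces Ct values for an ordered 21-marker panel with a
copy-number step at a known inter-marker position, technical triplicates
and four independent experiments, plus reference-gene wells.

Random streams are split per component (control draws, dosage
assignment, noise, qPCR wells) so enlarging one component does not
perturb the others; everything is reproducible bit-for-bit from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .annotation import (
    ExpressionPair,
    GeneCatalog,
    GeneModel,
    Region,
    RegionPartition,
)
from .qpcr import QpcrPlate

__all__ = [
    "DEFAULT_REGION_COUNTS",
    "DEFAULT_REGION_ORDER",
    "ExpressionSimConfig",
    "QpcrSimConfig",
    "SimTruth",
    "simulate_expression_pair",
    "simulate_qpcr_plate",
]

# Expressed-gene counts per analysis region in the emulated design
# (chromosome 11 split into long arm, non-repeat and repeat short arm).
DEFAULT_REGION_COUNTS: dict[str, int] = {
    "Chr1": 3386,
    "Chr2": 2763,
    "Chr3": 3016,
    "Chr4": 2047,
    "Chr5": 1952,
    "Chr6": 1927,
    "Chr7": 1789,
    "Chr8": 1557,
    "Chr9": 1332,
    "Chr10": 1223,
    "11L": 646,
    "11S-1": 448,
    "11S-2": 211,
    "Chr12": 1307,
}
DEFAULT_REGION_ORDER = list(DEFAULT_REGION_COUNTS)

# Physical layout: chromosome, span start, span end (1-based, bp).
_DEFAULT_REGION_SPANS: dict[str, tuple[str, int, int]] = {
    **{f"Chr{i}": (f"Chr{i}", 1, 30_000_000) for i in range(1, 11)},
    "11S-1": ("Chr11", 1, 5_399_999),
    "11S-2": ("Chr11", 5_400_000, 12_100_000),
    "11L": ("Chr11", 12_100_001, 29_000_000),
    "Chr12": ("Chr12", 1, 28_000_000),
}


@dataclass
class ExpressionSimConfig:
    """Conditions for the paired control/variant expression simulation.

    Defaults are the emulated design conditions: per-region expressed
    gene counts (23,604 total), the 11S-2 repeat region duplicated,
    pi_dosage = 0.346 of repeat genes at the full 2x dosage multiplier,
    no compensated (1x) fraction, genome-wide background up/down
    trans-effect fractions 5.55% / 4.18%, log-normal baseline expression
    (natural-log mean 1.6, sd 1.5; FPKM-like scale) and multiplicative
    log-normal noise with sd 0.25.
    """

    n_genes_per_region: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_REGION_COUNTS)
    )
    duplicated_regions: frozenset[str] = frozenset({"11S-2"})
    pi_dosage: float = 0.346
    pi_compensated: float = 0.0
    background_up_fraction: float = 0.0555
    background_down_fraction: float = 0.0418
    baseline_log_mean: float = 1.6
    baseline_log_sd: float = 1.5
    noise_log_sd: float = 0.25
    seed: int = 0
    region_spans: Mapping[str, tuple[str, int, int]] = field(
        default_factory=lambda: dict(_DEFAULT_REGION_SPANS)
    )

    def validate(self) -> None:
        fractions = [
            self.pi_dosage,
            self.pi_compensated,
            self.background_up_fraction,
            self.background_down_fraction,
        ]
        if any(not 0 <= f <= 1 for f in fractions):
            raise ValueError("all fractions must lie in [0, 1]")
        if self.pi_dosage + self.pi_compensated > 1 + 1e-12:
            raise ValueError("pi_dosage + pi_compensated must be <= 1")
        if self.noise_log_sd < 0 or self.baseline_log_sd < 0:
            raise ValueError("log-scale sd parameters must be >= 0")
        for region in self.duplicated_regions:
            if self.n_genes_per_region.get(region, 0) <= 0:
                raise ValueError(
                    f"duplicated region {region!r} has no genes"
                )
        for region in self.n_genes_per_region:
            if region not in self.region_spans:
                raise ValueError(f"no physical span for region {region!r}")


@dataclass
class SimTruth:
    """Ground truth of a simulation: per-gene multipliers, region labels,
    and (for the qPCR simulation) the true step position and levels."""

    multipliers: pd.Series | None = None
    region_map: dict[str, str] | None = None
    partition: RegionPartition | None = None
    duplicated_regions: frozenset[str] = frozenset()
    breakpoint_after_index: int | None = None
    copy_levels: tuple[float, float] | None = None


def _place_genes(
    config: ExpressionSimConfig,
) -> tuple[GeneCatalog, RegionPartition, dict[str, str]]:
    genes: list[GeneModel] = []
    region_map: dict[str, str] = {}
    regions: list[Region] = []
    for region_id, n in config.n_genes_per_region.items():
        chrom, span_start, span_end = config.region_spans[region_id]
        regions.append(Region(region_id, chrom, span_start, span_end))
        if n == 0:
            continue
        # evenly spaced starts across the span; short fixed gene length
        starts = np.linspace(span_start, span_end - 200, n).astype(int)
        for i, s in enumerate(starts):
            gid = f"{region_id}_{i:05d}"
            genes.append(GeneModel(gid, chrom, int(s), int(s) + 150, "+"))
            region_map[gid] = region_id
    return GeneCatalog(genes), RegionPartition(regions), region_map


def _draw_multipliers(
    config: ExpressionSimConfig,
    catalog: GeneCatalog,
    region_map: dict[str, str],
    rng: np.random.Generator,
) -> pd.Series:
    """Dosage multipliers with exact class counts.

    Within each duplicated region, exactly round(pi_dosage * n) genes get
    the full 2x multiplier and round(pi_compensated * n) get 1x, at
    random positions; the remainder get a partial effect uniform in
    (1, 2). Outside, exactly round(fraction * n) genes carry the
    background up (2x Uniform(1,2), i.e. (2,4)) or down
    (0.5x Uniform(0.5,1), i.e. (0.25,0.5)) trans-effect. Exact counts
    make the noiseless dosage fraction reproduce pi_dosage up to integer
    rounding rather than binomial sampling error.
    """
    gene_ids = catalog.gene_ids
    d = np.ones(len(gene_ids))
    aux = rng.random(len(gene_ids))  # uniform component, one per gene
    region_arr = np.array([region_map[g] for g in gene_ids])

    for region in sorted(config.duplicated_regions):
        idx = np.where(region_arr == region)[0]
        n = len(idx)
        n_full = round(config.pi_dosage * n)
        n_comp = round(config.pi_compensated * n)
        order = rng.permutation(idx)
        d[order[:n_full]] = 2.0
        d[order[n_full:n_full + n_comp]] = 1.0
        partial = order[n_full + n_comp:]
        d[partial] = 1.0 + aux[partial]  # partial effect in (1, 2)

    bg = np.where(
        ~np.isin(region_arr, sorted(config.duplicated_regions))
    )[0]
    n_bg = len(bg)
    n_up = round(config.background_up_fraction * n_bg)
    n_down = round(config.background_down_fraction * n_bg)
    order = rng.permutation(bg)
    up_idx = order[:n_up]
    down_idx = order[n_up:n_up + n_down]
    d[up_idx] = 2.0 * (1.0 + aux[up_idx])  # in (2, 4)
    d[down_idx] = 0.5 * (0.5 + 0.5 * aux[down_idx])  # in (0.25, 0.5)
    return pd.Series(d, index=gene_ids)


def simulate_expression_pair(
    config: ExpressionSimConfig | None = None,
) -> tuple[GeneCatalog, ExpressionPair, SimTruth]:
    """Simulate a control/variant expression pair with known multipliers.

    control_g ~ exp(Normal(baseline_log_mean, baseline_log_sd));
    variant_g = control_g * d_g * eps_g with eps_g ~ exp(Normal(0,
    noise_log_sd)) (identically 1 when noise_log_sd = 0, so noiseless
    ratios equal the true multipliers).
    """
    if config is None:
        config = ExpressionSimConfig()
    config.validate()

    catalog, partition, region_map = _place_genes(config)
    ss = np.random.SeedSequence(config.seed)
    rng_control, rng_dosage, rng_noise = (
        np.random.default_rng(child) for child in ss.spawn(3)
    )

    n = len(catalog)
    control = np.exp(
        rng_control.normal(config.baseline_log_mean, config.baseline_log_sd, n)
    )
    multipliers = _draw_multipliers(config, catalog, region_map, rng_dosage)
    if config.noise_log_sd > 0:
        eps = np.exp(rng_noise.normal(0.0, config.noise_log_sd, n))
    else:
        eps = np.ones(n)
    variant = control * multipliers.to_numpy() * eps

    pair = ExpressionPair(
        pd.DataFrame(
            {"control": control, "variant": variant}, index=catalog.gene_ids
        )
    )
    truth = SimTruth(
        multipliers=multipliers,
        region_map=region_map,
        partition=partition,
        duplicated_regions=config.duplicated_regions,
    )
    return catalog, pair, truth


# ---------------------------------------------------------------------------
# qPCR plate simulation


@dataclass
class QpcrSimConfig:
    """Conditions for the marker-panel qPCR simulation.

    21 markers ordered along the chromosome arm, a copy-number step from
    ``copy_levels[0]`` to ``copy_levels[1]`` after marker
    ``breakpoint_after_index`` (1-based; 0 = all markers at the right
    level, n_markers = no step within the panel), additive Gaussian Ct
    noise per well, four experiments of technical triplicates.
    """

    n_markers: int = 21
    breakpoint_after_index: int = 10
    copy_levels: tuple[float, float] = (1.0, 2.0)
    ct_noise_sd: float = 0.1
    n_experiments: int = 4
    n_replicates: int = 3
    ct_base: float = 20.0
    ref_ct_base: float = 18.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_markers < 2:
            raise ValueError("n_markers must be >= 2")
        if not 0 <= self.breakpoint_after_index <= self.n_markers:
            raise ValueError(
                "breakpoint_after_index must lie in [0, n_markers]"
            )
        if self.ct_noise_sd < 0:
            raise ValueError("ct_noise_sd must be >= 0")
        if min(self.copy_levels) <= 0:
            raise ValueError("copy levels must be positive")
        if self.n_experiments < 1 or self.n_replicates < 1:
            raise ValueError("need >= 1 experiment and >= 1 replicate")


def simulate_qpcr_plate(
    config: QpcrSimConfig | None = None,
) -> tuple[QpcrPlate, SimTruth]:
    """Simulate Ct wells for an ordered marker panel with one copy step.

    Marker i (1-based) has template amount T_i = left level if
    i <= breakpoint_after_index else right level, relative to the origin
    sample; test-sample marker wells read Ct = ct_base - log2(T_i) +
    noise, origin marker wells ct_base + noise, and reference wells (T=1)
    ref_ct_base + noise, for every experiment x replicate.
    """
    if config is None:
        config = QpcrSimConfig()
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))

    left, right = config.copy_levels
    marker_ids = [f"M{i:02d}" for i in range(1, config.n_markers + 1)]
    rows = []

    def noise() -> float:
        return float(rng.normal(0.0, config.ct_noise_sd)) if config.ct_noise_sd > 0 else 0.0

    for i, marker in enumerate(marker_ids, start=1):
        t = left if i <= config.breakpoint_after_index else right
        for exp in range(1, config.n_experiments + 1):
            for rep in range(1, config.n_replicates + 1):
                rows.append(
                    (marker, "test", "marker", exp, rep,
                     config.ct_base - float(np.log2(t)) + noise())
                )
                rows.append(
                    (marker, "origin", "marker", exp, rep,
                     config.ct_base + noise())
                )
    for sample in ("test", "origin"):
        for exp in range(1, config.n_experiments + 1):
            for rep in range(1, config.n_replicates + 1):
                rows.append(
                    ("REF", sample, "reference", exp, rep,
                     config.ref_ct_base + noise())
                )

    wells = pd.DataFrame(
        rows,
        columns=["marker_id", "sample", "target", "experiment", "replicate", "ct"],
    )
    plate = QpcrPlate(wells, marker_order=marker_ids)
    truth = SimTruth(
        breakpoint_after_index=config.breakpoint_after_index,
        copy_levels=config.copy_levels,
    )
    return plate, truth
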