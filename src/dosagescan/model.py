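"""Model/Results interfaces tying the analysis stages together.

:class:`DosageExpressionModel` is built from a gene catalog, a matched
control/variant expression pair and a region partition; ``fit()`` returns
a :class:`DosageExpressionResults` holding the ratio table, the
per-region differential-expression summary, the sliding-window median
profile, per-region ratio histograms with dosage-compensation calls,
KS shift tests and Fisher enrichment tests, with a ``summary()`` text
table. :class:`QpcrBreakpointModel` fits the step-changepoint model to a
qPCR marker panel and returns the breakpoint call.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import (
    ExpressionPair,
    GeneCatalog,
    RegionPartition,
    assign_regions,
    load_expression_pair,
    load_gene_annotation,
)
from .qpcr import BreakpointCall, CopyProfile, QpcrPlate, detect_breakpoint, relative_copy_profile
from .ratios import (
    CompensationCall,
    RatioHistogram,
    RatioTable,
    WindowProfile,
    assess_compensation,
    bin_ratio_distribution,
    compute_ratios,
    dosage_effect_fraction,
    sliding_window_median,
    summarize_regions,
)
from .stats import FisherResult, KsResult, fisher_exact_2x2, ks_two_sample

__all__ = [
    "DosageExpressionModel",
    "DosageExpressionResults",
    "QpcrBreakpointModel",
    "QpcrBreakpointResults",
]


class DosageExpressionModel:
    """Genome-wide dosage-effect analysis of one variant vs one control.

    Parameters
    ----------
    catalog : GeneCatalog
        Coordinate-ordered gene annotation.
    pair : ExpressionPair
        Joined control/variant expression values (FPKM-like).
    partition : RegionPartition, optional
        Chromosome region partition; genes outside listed regions fall
        back to their chromosome name.
    window, step : int
        Sliding-window size and step in genes (defaults 100 and 1).
    bin_width, cap : float
        Ratio-histogram bin width (0.05) and overflow cap (5.0).
    theta_up, theta_down : float
        Up/down classification thresholds (inclusive; 2.0 and 0.5).
    peak_tolerance : float
        Half-width for "peak near 1.0 / 2.0" compensation calls.
    ks_mode : {"expression", "ratio_background"}
        "expression" compares a region's variant vs control expression
        values; "ratio_background" compares a region's ratio distribution
        against the rest of the genome.
    fisher_pairs : sequence of (region, region), optional
        Region pairs for up-gene enrichment tests. When omitted, each
        duplicated-candidate region named "11S-2" is tested against
        "11L" and "11S-1" if present.
    region_order : sequence of str, optional
        Row order for the summary table.
    """

    def __init__(
        self,
        catalog: GeneCatalog,
        pair: ExpressionPair,
        partition: RegionPartition | None = None,
        *,
        window: int = 100,
        step: int = 1,
        bin_width: float = 0.05,
        cap: float = 5.0,
        theta_up: float = 2.0,
        theta_down: float = 0.5,
        inclusive_thresholds: bool = True,
        peak_tolerance: float = 0.10,
        ks_mode: str = "expression",
        ks_exact_threshold: float = 35.0,
        fisher_pairs: Sequence[tuple[str, str]] | None = None,
        region_order: Sequence[str] | None = None,
    ) -> None:
        if ks_mode not in {"expression", "ratio_background"}:
            raise ValueError("ks_mode must be 'expression' or 'ratio_background'")
        self.catalog = catalog
        self.pair = pair.restrict_to(catalog)
        self.partition = partition or RegionPartition([])
        self.window = window
        self.step = step
        self.bin_width = bin_width
        self.cap = cap
        self.theta_up = theta_up
        self.theta_down = theta_down
        self.inclusive_thresholds = inclusive_thresholds
        self.peak_tolerance = peak_tolerance
        self.ks_mode = ks_mode
        self.ks_exact_threshold = ks_exact_threshold
        self.fisher_pairs = list(fisher_pairs) if fisher_pairs else None
        self.region_order = list(region_order) if region_order else None
        self.region_map = assign_regions(self.catalog, self.partition)

    @classmethod
    def from_files(
        cls,
        annotation_path,
        control_path,
        variant_path,
        partition_path=None,
        feature_filter: str = "gene",
        id_attribute: str = "ID",
        **kwargs,
    ) -> "DosageExpressionModel":
        catalog = load_gene_annotation(
            annotation_path, feature_filter=feature_filter,
            id_attribute=id_attribute,
        )
        pair = load_expression_pair(control_path, variant_path)
        partition = (
            RegionPartition.from_tsv(partition_path) if partition_path else None
        )
        return cls(catalog, pair, partition, **kwargs)

    # -- fitting ------------------------------------------------------------

    def _default_fisher_pairs(self, regions: list[str]) -> list[tuple[str, str]]:
        pairs = []
        if "11S-2" in regions:
            for other in ("11L", "11S-1"):
                if other in regions:
                    pairs.append(("11S-2", other))
        return pairs

    def _background_gene_ids(self) -> list[str]:
        """Genes covered only by the default (whole-chromosome) rule."""
        chrom_of = {g.gene_id: g.chrom for g in self.catalog}
        return [
            gid for gid, region in self.region_map.items()
            if region == chrom_of[gid]
        ]

    def fit(self) -> "DosageExpressionResults":
        ratios = compute_ratios(
            self.pair,
            theta_up=self.theta_up,
            theta_down=self.theta_down,
            inclusive=self.inclusive_thresholds,
        )
        summary = summarize_regions(
            ratios, self.region_map, region_order=self.region_order
        )
        profile = sliding_window_median(
            ratios, self.catalog, window=self.window, step=self.step
        )

        regions = [r for r in summary["region_id"] if r != "Total"]
        genes_by_region: dict[str, list[str]] = {}
        for gid, region in self.region_map.items():
            genes_by_region.setdefault(region, []).append(gid)

        histograms: dict[str, RatioHistogram] = {}
        compensation: dict[str, CompensationCall] = {}
        fractions: dict[str, tuple[int, int, float]] = {}
        for region in regions:
            genes = genes_by_region.get(region, [])
            hist = bin_ratio_distribution(
                ratios, genes, bin_width=self.bin_width, cap=self.cap
            )
            histograms[region] = hist
            if hist.n_total > 0:
                compensation[region] = assess_compensation(
                    hist, tolerance=self.peak_tolerance, region_id=region
                )
            try:
                fractions[region] = dosage_effect_fraction(ratios, genes)
            except ValueError:
                pass

        ks_results = self._run_ks(ratios, genes_by_region, regions)
        fisher_results = self._run_fisher(summary, regions)

        return DosageExpressionResults(
            model=self,
            ratio_table=ratios,
            summary_table=summary,
            window_profile=profile,
            histograms=histograms,
            compensation_calls=compensation,
            dosage_fractions=fractions,
            ks_results=ks_results,
            fisher_results=fisher_results,
        )

    def _run_ks(
        self,
        ratios: RatioTable,
        genes_by_region: dict[str, list[str]],
        regions: list[str],
    ) -> dict[str, KsResult]:
        out: dict[str, KsResult] = {}
        data = ratios.data
        defined = data["ratio"].notna()

        def expr_test(gene_ids) -> KsResult | None:
            idx = data.index.intersection(pd.Index(gene_ids))
            sub = data.loc[idx]
            sub = sub[sub["ratio"].notna()]
            if len(sub) == 0:
                return None
            return ks_two_sample(
                sub["variant"], sub["control"],
                exact_threshold=self.ks_exact_threshold,
            )

        def ratio_test(gene_ids) -> KsResult | None:
            idx = data.index.intersection(pd.Index(gene_ids))
            x = data.loc[idx, "ratio"].dropna()
            y = data.loc[defined & ~data.index.isin(idx), "ratio"]
            if len(x) == 0 or len(y) == 0:
                return None
            return ks_two_sample(x, y, exact_threshold=self.ks_exact_threshold)

        test = expr_test if self.ks_mode == "expression" else ratio_test
        for region in regions:
            res = test(genes_by_region.get(region, []))
            if res is not None:
                out[region] = res
        background = self._background_gene_ids()
        if background:
            res = test(background)
            if res is not None:
                out["background"] = res
        return out

    def _run_fisher(
        self, summary: pd.DataFrame, regions: list[str]
    ) -> list[dict]:
        pairs = (
            self.fisher_pairs
            if self.fisher_pairs is not None
            else self._default_fisher_pairs(regions)
        )
        by_region = summary.set_index("region_id")
        out = []
        for region_a, region_b in pairs:
            if region_a not in by_region.index or region_b not in by_region.index:
                continue
            a = int(by_region.loc[region_a, "n_up"])
            b = int(by_region.loc[region_a, "n_expressed"]) - a
            c = int(by_region.loc[region_b, "n_up"])
            d = int(by_region.loc[region_b, "n_expressed"]) - c
            res = fisher_exact_2x2(a, b, c, d)
            out.append(
                {"region_a": region_a, "region_b": region_b, **res.to_dict()}
            )
        return out


@dataclass
class DosageExpressionResults:
    """Fitted genome-wide dosage analysis; see the accessor attributes."""

    model: DosageExpressionModel
    ratio_table: RatioTable
    summary_table: pd.DataFrame
    window_profile: WindowProfile
    histograms: dict[str, RatioHistogram]
    compensation_calls: dict[str, CompensationCall]
    dosage_fractions: dict[str, tuple[int, int, float]]
    ks_results: dict[str, KsResult]
    fisher_results: list[dict]

    def summary(self) -> str:
        """Human-readable report: region table, tests, compensation calls."""
        lines = ["Dosage expression analysis", "=" * 60]
        lines.append(f"genes joined: {len(self.ratio_table)}; "
                     f"defined ratios: {len(self.ratio_table.defined)}")
        lines.append("")
        lines.append("Differentially expressed genes per region")
        tbl = self.summary_table.drop(columns=["empty"])
        lines.append(tbl.to_string(index=False))
        if self.compensation_calls:
            lines.append("")
            lines.append("Compensation calls (modal ratio bin)")
            for region, call in self.compensation_calls.items():
                lines.append(
                    f"  {region}: mode {call.modal_bin_center:.3f} "
                    f"peak@1={call.has_peak_at_one} peak@2={call.has_peak_at_two}"
                )
        if self.ks_results:
            lines.append("")
            lines.append(f"KS tests (mode: {self.model.ks_mode})")
            for region, res in self.ks_results.items():
                lines.append(
                    f"  {region}: D={res.D:.4f} p={res.p_value:.3g} "
                    f"(n={res.n_x})"
                )
        for f in self.fisher_results:
            lines.append(
                f"Fisher {f['region_a']} vs {f['region_b']}: "
                f"OR={f['odds_ratio']:.3g} p={f['p_value']:.3g}"
            )
        return "\n".join(lines)

    def to_json_dict(self) -> dict:
        return {
            "n_genes": len(self.ratio_table),
            "n_defined_ratios": int(len(self.ratio_table.defined)),
            "summary_table": self.summary_table.to_dict(orient="records"),
            "compensation_calls": {
                k: v.to_dict() for k, v in self.compensation_calls.items()
            },
            "dosage_fractions": {
                k: {"k": k_, "n": n_, "fraction": f_}
                for k, (k_, n_, f_) in self.dosage_fractions.items()
            },
            "ks_tests": {k: v.to_dict() for k, v in self.ks_results.items()},
            "fisher_tests": self.fisher_results,
        }

    def save(self, out_dir) -> dict[str, str]:
        """Write all stage outputs as TSV/JSON under ``out_dir``."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written: dict[str, str] = {}
        self.ratio_table.to_tsv(out / "ratio_table.tsv")
        written["ratio_table"] = "ratio_table.tsv"
        self.window_profile.to_tsv(out / "window_profile.tsv")
        written["window_profile"] = "window_profile.tsv"
        self.summary_table.to_csv(out / "region_summary.tsv", sep="\t", index=False)
        written["region_summary"] = "region_summary.tsv"
        for region, hist in self.histograms.items():
            safe = region.replace("/", "_")
            hist.to_tsv(out / f"ratio_histogram_{safe}.tsv")
            written[f"histogram:{region}"] = f"ratio_histogram_{safe}.tsv"
        with open(out / "tests.json", "w") as fh:
            json.dump(
                {
                    "ks_tests": {k: v.to_dict() for k, v in self.ks_results.items()},
                    "fisher_tests": self.fisher_results,
                    "compensation_calls": {
                        k: v.to_dict()
                        for k, v in self.compensation_calls.items()
                    },
                },
                fh,
                indent=2,
            )
        written["tests"] = "tests.json"
        return written


class QpcrBreakpointModel:
    """Step-changepoint model for a qPCR marker panel copy profile."""

    def __init__(
        self,
        plate: QpcrPlate,
        candidate_levels: tuple[float, ...] = (1.0, 2.0),
        test_sample: str = "test",
        origin_sample: str = "origin",
    ) -> None:
        self.plate = plate
        self.candidate_levels = candidate_levels
        self.test_sample = test_sample
        self.origin_sample = origin_sample

    @classmethod
    def from_csv(cls, path, marker_order=None, **kwargs) -> "QpcrBreakpointModel":
        return cls(QpcrPlate.from_csv(path, marker_order), **kwargs)

    def fit(self) -> "QpcrBreakpointResults":
        profile = relative_copy_profile(
            self.plate,
            test_sample=self.test_sample,
            origin_sample=self.origin_sample,
        )
        call = detect_breakpoint(profile, self.candidate_levels)
        return QpcrBreakpointResults(model=self, copy_profile=profile, call=call)


@dataclass
class QpcrBreakpointResults:
    model: QpcrBreakpointModel
    copy_profile: CopyProfile
    call: BreakpointCall

    def summary(self) -> str:
        lines = ["qPCR copy-number breakpoint analysis", "=" * 60]
        lines.append(self.copy_profile.data.to_string(index=False))
        c = self.call
        if c.step_called:
            markers = self.copy_profile.marker_ids
            lines.append(
                f"step between {markers[c.changepoint - 1]} and "
                f"{markers[c.changepoint]} (position {c.changepoint}); "
                f"levels {c.left_level:.3f} -> {c.right_level:.3f} "
                f"(calls {c.left_call} -> {c.right_call})"
            )
        else:
            lines.append(
                f"no step within panel (level {c.left_level:.3f}, "
                f"call {c.left_call})"
            )
        return "\n".join(lines)

    def to_json_dict(self) -> dict:
        markers = self.copy_profile.marker_ids
        d = self.call.to_dict()
        if self.call.step_called:
            d["interval"] = [
                markers[self.call.changepoint - 1],
                markers[self.call.changepoint],
            ]
        else:
            d["interval"] = None
        return d

    def save(self, out_dir) -> dict[str, str]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.copy_profile.to_tsv(out / "copy_profile.tsv")
        with open(out / "breakpoint.json", "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=2)
        return {
            "copy_profile": "copy_profile.tsv",
            "breakpoint": "breakpoint.json",
        }
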