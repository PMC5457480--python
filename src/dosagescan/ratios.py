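"""Expression-ratio analysis of a duplication variant against a control.

The central quantity is the per-gene ratio score r_g = variant / control
(FPKM scale). Genes are classified as up-regulated (r >= 2, a positive
dosage effect for a 4:2 copy-number change), down-regulated (r <= 0.5, an
inverse dosage effect) or neutral; genes detected in only one sample are
treated as extreme up/down events for counting but carry no finite ratio.
On top of the ratio table sit the chromosome-wide sliding-window median
profile, the binned ratio distribution per region, the per-region
differential-expression summary table and the dosage-compensation call
(is the modal ratio near 1.0, i.e. buffered back to diploid level, or near
2.0, i.e. proportional to copy number).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotation import ExpressionPair, GeneCatalog

__all__ = [
    "RatioTable",
    "WindowProfile",
    "RatioHistogram",
    "CompensationCall",
    "compute_ratios",
    "sliding_window_median",
    "bin_ratio_distribution",
    "summarize_regions",
    "assess_compensation",
    "dosage_effect_fraction",
    "round_half_up_pct",
]

UP = "up"
DOWN = "down"
NEUTRAL = "neutral"
BOTH_ZERO = "both_zero"


@dataclass
class RatioTable:
    """Per-gene ratio scores with dosage classification.

    ``data`` is indexed by gene_id with columns:

    control, variant : the input expression values
    ratio            : variant/control where both > 0, else NaN
    expressed        : True when expressed (value > 0) in at least one sample
    zero_class       : none | control_zero | variant_zero | both_zero
    dosage_class     : up | down | neutral | both_zero
    """

    data: pd.DataFrame
    theta_up: float = 2.0
    theta_down: float = 0.5

    def __len__(self) -> int:
        return len(self.data)

    @property
    def defined(self) -> pd.Series:
        """Finite ratio values (both samples > 0), indexed by gene_id."""
        return self.data["ratio"].dropna()

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="gene_id")


def compute_ratios(
    pair: ExpressionPair,
    theta_up: float = 2.0,
    theta_down: float = 0.5,
    inclusive: bool = True,
) -> RatioTable:
    """Ratio scores r = variant/control and dosage classes for a joined pair.

    Thresholds are inclusive by default (r >= theta_up -> up,
    r <= theta_down -> down); ``inclusive=False`` switches to strict
    inequalities. A gene expressed only in the variant counts as up, only
    in the control as down; such genes have no finite ratio.
    """
    control = pair.data["control"].to_numpy(float)
    variant = pair.data["variant"].to_numpy(float)
    both = (control > 0) & (variant > 0)

    ratio = np.full(len(control), np.nan)
    np.divide(variant, control, out=ratio, where=both)

    zero_class = np.where(
        both,
        "none",
        np.where(
            (control == 0) & (variant == 0),
            BOTH_ZERO,
            np.where(control == 0, "control_zero", "variant_zero"),
        ),
    )

    if inclusive:
        is_up = both & (ratio >= theta_up)
        is_down = both & (ratio <= theta_down)
    else:
        is_up = both & (ratio > theta_up)
        is_down = both & (ratio < theta_down)
    is_up |= zero_class == "control_zero"
    is_down |= zero_class == "variant_zero"

    dosage_class = np.where(
        is_up, UP, np.where(is_down, DOWN, np.where(both, NEUTRAL, BOTH_ZERO))
    )

    df = pd.DataFrame(
        {
            "control": control,
            "variant": variant,
            "ratio": ratio,
            "expressed": (control > 0) | (variant > 0),
            "zero_class": zero_class,
            "dosage_class": dosage_class,
        },
        index=pair.data.index,
    )
    return RatioTable(df, theta_up=theta_up, theta_down=theta_down)


# ---------------------------------------------------------------------------
# sliding-window median profile


@dataclass
class WindowProfile:
    """Sliding-window medians of ratio scores along each chromosome.

    ``data`` has one row per window: chrom, start_index / center_index /
    end_index (0-based offsets into the chromosome's defined-ratio genes),
    first_gene, last_gene, median. Window size and step are in genes.
    """

    data: pd.DataFrame
    window: int
    step: int

    def __len__(self) -> int:
        return len(self.data)

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    def plot(self, ax=None):
        """Line plot of window medians, one panel-sharing line per chromosome."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 3))
        offset = 0
        for chrom, sub in self.data.groupby("chrom", sort=False):
            x = sub["center_index"].to_numpy() + offset
            ax.plot(x, sub["median"], lw=1.2, label=str(chrom))
            offset = x[-1] + self.window if len(x) else offset
        ax.axhline(1.0, color="grey", lw=0.6, ls="--")
        ax.set_xlabel("gene index along genome")
        ax.set_ylabel(f"median ratio ({self.window}-gene window)")
        return ax


def sliding_window_median(
    ratios: RatioTable,
    catalog: GeneCatalog,
    window: int = 100,
    step: int = 1,
) -> WindowProfile:
    """Median ratio in sliding windows of ``window`` genes, per chromosome.

    Windows slide over the coordinate-ordered genes that have a defined
    ratio and never span chromosomes; chromosomes with fewer such genes
    than ``window`` yield no windows. The median is the standard order
    statistic (mean of the two central values for even ``window``).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if step < 1:
        raise ValueError("step must be >= 1")

    defined = ratios.defined
    rows = []
    cat = catalog.to_dataframe()
    cat = cat[cat["gene_id"].isin(defined.index)]
    for chrom, sub in cat.groupby("chrom", sort=False):
        vals = defined.loc[sub["gene_id"]].to_numpy()
        ids = sub["gene_id"].to_numpy()
        n = len(vals)
        if n < window:
            continue
        view = np.lib.stride_tricks.sliding_window_view(vals, window)[::step]
        medians = np.median(view, axis=1)
        starts = np.arange(0, n - window + 1, step)
        for s, m in zip(starts, medians):
            rows.append(
                {
                    "chrom": chrom,
                    "start_index": int(s),
                    "center_index": int(s + (window - 1) // 2),
                    "end_index": int(s + window - 1),
                    "first_gene": ids[s],
                    "last_gene": ids[s + window - 1],
                    "median": float(m),
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "chrom", "start_index", "center_index", "end_index",
            "first_gene", "last_gene", "median",
        ],
    )
    return WindowProfile(df, window=window, step=step)


# ---------------------------------------------------------------------------
# binned ratio distribution


@dataclass
class RatioHistogram:
    """Ratio counts in right-open bins [k*w, (k+1)*w) plus an overflow bin.

    ``counts[k]`` covers [k*w, (k+1)*w) for k < cap/w; ratios >= cap land
    in ``overflow``. ``n_total`` is the number of finite ratios binned.
    """

    bin_width: float
    cap: float
    counts: np.ndarray
    overflow: int
    n_total: int

    @property
    def bin_centers(self) -> np.ndarray:
        k = np.arange(len(self.counts))
        return (k + 0.5) * self.bin_width

    def to_frame(self) -> pd.DataFrame:
        k = np.arange(len(self.counts))
        df = pd.DataFrame(
            {
                "bin_low": k * self.bin_width,
                "bin_high": (k + 1) * self.bin_width,
                "count": self.counts,
            }
        )
        overflow = pd.DataFrame(
            {"bin_low": [self.cap], "bin_high": [np.inf], "count": [self.overflow]}
        )
        return pd.concat([df, overflow], ignore_index=True)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.bar(self.bin_centers, self.counts, width=self.bin_width * 0.9)
        ax.axvline(1.0, color="blue", lw=1)
        ax.axvline(2.0, color="red", lw=1)
        ax.axvline(0.5, color="red", lw=1, ls="--")
        ax.set_xlabel("expression ratio (variant / control)")
        ax.set_ylabel("gene count")
        return ax


def bin_ratio_distribution(
    ratios: RatioTable,
    region_genes: Iterable[str] | None = None,
    bin_width: float = 0.05,
    cap: float = 5.0,
) -> RatioHistogram:
    """Histogram of defined ratios with fixed-width right-open bins.

    ``region_genes`` restricts the input to a gene set (e.g. one region);
    ratios >= ``cap`` are pooled into the overflow bin. ``cap`` must be a
    positive multiple of ``bin_width``.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    n_bins = cap / bin_width
    if cap <= 0 or abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError("cap must be a positive multiple of bin_width")
    n_bins = int(round(n_bins))

    defined = ratios.defined
    if region_genes is not None:
        idx = defined.index.intersection(pd.Index(region_genes))
        defined = defined.loc[idx]
    vals = defined.to_numpy()

    overflow = int((vals >= cap).sum())
    inside = vals[vals < cap]
    k = np.floor(inside / bin_width).astype(int)
    counts = np.bincount(k, minlength=n_bins)
    return RatioHistogram(
        bin_width=bin_width,
        cap=cap,
        counts=counts,
        overflow=overflow,
        n_total=len(vals),
    )


# ---------------------------------------------------------------------------
# per-region summary table


def round_half_up_pct(k: int, n: int, decimals: int = 2) -> float:
    """100*k/n rounded half-up to ``decimals`` (exact decimal arithmetic)."""
    if n == 0:
        return 0.0
    q = Decimal(100 * k) / Decimal(n)
    exp = Decimal(1).scaleb(-decimals)
    return float(q.quantize(exp, rounding=ROUND_HALF_UP))


def summarize_regions(
    ratios: RatioTable,
    region_map: dict[str, str],
    region_order: Sequence[str] | None = None,
    total_label: str = "Total",
) -> pd.DataFrame:
    """Per-region counts of expressed / up / down genes with percentages.

    ``n_expressed`` counts genes with expression > 0 in at least one sample;
    percentages are of expressed genes, rounded half-up to 2 decimals. A
    final row sums all regions. Empty regions get 0.00 percentages and an
    ``empty`` flag.
    """
    df = ratios.data.copy()
    df["region"] = [region_map.get(g, "unassigned") for g in df.index]

    regions_present = list(dict.fromkeys(df["region"]))
    if region_order is None:
        order = sorted(regions_present)
    else:
        order = [r for r in region_order if r in regions_present]
        order += [r for r in regions_present if r not in order]

    rows = []
    for region in order:
        sub = df[df["region"] == region]
        n_expressed = int(sub["expressed"].sum())
        expressed = sub[sub["expressed"]]
        n_up = int((expressed["dosage_class"] == UP).sum())
        n_down = int((expressed["dosage_class"] == DOWN).sum())
        rows.append(
            {
                "region_id": region,
                "n_expressed": n_expressed,
                "n_up": n_up,
                "up_pct": round_half_up_pct(n_up, n_expressed),
                "n_down": n_down,
                "down_pct": round_half_up_pct(n_down, n_expressed),
                "empty": n_expressed == 0,
            }
        )
    total_expressed = sum(r["n_expressed"] for r in rows)
    total_up = sum(r["n_up"] for r in rows)
    total_down = sum(r["n_down"] for r in rows)
    rows.append(
        {
            "region_id": total_label,
            "n_expressed": total_expressed,
            "n_up": total_up,
            "up_pct": round_half_up_pct(total_up, total_expressed),
            "n_down": total_down,
            "down_pct": round_half_up_pct(total_down, total_expressed),
            "empty": total_expressed == 0,
        }
    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# dosage-compensation assessment


@dataclass
class CompensationCall:
    """Where the modal ratio bin sits: near 1.0 (compensation) or 2.0 (dosage).

    ``has_peak_at_one`` is True iff |modal_bin_center - 1.0| <= tolerance,
    and analogously for 2.0.
    """

    region_id: str
    modal_bin_center: float
    has_peak_at_one: bool
    has_peak_at_two: bool
    tolerance: float = 0.10

    def to_dict(self) -> dict:
        return {
            "region_id": self.region_id,
            "modal_bin_center": self.modal_bin_center,
            "has_peak_at_one": self.has_peak_at_one,
            "has_peak_at_two": self.has_peak_at_two,
            "tolerance": self.tolerance,
        }


def assess_compensation(
    hist: RatioHistogram,
    tolerance: float = 0.10,
    region_id: str = "",
) -> CompensationCall:
    """Locate the modal ratio bin and flag peaks near 1.0 and 2.0.

    Ties between equal-count bins go to the smaller bin center. If the
    overflow bin alone carries the maximum, its nominal center (cap + w/2)
    is used; it is never near 1.0 or 2.0 with the default cap.
    """
    if hist.n_total == 0:
        raise ValueError("empty histogram: no defined ratios to assess")
    finite_max = int(hist.counts.max()) if len(hist.counts) else 0
    if hist.overflow > finite_max:
        modal_center = hist.cap + hist.bin_width / 2
    else:
        modal_center = float(hist.bin_centers[int(np.argmax(hist.counts))])
    return CompensationCall(
        region_id=region_id,
        modal_bin_center=modal_center,
        has_peak_at_one=abs(modal_center - 1.0) <= tolerance,
        has_peak_at_two=abs(modal_center - 2.0) <= tolerance,
        tolerance=tolerance,
    )


def dosage_effect_fraction(
    ratios: RatioTable, region_genes: Iterable[str]
) -> tuple[int, int, float]:
    """(k, n, k/n): up-classified over expressed genes in a region."""
    idx = ratios.data.index.intersection(pd.Index(region_genes))
    sub = ratios.data.loc[idx]
    expressed = sub[sub["expressed"]]
    n = len(expressed)
    if n == 0:
        raise ValueError("region has no expressed genes")
    k = int((expressed["dosage_class"] == UP).sum())
    return k, n, k / n
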