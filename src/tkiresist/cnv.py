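"""Pseudo-probe copy-number analysis from paired tumor/normal read counts.

Exome read counts are aggregated into "pseudo probes" — genomic windows of
2–5 kb built from high-mapping-quality alignments (MQ > 40 upstream) — to
mimic array CGH probes. For each probe the tumor/normal read-count ratio is
log2-transformed, corrected for GC bias, and median-centred at zero on the
autosomes, so a balanced diploid region sits at log2 0, a single-copy gain
(3 vs 2 copies) at log2(1.5) ~ +0.585 and a single-copy loss at
log2(0.5) = -1.

Windows follow the BED convention: 0-based, half-open.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

PROBE_MIN_SIZE = 2_000
PROBE_MAX_SIZE = 5_000

#: Chromosome names excluded from median centring (sex chromosomes).
NON_AUTOSOMES = {"X", "Y", "chrX", "chrY"}


@dataclass
class CnvConfig:
    """Tunables for probe construction and calling.

    ``read_length`` converts read counts to mean per-base coverage
    (coverage = count * read_length / probe size); probes whose normal-sample
    mean coverage is below ``min_mean_coverage`` are discarded. ``min_mq``
    documents the alignment filter expected upstream of the window counts.
    Gain/loss thresholds replace the original study's visual inspection with
    reproducible cutoffs.
    """

    probe_target_size: int = 2_000
    min_mean_coverage: float = 1.0
    min_mq: int = 40
    read_length: int = 100
    gc_bin_width: float = 0.01
    min_bin_probes: int = 10
    gain_log2: float = 0.3
    loss_log2: float = -0.3

    def __post_init__(self) -> None:
        if not (PROBE_MIN_SIZE <= self.probe_target_size <= PROBE_MAX_SIZE):
            raise ValueError(
                f"probe_target_size must lie in [{PROBE_MIN_SIZE}, "
                f"{PROBE_MAX_SIZE}] bp, got {self.probe_target_size}"
            )
        if self.gain_log2 <= 0 or self.loss_log2 >= 0:
            raise ValueError("gain threshold must be > 0 and loss threshold < 0")


@dataclass(frozen=True)
class CnvComparison:
    chrom: str
    start: int
    end: int
    median_log2_pre: float
    median_log2_post: float
    call_pre: str
    call_post: str
    discordant: bool


PROBE_COLUMNS = ["chrom", "start", "end", "gc", "normal_count", "tumor_count"]


def _validate_windows(windows: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PROBE_COLUMNS if c not in windows.columns]
    if missing:
        raise ValueError(f"window table missing columns {missing}")
    df = windows.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    for chrom, grp in df.groupby("chrom", sort=False):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        if (ends <= starts).any():
            raise ValueError(f"{chrom}: window with non-positive length")
        if (starts[1:] < ends[:-1]).any():
            raise ValueError(f"{chrom}: overlapping input windows")
    return df


def tile_pseudoprobes(windows: pd.DataFrame, cfg: Optional[CnvConfig] = None) -> pd.DataFrame:
    """Aggregate sorted non-overlapping windows into 2–5 kb pseudo probes.

    Consecutive windows on a chromosome are merged until the probe reaches
    ``probe_target_size``; counts are summed and GC is length-weighted.
    Probes whose normal-sample mean coverage falls below the minimum are
    dropped (their number is recorded in ``df.attrs['n_discarded']``).
    """
    cfg = cfg or CnvConfig()
    df = _validate_windows(windows)
    probes: List[dict] = []
    n_discarded = 0
    for chrom, grp in df.groupby("chrom", sort=False):
        acc: List[pd.Series] = []
        acc_len = 0
        rows = [row for _, row in grp.iterrows()]
        for i, row in enumerate(rows):
            acc.append(row)
            acc_len += row["end"] - row["start"]
            # flush when target reached, or at chromosome end, but never
            # exceed the maximum probe size with the next window
            next_len = rows[i + 1]["end"] - rows[i + 1]["start"] if i + 1 < len(rows) else 0
            if acc_len >= cfg.probe_target_size or i == len(rows) - 1 or acc_len + next_len > PROBE_MAX_SIZE:
                start, end = acc[0]["start"], acc[-1]["end"]
                size = end - start
                if not (PROBE_MIN_SIZE <= size <= PROBE_MAX_SIZE):
                    acc, acc_len = [], 0
                    continue  # short tail at chromosome end
                lengths = np.array([r["end"] - r["start"] for r in acc], dtype=float)
                gc = float(np.average([r["gc"] for r in acc], weights=lengths))
                normal = int(sum(r["normal_count"] for r in acc))
                tumor = int(sum(r["tumor_count"] for r in acc))
                coverage = normal * cfg.read_length / size
                if coverage < cfg.min_mean_coverage:
                    n_discarded += 1
                else:
                    probes.append(
                        {
                            "chrom": chrom,
                            "start": int(start),
                            "end": int(end),
                            "gc": gc,
                            "normal_count": normal,
                            "tumor_count": tumor,
                            "mean_coverage": coverage,
                        }
                    )
                acc, acc_len = [], 0
    out = pd.DataFrame(probes, columns=PROBE_COLUMNS + ["mean_coverage"])
    out.attrs["n_discarded"] = n_discarded
    return out


def gc_normalize_log2(probes: pd.DataFrame, cfg: Optional[CnvConfig] = None) -> pd.DataFrame:
    """GC-normalized log2 tumor/normal ratios, median-centred on autosomes.

    Raw ratio = tumor_count / normal_count; a pseudo-count of 0.5 is added to
    both counts when tumor_count is 0 (flagged in the ``pseudocounted``
    column). Probes with normal_count 0 are flagged ``unratioable`` and get
    NaN ratios, excluded from all medians. GC correction subtracts the median
    log2 ratio of each GC bin (width 0.01 by default); sparse bins fall back
    to the global median. Finally the autosomal median is recentred to 0.
    """
    cfg = cfg or CnvConfig()
    df = probes.copy()
    tumor = df["tumor_count"].to_numpy(dtype=float)
    normal = df["normal_count"].to_numpy(dtype=float)
    unratioable = normal == 0
    pseudocounted = (tumor == 0) & ~unratioable
    t = np.where(pseudocounted, tumor + 0.5, tumor)
    n = np.where(pseudocounted, normal + 0.5, normal)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2r = np.where(unratioable, np.nan, np.log2(t / n))
    df["log2_ratio_raw"] = log2r
    df["unratioable"] = unratioable
    df["pseudocounted"] = pseudocounted

    valid = ~np.isnan(log2r)
    gc_arr = df["gc"].to_numpy(dtype=float)
    bins = np.floor(gc_arr / cfg.gc_bin_width).astype(int)
    centers, medians = [], []
    for b in np.unique(bins[valid]):
        mask = (bins == b) & valid
        if mask.sum() >= cfg.min_bin_probes:
            centers.append((b + 0.5) * cfg.gc_bin_width)
            medians.append(float(np.median(log2r[mask])))
    corrected = log2r.copy()
    if centers:
        # piecewise-linear median-vs-GC curve; sparse tail bins borrow the
        # interpolated (edge: nearest) well-populated bin median
        correction = np.interp(gc_arr, centers, medians)
        corrected[valid] = log2r[valid] - correction[valid]
    elif valid.any():
        corrected[valid] = log2r[valid] - float(np.median(log2r[valid]))

    autosomal = valid & ~df["chrom"].isin(NON_AUTOSOMES).to_numpy()
    centre_mask = autosomal if autosomal.any() else valid
    centre = float(np.median(corrected[centre_mask])) if centre_mask.any() else 0.0
    df["log2_ratio"] = corrected - centre
    return df


def _call(median_log2: float, cfg: CnvConfig) -> str:
    if math.isnan(median_log2):
        return "neutral"
    if median_log2 >= cfg.gain_log2:
        return "gain"
    if median_log2 <= cfg.loss_log2:
        return "loss"
    return "neutral"


def compare_cnv_profiles(
    pre: pd.DataFrame,
    post: pd.DataFrame,
    cfg: Optional[CnvConfig] = None,
    regions: Optional[Sequence[Tuple[str, int, int]]] = None,
) -> List[CnvComparison]:
    """Region-level gain/loss calls in pre- vs post-treatment profiles.

    Both probe sets must be tiled on the identical grid. Calls derive from
    the median normalized log2 ratio per region against the configured
    thresholds; a region is discordant when the pre and post calls differ.
    When ``regions`` is omitted each chromosome is one region.
    """
    cfg = cfg or CnvConfig()
    for col in ("chrom", "start", "end", "log2_ratio"):
        if col not in pre.columns or col not in post.columns:
            raise ValueError(f"probe tables must carry a {col!r} column")
    grid_pre = pre[["chrom", "start", "end"]].reset_index(drop=True)
    grid_post = post[["chrom", "start", "end"]].reset_index(drop=True)
    if len(grid_pre) != len(grid_post) or not grid_pre.equals(grid_post):
        raise ValueError("pre and post probe grids do not match")

    if regions is None:
        regions = [
            (chrom, int(grp["start"].min()), int(grp["end"].max()))
            for chrom, grp in pre.groupby("chrom", sort=False)
        ]

    out: List[CnvComparison] = []
    for chrom, start, end in regions:
        in_region = (
            (pre["chrom"] == chrom) & (pre["start"] >= start) & (pre["end"] <= end)
        ).to_numpy()
        med_pre = float(np.nanmedian(pre.loc[in_region, "log2_ratio"])) if in_region.any() else math.nan
        med_post = float(np.nanmedian(post.loc[in_region, "log2_ratio"])) if in_region.any() else math.nan
        call_pre = _call(med_pre, cfg)
        call_post = _call(med_post, cfg)
        out.append(
            CnvComparison(
                chrom=chrom,
                start=start,
                end=end,
                median_log2_pre=med_pre,
                median_log2_post=med_post,
                call_pre=call_pre,
                call_post=call_post,
                discordant=call_pre != call_post,
            )
        )
    return out


def comparisons_to_dataframe(comparisons: Sequence[CnvComparison]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in comparisons])
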