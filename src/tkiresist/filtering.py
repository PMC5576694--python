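"""Paired normal / pre- / post-treatment somatic filter cascade.

The cascade identifies candidate treatment-resistance mutations from
read-count tables of paired samples:

1. discard variants whose paired-normal total read count is below 10 —
   personal (germline) status cannot be excluded at such shallow coverage;
2. + 3. call a variant germline when the normal sample shows >=2 mutant reads
   at a total depth of 10–49, or >=3 mutant reads at a depth of >=50;
   the remaining variants are regarded as true somatic mutations;
4. discard somatic variants with less than 10x coverage in the pre-treatment
   (P) or post-treatment (R) tumor biopsy (R only when no P sample exists);
5. select resistance candidates by one of two strategies:
   * strategy A (no pre-treatment sample required): variant is present in the
     resistant biopsy, MRF_R > 0;
   * strategy B (paired P and R): the mutant read frequency more than doubles
     under treatment, MRF_R > 2 * MRF_P (strict);
   and finally keep only variants with mapping quality > 20 and variant
   quality score > 20 (both strict).

Every input variant receives exactly one outcome in the audit trace, so the
per-outcome counts always sum to the input size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import pandas as pd

from .variants import (
    Mrf,
    PatientVariantSet,
    VariantKey,
    VariantObservation,
    compute_mrf,
)

#: Mutually exclusive and exhaustive trace outcomes, in cascade order.
OUTCOMES = (
    "removed_step1",
    "removed_germline",
    "removed_step4",
    "not_selected",
    "removed_quality",
    "selected",
)


@dataclass
class FilterConfig:
    """Numeric thresholds of the cascade.

    Defaults encode the published rules: normal depth < 10 removed;
    germline bands (mutant >= 2 at total 10–49) and (mutant >= 3 at
    total >= 50); tumor depth >= 10; MRF fold 2 (strict >); MQ and QUAL
    both strictly > 20.
    """

    normal_min_depth: int = 10
    germline_band1_min_mutant: int = 2
    germline_band1_total: Tuple[int, int] = (10, 49)
    germline_band2_min_mutant: int = 3
    germline_band2_min_total: int = 50
    tumor_min_depth: int = 10
    mrf_fold: float = 2.0
    min_mq: float = 20.0
    min_qual: float = 20.0

    def __post_init__(self) -> None:
        numeric = [
            self.normal_min_depth,
            self.germline_band1_min_mutant,
            self.germline_band2_min_mutant,
            self.germline_band2_min_total,
            self.tumor_min_depth,
            self.mrf_fold,
            self.min_mq,
            self.min_qual,
        ]
        if any(x <= 0 for x in numeric):
            raise ValueError("all filter thresholds must be > 0")
        lo, hi = self.germline_band1_total
        if not (0 < lo <= hi):
            raise ValueError("germline band-1 total range must satisfy 0 < lo <= hi")


@dataclass
class FilterTrace:
    """Audit record for one variant: which step removed it, or 'selected'."""

    key: VariantKey
    outcome: str
    strategy: str
    gene: str = ""
    mrf_p: Optional[Mrf] = None
    mrf_r: Optional[Mrf] = None
    note: str = ""


# ---------------------------------------------------------------------------
# Individual cascade steps
# ---------------------------------------------------------------------------

def filter_normal_depth(
    pset: PatientVariantSet,
    cfg: FilterConfig,
    keys: Optional[Iterable[VariantKey]] = None,
) -> Tuple[List[VariantKey], List[VariantKey]]:
    """Step 1: partition variant keys into (removed, surviving) on normal depth.

    A variant without a normal observation is treated as depth 0 and removed.
    """
    if keys is None:
        keys = pset.variant_keys()
    removed, surviving = [], []
    for key in keys:
        n_obs = pset.get(key, "N")
        depth = n_obs.total_reads if n_obs is not None else 0
        (removed if depth < cfg.normal_min_depth else surviving).append(key)
    return removed, surviving


def classify_germline(normal_obs: VariantObservation, cfg: FilterConfig) -> str:
    """Steps 2+3: 'germline' or 'somatic' from normal-sample read counts."""
    m, t = normal_obs.mutant_reads, normal_obs.total_reads
    lo, hi = cfg.germline_band1_total
    band1 = m >= cfg.germline_band1_min_mutant and lo <= t <= hi
    band2 = m >= cfg.germline_band2_min_mutant and t >= cfg.germline_band2_min_total
    return "germline" if (band1 or band2) else "somatic"


def filter_tumor_depth(
    pset: PatientVariantSet,
    cfg: FilterConfig,
    strategy: str,
    keys: Optional[Iterable[VariantKey]] = None,
) -> Tuple[List[VariantKey], List[VariantKey]]:
    """Step 4: partition on tumor coverage.

    Strategy B requires >= `tumor_min_depth` total reads in both the
    pre-treatment and the post-treatment biopsy; strategy A (no pre-treatment
    sample) checks the post-treatment biopsy only. A variant with no
    observation in a required role has unknown coverage and is removed.
    """
    _check_strategy(strategy)
    if strategy == "B" and not pset.has_role("P"):
        raise ValueError(
            f"strategy B requires a pre-treatment (P) sample for patient "
            f"{pset.patient_id}"
        )
    if keys is None:
        keys = pset.variant_keys()
    required = ("P", "R") if strategy == "B" else ("R",)
    removed, surviving = [], []
    for key in keys:
        ok = True
        for role in required:
            obs = pset.get(key, role)
            if obs is None or obs.total_reads < cfg.tumor_min_depth:
                ok = False
                break
        (surviving if ok else removed).append(key)
    return removed, surviving


def apply_quality_filter(
    variants: Iterable[VariantObservation], cfg: FilterConfig
) -> Tuple[List[VariantObservation], List[VariantObservation]]:
    """Final gate: partition into (removed, retained) on MQ and QUAL.

    Retained iff mq > min_mq and qual > min_qual, both strict; a missing
    quality value fails the gate.
    """
    removed, retained = [], []
    for obs in variants:
        ok = (
            obs.mq is not None
            and obs.qual is not None
            and obs.mq > cfg.min_mq
            and obs.qual > cfg.min_qual
        )
        (retained if ok else removed).append(obs)
    return removed, retained


def select_strategy_a(
    pset: PatientVariantSet,
    cfg: FilterConfig,
    keys: Optional[Iterable[VariantKey]] = None,
) -> Tuple[List[VariantKey], List[str]]:
    """Strategy A presence rule: selected iff MRF_R > 0.

    Returns the selected keys and the distinct gene symbols they hit
    (first-seen order).
    """
    if keys is None:
        _, keys = filter_tumor_depth(pset, cfg, "A")
    selected: List[VariantKey] = []
    genes: Dict[str, None] = {}
    for key in keys:
        obs = pset.get(key, "R")
        if obs is None:
            continue
        mrf = compute_mrf(obs)
        if mrf.defined and mrf.value > 0:
            selected.append(key)
            if obs.gene:
                genes.setdefault(obs.gene.strip())
    return selected, list(genes)


def select_strategy_b(
    pset: PatientVariantSet,
    cfg: FilterConfig,
    keys: Optional[Iterable[VariantKey]] = None,
) -> List[VariantKey]:
    """Strategy B doubling rule: selected iff MRF_R > mrf_fold * MRF_P (strict).

    Resistant-specific variants (MRF_P = 0, MRF_R > 0) satisfy the rule.
    """
    if keys is None:
        _, keys = filter_tumor_depth(pset, cfg, "B")
    selected = []
    for key in keys:
        p_obs, r_obs = pset.get(key, "P"), pset.get(key, "R")
        if p_obs is None or r_obs is None:
            continue
        mrf_p, mrf_r = compute_mrf(p_obs), compute_mrf(r_obs)
        if not (mrf_p.defined and mrf_r.defined):
            continue
        if mrf_r.value > cfg.mrf_fold * mrf_p.value:
            selected.append(key)
    return selected


def _check_strategy(strategy: str) -> None:
    if strategy not in ("A", "B"):
        raise ValueError(f"strategy must be 'A' or 'B', got {strategy!r}")


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def run_filter_pipeline(
    pset: PatientVariantSet,
    cfg: Optional[FilterConfig] = None,
    strategy: str = "B",
) -> List[FilterTrace]:
    """Run the full cascade on one patient, returning one trace per variant.

    The variant universe is every key observed in a tumor role (P or R).
    Step order: normal depth -> germline call -> tumor depth -> strategy
    selection -> quality gate (applied last, to would-be selections only).
    """
    _check_strategy(strategy)
    cfg = cfg or FilterConfig()
    if strategy == "B" and not pset.has_role("P"):
        raise ValueError(
            f"strategy B requires a pre-treatment (P) sample for patient "
            f"{pset.patient_id}"
        )

    universe: Dict[VariantKey, None] = {}
    for role in ("P", "R"):
        for key in pset.keys_in_role(role):
            universe.setdefault(key)

    traces: List[FilterTrace] = []
    for key in universe:
        r_obs = pset.get(key, "R")
        p_obs = pset.get(key, "P")
        gene = ""
        for obs in (r_obs, p_obs):
            if obs is not None and obs.gene:
                gene = obs.gene
                break
        mrf_p = compute_mrf(p_obs) if p_obs is not None else None
        mrf_r = compute_mrf(r_obs) if r_obs is not None else None

        def trace(outcome: str, note: str = "") -> FilterTrace:
            return FilterTrace(
                key=key,
                outcome=outcome,
                strategy=strategy,
                gene=gene,
                mrf_p=mrf_p,
                mrf_r=mrf_r,
                note=note,
            )

        # Step 1: normal depth.
        n_obs = pset.get(key, "N")
        n_depth = n_obs.total_reads if n_obs is not None else 0
        if n_depth < cfg.normal_min_depth:
            traces.append(
                trace("removed_step1", "no normal observation" if n_obs is None else "")
            )
            continue

        # Steps 2+3: germline call on the normal counts.
        if classify_germline(n_obs, cfg) == "germline":
            traces.append(trace("removed_germline"))
            continue

        # Step 4: tumor coverage.
        required = ("P", "R") if strategy == "B" else ("R",)
        shallow = False
        for role in required:
            obs = pset.get(key, role)
            if obs is None or obs.total_reads < cfg.tumor_min_depth:
                shallow = True
                break
        if shallow:
            traces.append(trace("removed_step4"))
            continue

        # Step 5 / presence rule.
        if strategy == "A":
            assert mrf_r is not None
            hit = mrf_r.defined and mrf_r.value > 0
        else:
            assert mrf_p is not None and mrf_r is not None
            if not (mrf_p.defined and mrf_r.defined):
                # Depth >= 10 in both roles makes this unreachable; keep a
                # defensive removal rather than selecting on undefined MRF.
                traces.append(trace("removed_step4", "undefined MRF"))
                continue
            hit = mrf_r.value > cfg.mrf_fold * mrf_p.value
        if not hit:
            traces.append(trace("not_selected"))
            continue

        # Final step: quality gate on the resistant-biopsy observation.
        removed, _retained = apply_quality_filter([r_obs], cfg)
        traces.append(trace("removed_quality" if removed else "selected"))

    return traces


def selected_keys(traces: Iterable[FilterTrace]) -> List[VariantKey]:
    return [t.key for t in traces if t.outcome == "selected"]


def selected_genes(traces: Iterable[FilterTrace]) -> List[str]:
    """Distinct gene symbols of selected variants, first-seen order."""
    genes: Dict[str, None] = {}
    for t in traces:
        if t.outcome == "selected" and t.gene:
            genes.setdefault(t.gene.strip())
    return list(genes)


def traces_to_dataframe(traces: Iterable[FilterTrace], cfg: Optional[FilterConfig] = None) -> pd.DataFrame:
    """Flatten traces to the audit TSV layout (one row per input variant)."""
    cfg = cfg or FilterConfig()
    rows = []
    for t in traces:
        rows.append(
            {
                "chrom": t.key[0],
                "pos": t.key[1],
                "ref": t.key[2],
                "alt": t.key[3],
                "gene": t.gene,
                "strategy": t.strategy,
                "outcome": t.outcome,
                "mrf_p": t.mrf_p.value if (t.mrf_p and t.mrf_p.defined) else None,
                "mrf_r": t.mrf_r.value if (t.mrf_r and t.mrf_r.defined) else None,
                "normal_min_depth": cfg.normal_min_depth,
                "tumor_min_depth": cfg.tumor_min_depth,
                "mrf_fold": cfg.mrf_fold,
                "min_mq": cfg.min_mq,
                "min_qual": cfg.min_qual,
                "note": t.note,
            }
        )
    return pd.DataFrame(rows)
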