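"""Synthetic paired-sample data with known ground truth.

Three generators emulate the data structures of a paired
normal / pre-treatment / post-treatment exome study so every downstream
stage is testable without any sequencing download:

* :func:`gen_patient_variants` — per-patient variant read-count tables with
  planted germline (heterozygous, allele fraction ~0.5 in the normal),
  shared-somatic (equal mutant read frequency pre and post) and
  resistant-enriched variants (post-treatment MRF a fixed fold above the
  pre-treatment MRF), plus genes planted recurrently across patients.
* :func:`gen_coverage_tracks` — paired per-window read counts with a GC
  profile, optional multiplicative GC bias, and planted copy-number
  segments.
* :func:`gen_cohort` — survival cohorts with exponential event times
  (median m ⇒ rate ln2/m), independent exponential censoring, and RECIST
  response labels.

Noise model: total depth is Poisson around the mean depth and mutant reads
are binomial given the true MRF, matching the count nature of the data;
``noise=False`` gives the deterministic expectation (rounded), which is what
exact ground-truth-recovery tests use. Identical seeds give identical
output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .cohort import CohortRecord
from .variants import PatientVariantSet, VariantObservation

_CHROMS = [str(c) for c in range(1, 23)]


# ---------------------------------------------------------------------------
# Variant tables
# ---------------------------------------------------------------------------

@dataclass
class VariantSimSpec:
    """Parameters of the paired variant-table generator.

    Counts are per patient except ``n_recurrent_genes``, which plants one
    resistant-enriched variant of the same gene in (at least) two patients.
    Depth and purity are not published for the emulated study; the defaults
    (100x mean depth, pre-treatment somatic MRF 0.10, fold change 4) are this
    package's choices of a realistic FFPE exome scenario.
    """

    n_patients: int = 3
    n_germline: int = 30
    n_shared_somatic: int = 10
    n_resistant_specific: int = 5
    n_recurrent_genes: int = 0
    depth_mean: float = 100.0
    germline_vaf: float = 0.5
    somatic_mrf_pre: float = 0.10
    mrf_fold_change: float = 4.0
    seed: int = 0
    noise: bool = True

    def __post_init__(self) -> None:
        counts = (
            self.n_patients,
            self.n_germline,
            self.n_shared_somatic,
            self.n_resistant_specific,
            self.n_recurrent_genes,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        for frac in (self.germline_vaf, self.somatic_mrf_pre):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.mrf_fold_change <= 0:
            raise ValueError("mrf_fold_change must be > 0")
        if self.depth_mean < 0:
            raise ValueError("depth_mean must be >= 0")
        if self.n_recurrent_genes > 0 and self.n_patients < 2:
            raise ValueError("recurrent genes need at least 2 patients")


def _draw_counts(rng: np.random.Generator, depth_mean: float, mrf: float, noise: bool) -> Tuple[int, int]:
    if noise:
        total = int(rng.poisson(depth_mean))
        mutant = int(rng.binomial(total, mrf)) if total > 0 else 0
    else:
        total = int(round(depth_mean))
        mutant = int(round(mrf * total))
    return total, mutant


def gen_patient_variants(
    spec: VariantSimSpec,
) -> Tuple[List[PatientVariantSet], pd.DataFrame]:
    """Generate per-patient variant sets and a ground-truth label table.

    Returns ``(patient_sets, truth)`` where ``truth`` has one row per
    planted variant with columns ``patient, chrom, pos, ref, alt, gene,
    label`` and label in {germline, shared_somatic, resistant_specific}.
    Resistant-enriched variants have a true post-treatment MRF of
    ``mrf_fold_change`` times the pre-treatment MRF, so with a fold change
    above 2 they satisfy the doubling rule by construction.
    """
    rng = np.random.default_rng(spec.seed)
    bases = np.array(["A", "C", "G", "T"])

    mrf_post_enriched = min(spec.mrf_fold_change * spec.somatic_mrf_pre, 0.95)

    # gene -> list of patient indices carrying a planted recurrent variant
    recurrent_plan: List[Tuple[str, int]] = []
    for g in range(spec.n_recurrent_genes):
        gene = f"REC{g + 1:03d}"
        p1 = g % spec.n_patients
        p2 = (g + 1) % spec.n_patients
        recurrent_plan.extend([(gene, p1), (gene, p2)])

    psets: List[PatientVariantSet] = []
    truth_rows: List[dict] = []
    for p in range(spec.n_patients):
        pid = f"SIM{p + 1:02d}"
        pset = PatientVariantSet(patient_id=pid)
        plan: List[Tuple[str, str]] = (
            [("germline", "")] * spec.n_germline
            + [("shared_somatic", "")] * spec.n_shared_somatic
            + [("resistant_specific", "")] * spec.n_resistant_specific
            + [("resistant_specific", gene) for gene, pi in recurrent_plan if pi == p]
        )
        used_pos: set = set()
        for i, (label, gene) in enumerate(plan):
            chrom = _CHROMS[int(rng.integers(len(_CHROMS)))]
            pos = int(rng.integers(1, 100_000_000))
            while (chrom, pos) in used_pos:
                pos = int(rng.integers(1, 100_000_000))
            used_pos.add((chrom, pos))
            ref, alt = rng.choice(bases, size=2, replace=False)
            gene = gene or f"GENE_{pid}_{i + 1:04d}"

            if label == "germline":
                mrf_n = mrf_p = mrf_r = spec.germline_vaf
            elif label == "shared_somatic":
                mrf_n, mrf_p, mrf_r = 0.0, spec.somatic_mrf_pre, spec.somatic_mrf_pre
            else:
                mrf_n, mrf_p, mrf_r = 0.0, spec.somatic_mrf_pre, mrf_post_enriched

            for role, mrf in (("N", mrf_n), ("P", mrf_p), ("R", mrf_r)):
                total, mutant = _draw_counts(rng, spec.depth_mean, mrf, spec.noise)
                pset.add(
                    role,
                    VariantObservation(
                        chrom=chrom,
                        pos=pos,
                        ref=str(ref),
                        alt=str(alt),
                        gene=gene,
                        total_reads=total,
                        mutant_reads=mutant,
                        mq=60.0,
                        qual=99.0,
                    ),
                )
            truth_rows.append(
                {
                    "patient": pid,
                    "chrom": chrom,
                    "pos": pos,
                    "ref": str(ref),
                    "alt": str(alt),
                    "gene": gene,
                    "label": label,
                }
            )
        psets.append(pset)
    truth = pd.DataFrame(
        truth_rows, columns=["patient", "chrom", "pos", "ref", "alt", "gene", "label"]
    )
    return psets, truth


# ---------------------------------------------------------------------------
# Coverage tracks
# ---------------------------------------------------------------------------

@dataclass
class CnvSimSpec:
    """Parameters of the paired coverage-track generator.

    ``planted_segments`` is a list of ``(start, end, tumor_copies,
    normal_copies)`` in bp on a single synthetic chromosome; outside planted
    segments both samples are diploid. ``gc_bias_strength`` is the slope of
    a multiplicative linear bias around GC 0.5 and ``gc_bias_mode`` says
    whether it hits both samples ('shared', cancels in the ratio) or the
    tumor only ('tumor_only', which the normalization must remove).
    ``depth_mean`` is the expected read count per window at copy number 2.
    """

    genome_length: int = 10_000_000
    probe_target_size: int = 2_000
    gc_profile: Optional[Sequence[float]] = None
    planted_segments: Sequence[Tuple[int, int, int, int]] = ()
    gc_bias_strength: float = 0.0
    gc_bias_mode: str = "shared"
    depth_mean: float = 100.0
    seed: int = 0
    noise: bool = True
    chrom: str = "1"

    def __post_init__(self) -> None:
        if self.genome_length <= 0 or self.probe_target_size <= 0:
            raise ValueError("genome_length and probe_target_size must be > 0")
        if self.gc_bias_mode not in ("shared", "tumor_only"):
            raise ValueError("gc_bias_mode must be 'shared' or 'tumor_only'")
        segs = sorted(self.planted_segments)
        for start, end, tc, nc in segs:
            if not (0 <= start < end <= self.genome_length):
                raise ValueError(f"segment ({start}, {end}) outside genome")
            if tc < 0 or nc < 0:
                raise ValueError("copy numbers must be >= 0")
        for (s1, e1, *_), (s2, _e2, *_) in zip(segs, segs[1:]):
            if s2 < e1:
                raise ValueError("overlapping planted segments")


def gen_coverage_tracks(spec: CnvSimSpec) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Generate paired per-window read counts with GC fractions.

    Returns ``(windows, truth)``: windows with columns ``chrom, start, end,
    gc, normal_count, tumor_count`` (BED convention) and the planted-segment
    table. The expected tumor/normal ratio inside a planted segment is
    ``tumor_copies / normal_copies`` before noise and GC bias.
    """
    rng = np.random.default_rng(spec.seed)
    w = spec.probe_target_size
    n_windows = spec.genome_length // w
    starts = np.arange(n_windows) * w
    ends = starts + w

    if spec.gc_profile is not None:
        gc = np.asarray(spec.gc_profile, dtype=float)
        if len(gc) != n_windows:
            raise ValueError(f"gc_profile must have {n_windows} entries, got {len(gc)}")
        if ((gc < 0) | (gc > 1)).any():
            raise ValueError("gc fractions must lie in [0, 1]")
    else:
        # smooth-ish profile: slow sinusoid plus jitter, clipped to [0.2, 0.8]
        gc = 0.5 + 0.12 * np.sin(2 * np.pi * starts / 2e6) + rng.normal(0, 0.05, n_windows)
        gc = np.clip(gc, 0.2, 0.8)

    tumor_copies = np.full(n_windows, 2.0)
    normal_copies = np.full(n_windows, 2.0)
    for start, end, tc, nc in spec.planted_segments:
        mask = (starts >= start) & (ends <= end)
        tumor_copies[mask] = tc
        normal_copies[mask] = nc

    bias = np.clip(1.0 + spec.gc_bias_strength * (gc - 0.5), 0.0, None)
    bias_tumor = bias
    bias_normal = bias if spec.gc_bias_mode == "shared" else np.ones(n_windows)

    mean_tumor = spec.depth_mean * (tumor_copies / 2.0) * bias_tumor
    mean_normal = spec.depth_mean * (normal_copies / 2.0) * bias_normal
    if spec.noise:
        tumor = rng.poisson(mean_tumor)
        normal = rng.poisson(mean_normal)
    else:
        tumor = np.round(mean_tumor).astype(int)
        normal = np.round(mean_normal).astype(int)

    windows = pd.DataFrame(
        {
            "chrom": spec.chrom,
            "start": starts,
            "end": ends,
            "gc": gc,
            "normal_count": normal.astype(int),
            "tumor_count": tumor.astype(int),
        }
    )
    truth = pd.DataFrame(
        list(spec.planted_segments),
        columns=["start", "end", "tumor_copies", "normal_copies"],
    )
    return windows, truth


# ---------------------------------------------------------------------------
# Survival cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortSimSpec:
    """Parameters of the survival-cohort generator.

    Event times are exponential with the requested per-group medians
    (median m ⇒ rate ln2/m). Censoring is by an independent exponential
    censoring time whose rate is set so the expected censored fraction is
    ``censor_fraction``. Defaults emulate a second-line TKI cohort: PFS
    medians 2.8/2.7 months and OS medians 8.8/3.6 months for the T790M+ and
    T790M- groups, response probabilities PR 0.18 / SD 0.61 / PD 0.21.
    """

    n_patients: int = 38
    median_pfs_by_group: Mapping[str, float] = field(
        default_factory=lambda: {"T790M+": 2.8, "T790M-": 2.7}
    )
    median_os_by_group: Mapping[str, float] = field(
        default_factory=lambda: {"T790M+": 8.8, "T790M-": 3.6}
    )
    censor_fraction: float = 0.1
    response_distribution: Mapping[str, float] = field(
        default_factory=lambda: {"PR": 0.18, "SD": 0.61, "PD": 0.21}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if not 0.0 <= self.censor_fraction <= 1.0:
            raise ValueError("censor_fraction must lie in [0, 1]")
        if set(self.median_pfs_by_group) != set(self.median_os_by_group):
            raise ValueError("PFS and OS group labels must match")
        for m in (*self.median_pfs_by_group.values(), *self.median_os_by_group.values()):
            if m <= 0:
                raise ValueError("medians must be > 0")
        bad = set(self.response_distribution) - {"CR", "PR", "SD", "PD"}
        if bad:
            raise ValueError(f"unknown response labels {bad}")
        total = sum(self.response_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"response probabilities must sum to 1, got {total}")


_CHANGE_RANGE = {"CR": (-100.0, -100.0), "PR": (-95.0, -31.0), "SD": (-30.0, 20.0), "PD": (21.0, 120.0)}


def _observe(
    rng: np.random.Generator, t_event: float, event_rate: float, censor_fraction: float
) -> Tuple[float, bool]:
    if censor_fraction <= 0.0:
        return t_event, True
    if censor_fraction >= 1.0:
        return t_event, False
    # independent exponential censoring time C with rate rc chosen so
    # P(C < T) = rc / (rc + rt) = f; observe min(T, C)
    rc = event_rate * censor_fraction / (1.0 - censor_fraction)
    t_cens = rng.exponential(1.0 / rc)
    if t_cens < t_event:
        return t_cens, False
    return t_event, True


def gen_cohort(spec: CohortSimSpec) -> List[CohortRecord]:
    """Generate survival cohort records with known group medians."""
    rng = np.random.default_rng(spec.seed)
    groups = list(spec.median_pfs_by_group)
    labels = list(spec.response_distribution)
    probs = np.array([spec.response_distribution[l] for l in labels], dtype=float)
    records: List[CohortRecord] = []
    for i in range(spec.n_patients):
        group = groups[i % len(groups)]
        m_pfs = spec.median_pfs_by_group[group]
        m_os = spec.median_os_by_group[group]
        rate_pfs = math.log(2) / m_pfs
        rate_os = math.log(2) / m_os
        t_pfs = rng.exponential(1.0 / rate_pfs)
        t_os = rng.exponential(1.0 / rate_os)
        pfs, pfs_event = _observe(rng, t_pfs, rate_pfs, spec.censor_fraction)
        os_, os_event = _observe(rng, t_os, rate_os, spec.censor_fraction)
        response = str(rng.choice(labels, p=probs)) if labels else None
        lo, hi = _CHANGE_RANGE[response]
        change = float(rng.uniform(lo, hi)) if lo < hi else lo
        records.append(
            CohortRecord(
                patient_id=f"SIMC{i + 1:04d}",
                egfr_status="activating",
                t790m={"T790M+": True, "T790M-": False}.get(group),
                best_tumor_change=change,
                response=response,
                pfs_months=pfs,
                pfs_event=pfs_event,
                os_months=os_,
                os_event=os_event,
                group=group,
            )
        )
    return records


def cohort_to_dataframe(records: Sequence[CohortRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])
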