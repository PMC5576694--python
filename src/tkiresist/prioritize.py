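"""Prioritization of filtered variants.

Three orthogonal views rank candidate resistance mutations:

* CADD deleteriousness classes — "probable" functional effect for CADD > 20
  (top 1% most deleterious positions genome-wide), "possible" for
  10 < CADD <= 20 (top 10%), "below" otherwise; a missing score leaves the
  variant "unclassified" (never treated as 0).
* cross-patient recurrence — a gene is recurrent when selected mutations hit
  it in at least ``k`` distinct patients.
* population/somatic database flags — variants absent from ExAC but present
  in COSMIC are the most interesting tier; presence in ExAC marks a variant
  as likely a residual personal variant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Set

import pandas as pd

from .variants import VariantObservation

CADD_PROBABLE_MIN = 20.0  # strict: probable iff cadd > 20
CADD_POSSIBLE_MIN = 10.0  # strict: possible iff 10 < cadd <= 20


@dataclass(frozen=True)
class RecurrenceReport:
    gene: str
    patients: frozenset
    n_mutations: int
    recurrent: bool


def classify_cadd(cadd: Optional[float]) -> str:
    """CADD class of one score: probable / possible / below / unclassified."""
    if cadd is None:
        return "unclassified"
    if cadd > CADD_PROBABLE_MIN:
        return "probable"
    if cadd > CADD_POSSIBLE_MIN:
        return "possible"
    return "below"


def classify_cadd_variants(variants: Iterable[VariantObservation]) -> List[str]:
    return [classify_cadd(v.cadd) for v in variants]


def find_recurrent_genes(
    per_patient_selected: Mapping[str, Iterable],
    k: int = 2,
) -> List[RecurrenceReport]:
    """Cross-patient recurrence of selected mutations.

    ``per_patient_selected`` maps patient id to that patient's selected
    variants; each variant needs a ``gene`` attribute (VariantObservation) or
    is taken as a bare gene symbol. Distinct patients are counted, not
    mutations. Reports are sorted by patient count (desc), then gene name.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    patients_by_gene: Dict[str, Set[str]] = {}
    mutations_by_gene: Dict[str, int] = {}
    for patient, variants in per_patient_selected.items():
        for v in variants:
            gene = (v.gene if hasattr(v, "gene") else str(v)).strip()
            if not gene:
                continue
            patients_by_gene.setdefault(gene, set()).add(patient)
            mutations_by_gene[gene] = mutations_by_gene.get(gene, 0) + 1
    reports = [
        RecurrenceReport(
            gene=g,
            patients=frozenset(ps),
            n_mutations=mutations_by_gene[g],
            recurrent=len(ps) >= k,
        )
        for g, ps in patients_by_gene.items()
    ]
    reports.sort(key=lambda r: (-len(r.patients), r.gene))
    return reports


def flag_database_presence(variants: Iterable[VariantObservation]) -> List[str]:
    """Tier each variant from its ExAC / COSMIC presence flags.

    tier1: absent from ExAC, present in COSMIC (most likely relevant);
    tier2: absent from both; tier3: present in ExAC (likely a residual
    personal variant); untiered: flags missing.
    """
    tiers = []
    for v in variants:
        if v.in_exac is None:
            tiers.append("untiered")
        elif v.in_exac:
            tiers.append("tier3")
        elif v.in_cosmic:
            tiers.append("tier1")
        elif v.in_cosmic is None:
            tiers.append("untiered")
        else:
            tiers.append("tier2")
    return tiers


_TIER_ORDER = {"tier1": 0, "tier2": 1, "tier3": 2, "untiered": 3}


def prioritization_report(
    per_patient_selected: Mapping[str, Iterable[VariantObservation]],
    k: int = 2,
) -> pd.DataFrame:
    """Gene-level report: patients, mutation count, max CADD, class, best tier.

    Untiered genes (no database flags on any mutation) list last within a
    patient-count level.
    """
    recur = find_recurrent_genes(per_patient_selected, k=k)
    by_gene: Dict[str, List[VariantObservation]] = {}
    for _patient, variants in per_patient_selected.items():
        for v in variants:
            if v.gene.strip():
                by_gene.setdefault(v.gene.strip(), []).append(v)
    rows = []
    for rep in recur:
        vs = by_gene[rep.gene]
        cadds = [v.cadd for v in vs if v.cadd is not None]
        max_cadd = max(cadds) if cadds else None
        tiers = flag_database_presence(vs)
        best_tier = min(tiers, key=lambda t: _TIER_ORDER[t])
        rows.append(
            {
                "gene": rep.gene,
                "patients": ",".join(sorted(rep.patients)),
                "n_patients": len(rep.patients),
                "n_mutations": rep.n_mutations,
                "recurrent": rep.recurrent,
                "max_cadd": max_cadd,
                "cadd_class": classify_cadd(max_cadd),
                "tier": best_tier,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "gene",
            "patients",
            "n_patients",
            "n_mutations",
            "recurrent",
            "max_cadd",
            "cadd_class",
            "tier",
        ],
    )
    if not df.empty:
        df["_tier_rank"] = df["tier"].map(_TIER_ORDER)
        df = (
            df.sort_values(
                ["n_patients", "_tier_rank", "gene"], ascending=[False, True, True]
            )
            .drop(columns="_tier_rank")
            .reset_index(drop=True)
        )
    return df
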