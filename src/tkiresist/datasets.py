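"""Packaged cohort tables and loaders.

Three small TSV fixtures ship with the package, transcribed from the
published cohort of 38 afatinib-treated NSCLC patients:

* ``table1`` — EGFR mutation-status counts per biopsy timepoint (first
  biopsy, pre-afatinib, post-afatinib, WES subset);
* ``table2`` — patient characteristics split by T790M status, including the
  prior-TKI rows used for the erlotinib/gefitinib T790M comparison;
* ``table3`` — the 28 recurrent resistance-specific mutations in 6 genes
  found across the three patients with full normal/pre/post trios.
"""

from __future__ import annotations

from importlib import resources
from typing import List, Optional

import numpy as np
import pandas as pd

from .cohort import CohortRecord
from .variants import VariantObservation, _parse_optional_float


def _load(name: str) -> pd.DataFrame:
    ref = resources.files("tkiresist.data").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", keep_default_na=False)


def load_table1() -> pd.DataFrame:
    """EGFR mutation-status counts per biopsy column."""
    df = _load("table1_egfr_status.tsv")
    for c in ("egfr_activating", "t790m", "first_biopsy", "pre_afatinib", "post_afatinib", "wes"):
        df[c] = df[c].astype(int)
    return df


def load_table2() -> pd.DataFrame:
    """Patient characteristics by T790M status."""
    df = _load("table2_characteristics.tsv")
    for c in ("t790m_positive", "t790m_negative"):
        df[c] = df[c].astype(int)
    return df


def load_table3() -> pd.DataFrame:
    """Recurrent mutations (gene, patient, locus, amino-acid change, CADD)."""
    df = _load("table3_recurrent_mutations.tsv")
    df["pos"] = df["pos"].astype(int)
    df["cadd"] = [_parse_optional_float(x) for x in df["cadd"]]
    return df


def table3_variants(df: Optional[pd.DataFrame] = None) -> List[dict]:
    """Table-3 rows as dicts with a VariantObservation-compatible shape.

    Read counts are not printed in the source table, so each row carries
    only locus, gene, amino-acid change and CADD score, keyed by patient.
    """
    if df is None:
        df = load_table3()
    rows = []
    for r in df.itertuples(index=False):
        cadd = None if pd.isna(r.cadd) else float(r.cadd)
        rows.append(
            {
                "patient": r.patient,
                "obs": VariantObservation(
                    chrom=str(r.chrom),
                    pos=int(r.pos),
                    ref=r.ref,
                    alt=r.alt,
                    gene=r.gene,
                    aa_change=r.aa_change,
                    total_reads=0,
                    mutant_reads=0,
                    cadd=cadd,
                ),
            }
        )
    return rows


def records_from_table1(df: Optional[pd.DataFrame] = None, column: str = "pre_afatinib") -> List[CohortRecord]:
    """Expand one count column of table 1 into per-patient records.

    Only patients with a known activating EGFR mutation get a defined T790M
    flag; wild-type / untested rows yield records with ``t790m=None`` so the
    T790M denominator counts EGFR-positive patients only.
    """
    if df is None:
        df = load_table1()
    records = []
    i = 0
    for row in df.itertuples(index=False):
        for _ in range(int(getattr(row, column))):
            i += 1
            activating = bool(row.egfr_activating)
            records.append(
                CohortRecord(
                    patient_id=f"{column}_{i:03d}",
                    egfr_status=row.category if activating else "",
                    t790m=bool(row.t790m) if activating else None,
                )
            )
    return records


def records_from_table2(df: Optional[pd.DataFrame] = None) -> List[CohortRecord]:
    """Expand the prior-TKI rows of table 2 into per-patient records.

    All patients in this table carry an activating EGFR mutation with known
    T790M status (it defines the columns).
    """
    if df is None:
        df = load_table2()
    tki_rows = df[df["characteristic"] == "EGFR TKI before afatinib"]
    tki_map = {"erlotinib": "erlotinib", "gefitinib": "gefitinib", "both subsequently": "both"}
    records = []
    i = 0
    for row in tki_rows.itertuples(index=False):
        for t790m, n in ((True, row.t790m_positive), (False, row.t790m_negative)):
            for _ in range(int(n)):
                i += 1
                records.append(
                    CohortRecord(
                        patient_id=f"t2_{i:03d}",
                        egfr_status="activating",
                        t790m=t790m,
                        prior_tki=tki_map[row.category],
                    )
                )
    return records
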