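"""Per-sample variant observations and their alignment into per-patient sets.

A variant is identified by its key ``(chrom, pos, ref, alt)`` with 1-based
positions (VCF convention). Each patient carries observations of a variant in
up to three sample roles:

* ``N`` — paired normal tissue or blood (always required downstream),
* ``P`` — pre-treatment ("primary") tumor biopsy,
* ``R`` — post-treatment ("resistant") tumor biopsy.

The central per-sample statistic is the mutant read frequency (MRF): mutant
reads divided by total reads at the variant position. MRF is undefined when
the total read count is zero; it is never silently coerced to 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import pandas as pd

VariantKey = Tuple[str, int, str, str]

ROLES = ("N", "P", "R")

#: Column order of the flat TSV variant-table dialect.
TSV_COLUMNS = [
    "patient",
    "role",
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "aa_change",
    "total_reads",
    "mutant_reads",
    "mq",
    "qual",
    "cadd",
    "in_exac",
    "in_cosmic",
]


class VariantFormatError(ValueError):
    """Raised when an input variant table violates the format contract."""


@dataclass
class VariantObservation:
    """One variant observed in one sample.

    ``cadd``, ``impact``, ``in_exac`` and ``in_cosmic`` are annotations that
    may be missing (``None``); missing is distinct from 0/False so that
    prioritization can never promote unannotated variants.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    total_reads: int
    mutant_reads: int
    gene: str = ""
    aa_change: str = ""
    mq: Optional[float] = None
    qual: Optional[float] = None
    cadd: Optional[float] = None
    impact: Optional[str] = None
    in_exac: Optional[bool] = None
    in_cosmic: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt alleles must be non-empty")
        if self.total_reads < 0 or self.mutant_reads < 0:
            raise ValueError("read counts must be non-negative")
        if self.mutant_reads > self.total_reads:
            raise ValueError(
                f"mutant_reads ({self.mutant_reads}) exceeds total_reads "
                f"({self.total_reads}) at {self.chrom}:{self.pos}"
            )

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class Mrf:
    """Mutant read frequency; ``defined`` is False when total reads are 0."""

    value: float
    defined: bool = True

    def __float__(self) -> float:
        return self.value if self.defined else math.nan


def compute_mrf(obs: VariantObservation) -> Mrf:
    """Mutant read frequency of one observation: mutant / total reads."""
    if obs.total_reads == 0:
        return Mrf(0.0, defined=False)
    return Mrf(obs.mutant_reads / obs.total_reads, defined=True)


@dataclass
class PatientVariantSet:
    """A patient's variants aligned across sample roles N, P and R.

    Observations are keyed by ``(variant key, role)``; a variant key appears
    at most once per role.
    """

    patient_id: str
    observations: Dict[Tuple[VariantKey, str], VariantObservation] = field(
        default_factory=dict
    )

    def add(self, role: str, obs: VariantObservation) -> None:
        if role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {role!r}")
        slot = (obs.key, role)
        if slot in self.observations:
            raise ValueError(
                f"duplicate observation for {obs.key} in role {role} "
                f"of patient {self.patient_id}"
            )
        self.observations[slot] = obs

    def get(self, key: VariantKey, role: str) -> Optional[VariantObservation]:
        return self.observations.get((key, role))

    def has_role(self, role: str) -> bool:
        return any(r == role for (_, r) in self.observations)

    def keys_in_role(self, role: str) -> List[VariantKey]:
        return [k for (k, r) in self.observations if r == role]

    def variant_keys(self) -> List[VariantKey]:
        """All distinct variant keys, in first-seen order."""
        seen: Dict[VariantKey, None] = {}
        for (k, _r) in self.observations:
            seen.setdefault(k)
        return list(seen)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _parse_optional_bool(x) -> Optional[bool]:
    if x is None or (isinstance(x, float) and math.isnan(x)) or x == "":
        return None
    if isinstance(x, bool):
        return x
    s = str(x).strip().lower()
    if s in {"1", "true", "t", "yes"}:
        return True
    if s in {"0", "false", "f", "no"}:
        return False
    raise VariantFormatError(f"cannot interpret {x!r} as a boolean flag")


def _parse_optional_float(x) -> Optional[float]:
    if x is None or x == "" or (isinstance(x, float) and math.isnan(x)):
        return None
    s = str(x).strip()
    if s.upper() in {"NA", "NAN", "."}:
        return None
    return float(s)


def read_variant_table(path, format: str = "tsv") -> List[VariantObservation]:
    """Read variant observations from a flat TSV table or a VCF file.

    The TSV dialect is the one written by :func:`write_variant_table`
    (columns ``patient role chrom pos ref alt gene aa_change total_reads
    mutant_reads mq qual cadd in_exac in_cosmic``). VCF records must carry a
    per-sample allele-depth (AD) field; multi-allelic records are split into
    one observation per alternate allele, with the total read count taken as
    the sum over all AD entries.
    """
    path = Path(path)
    if format == "tsv":
        return _read_tsv(path)
    if format == "vcf":
        return _read_vcf(path)
    raise VariantFormatError(f"unknown variant-table format: {format!r}")


def _read_tsv(path: Path) -> List[VariantObservation]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in TSV_COLUMNS if c not in df.columns and c not in ("patient", "role")]
    if missing:
        raise VariantFormatError(f"{path}: missing columns {missing}")
    out: List[VariantObservation] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 header line
        d = row._asdict()
        try:
            obs = VariantObservation(
                chrom=str(d["chrom"]),
                pos=int(d["pos"]),
                ref=str(d["ref"]),
                alt=str(d["alt"]),
                gene=str(d.get("gene", "")),
                aa_change=str(d.get("aa_change", "")),
                total_reads=int(d["total_reads"]),
                mutant_reads=int(d["mutant_reads"]),
                mq=_parse_optional_float(d.get("mq")),
                qual=_parse_optional_float(d.get("qual")),
                cadd=_parse_optional_float(d.get("cadd")),
                in_exac=_parse_optional_bool(d.get("in_exac")),
                in_cosmic=_parse_optional_bool(d.get("in_cosmic")),
            )
        except ValueError as exc:
            raise VariantFormatError(f"{path}: line {i}: {exc}") from exc
        out.append(obs)
    return out


def _read_vcf(path: Path) -> List[VariantObservation]:
    from cyvcf2 import VCF

    out: List[VariantObservation] = []
    vcf = VCF(str(path))
    try:
        for rec in vcf:
            ad = rec.format("AD")
            if ad is None:
                raise VariantFormatError(
                    f"{path}: record {rec.CHROM}:{rec.POS} lacks an AD field"
                )
            depths = [int(x) for x in ad[0] if int(x) >= 0]
            total = sum(depths)
            gene = rec.INFO.get("GENE") or ""
            aa = rec.INFO.get("AA") or ""
            mq = rec.INFO.get("MQ")
            for j, alt in enumerate(rec.ALT):
                mutant = depths[j + 1] if j + 1 < len(depths) else 0
                try:
                    out.append(
                        VariantObservation(
                            chrom=rec.CHROM,
                            pos=rec.POS,
                            ref=rec.REF,
                            alt=alt,
                            gene=str(gene),
                            aa_change=str(aa),
                            total_reads=total,
                            mutant_reads=mutant,
                            mq=float(mq) if mq is not None else None,
                            qual=float(rec.QUAL) if rec.QUAL is not None else None,
                        )
                    )
                except ValueError as exc:
                    raise VariantFormatError(
                        f"{path}: record {rec.CHROM}:{rec.POS}: {exc}"
                    ) from exc
    finally:
        vcf.close()
    return out


def _fmt_opt(x) -> str:
    if x is None:
        return ""
    if isinstance(x, bool):
        return "1" if x else "0"
    return f"{x:g}" if isinstance(x, float) else str(x)


def write_variant_table(
    observations: Iterable[VariantObservation],
    path,
    patient: str = "",
    role: str = "",
) -> None:
    """Write observations in the flat TSV dialect (lossless round trip)."""
    rows = []
    for obs in observations:
        rows.append(
            {
                "patient": patient,
                "role": role,
                "chrom": obs.chrom,
                "pos": obs.pos,
                "ref": obs.ref,
                "alt": obs.alt,
                "gene": obs.gene,
                "aa_change": obs.aa_change,
                "total_reads": obs.total_reads,
                "mutant_reads": obs.mutant_reads,
                "mq": _fmt_opt(obs.mq),
                "qual": _fmt_opt(obs.qual),
                "cadd": _fmt_opt(obs.cadd),
                "in_exac": _fmt_opt(obs.in_exac),
                "in_cosmic": _fmt_opt(obs.in_cosmic),
            }
        )
    df = pd.DataFrame(rows, columns=TSV_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def write_vcf(observations: Iterable[VariantObservation], path, sample: str = "SAMPLE") -> None:
    """Write observations as a minimal VCF 4.2 file with per-sample AD.

    The AD field follows the ref,alt convention: total = ref depth + alt
    depth, so a record written from (total 50, mutant 5) carries ``45,5``.
    """
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
        '##INFO=<ID=AA,Number=1,Type=String,Description="Amino-acid change">',
        '##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}",
    ]
    for obs in observations:
        info_parts = []
        if obs.gene:
            info_parts.append(f"GENE={obs.gene}")
        if obs.aa_change:
            info_parts.append(f"AA={obs.aa_change}")
        if obs.mq is not None:
            info_parts.append(f"MQ={obs.mq:g}")
        info = ";".join(info_parts) or "."
        qual = f"{obs.qual:g}" if obs.qual is not None else "."
        ad = f"{obs.total_reads - obs.mutant_reads},{obs.mutant_reads}"
        lines.append(
            f"{obs.chrom}\t{obs.pos}\t.\t{obs.ref}\t{obs.alt}\t{qual}\t.\t{info}\tAD\t{ad}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def attach_annotations(
    variants: Iterable[VariantObservation],
    annotations: pd.DataFrame,
) -> List[VariantObservation]:
    """Attach cadd / in_exac / in_cosmic columns keyed by (chrom, pos, ref, alt).

    Unmatched variants keep their missing flags; no variant is ever dropped.
    Duplicate annotation keys are an error.
    """
    variants = list(variants)
    if annotations.empty:
        return [replace(v) for v in variants]
    keyed: Dict[VariantKey, Mapping] = {}
    for row in annotations.itertuples(index=False):
        d = row._asdict()
        key = (str(d["chrom"]), int(d["pos"]), str(d["ref"]), str(d["alt"]))
        if key in keyed:
            raise ValueError(f"duplicate annotation key {key}")
        keyed[key] = d
    out = []
    for v in variants:
        d = keyed.get(v.key)
        if d is None:
            out.append(replace(v))
            continue
        out.append(
            replace(
                v,
                cadd=_parse_optional_float(d.get("cadd")) if "cadd" in d else v.cadd,
                in_exac=_parse_optional_bool(d.get("in_exac")) if "in_exac" in d else v.in_exac,
                in_cosmic=_parse_optional_bool(d.get("in_cosmic")) if "in_cosmic" in d else v.in_cosmic,
            )
        )
    return out
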