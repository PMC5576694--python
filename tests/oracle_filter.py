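"""Independent straight-line re-implementation of the filter cascade.

Deliberately written as one flat function over plain dict rows, with the
published rules transcribed literally, so it shares no code path with
``tkiresist.filtering``. Used as the oracle in equivalence tests.
"""

import numpy as np

from tkiresist.variants import PatientVariantSet, VariantObservation


def oracle_outcomes(rows_by_role, strategy):
    """Map variant key -> outcome, given {role: {key: (total, mutant, mq, qual)}}."""
    n_tab = rows_by_role.get("N", {})
    p_tab = rows_by_role.get("P", {})
    r_tab = rows_by_role.get("R", {})
    universe = list(dict.fromkeys(list(p_tab) + list(r_tab)))
    out = {}
    for key in universe:
        nt, nm = (n_tab[key][0], n_tab[key][1]) if key in n_tab else (0, 0)
        if nt < 10:
            out[key] = "removed_step1"
            continue
        if (nm >= 2 and 10 <= nt <= 49) or (nm >= 3 and nt >= 50):
            out[key] = "removed_germline"
            continue
        if strategy == "B":
            if key not in p_tab or key not in r_tab or p_tab[key][0] < 10 or r_tab[key][0] < 10:
                out[key] = "removed_step4"
                continue
            mrf_p = p_tab[key][1] / p_tab[key][0]
            mrf_r = r_tab[key][1] / r_tab[key][0]
            hit = mrf_r > 2 * mrf_p
        else:
            if key not in r_tab or r_tab[key][0] < 10:
                out[key] = "removed_step4"
                continue
            hit = r_tab[key][1] / r_tab[key][0] > 0
        if not hit:
            out[key] = "not_selected"
            continue
        mq, qual = r_tab[key][2], r_tab[key][3]
        out[key] = "selected" if (mq > 20 and qual > 20) else "removed_quality"
    return out


def random_patient_table(rng: np.random.Generator, n_variants: int, patient_id="RND"):
    """A random paired table straddling every threshold of the cascade.

    Returns (PatientVariantSet, rows_by_role) where rows_by_role feeds the
    oracle. Roles are dropped at random so missing-observation paths are
    exercised; counts concentrate around the 10/49/50 depth boundaries and
    MQ/QUAL around 20.
    """
    pset = PatientVariantSet(patient_id=patient_id)
    rows_by_role = {"N": {}, "P": {}, "R": {}}
    for i in range(n_variants):
        key = ("1", i + 1, "A", "T")
        for role in ("N", "P", "R"):
            if rng.random() < 0.12:  # missing observation
                continue
            total = int(rng.choice([0, 5, 9, 10, 11, 30, 49, 50, 51, 100]))
            mutant = int(rng.integers(0, total + 1)) if total else 0
            mq = float(rng.choice([10.0, 20.0, 20.5, 21.0, 60.0]))
            qual = float(rng.choice([5.0, 19.0, 20.0, 21.0, 99.0]))
            rows_by_role[role][key] = (total, mutant, mq, qual)
            pset.add(
                role,
                VariantObservation(
                    chrom=key[0], pos=key[1], ref=key[2], alt=key[3],
                    gene=f"G{i}", total_reads=total, mutant_reads=mutant,
                    mq=mq, qual=qual,
                ),
            )
    return pset, rows_by_role
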