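"""Applicability domain via statistical defects of attribute keys.

An attribute that appears with very different relative frequency in the
training and test sets is statistically "defective": a model calibrated on
the training set cannot be trusted to extrapolate through it.  The defect of
a key is

    d(key) = |P_tr(key) − P_te(key)| / (N_tr(key) + N_te(key)),

where P is the fraction of molecules in the set containing the key and N the
number of such molecules.  A molecule's defect D is the sum of d over its
attribute occurrences; the molecule is inside the applicability domain when
D is below twice the mean training-set defect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import AttributeKey, AttributeProfile


@dataclass
class DefectTable:
    defects: dict[AttributeKey, float]
    threshold: float
    mean_training_defect: float
    multiplier: float = 2.0

    def molecule_defect(self, profile: AttributeProfile) -> float:
        return sum(
            count * self.defects.get(key, 0.0)
            for key, count in profile.counts.items()
        )


def _presence_counts(profiles: list[AttributeProfile]) -> dict[AttributeKey, int]:
    counts: dict[AttributeKey, int] = {}
    for prof in profiles:
        for key in prof.keys():
            counts[key] = counts.get(key, 0) + 1
    return counts


def attribute_defects(
    training: list[AttributeProfile],
    test: list[AttributeProfile],
    multiplier: float = 2.0,
    per_occurrence: bool = False,
) -> DefectTable:
    """Build the defect table and the 2×mean-training-defect threshold.

    ``per_occurrence=True`` switches P and N from per-molecule presence to
    raw occurrence counts (an alternative convention; off by default).
    """
    if not training or not test:
        raise ValueError("both sets must be non-empty")

    if per_occurrence:
        n_tr = {k: 0 for p in training for k in p.keys()}
        n_te = {k: 0 for p in test for k in p.keys()}
        tot_tr = sum(p.total() for p in training)
        tot_te = sum(p.total() for p in test)
        for p in training:
            for k, c in p.counts.items():
                n_tr[k] += c
        for p in test:
            for k, c in p.counts.items():
                n_te[k] += c
    else:
        n_tr = _presence_counts(training)
        n_te = _presence_counts(test)
        tot_tr = len(training)
        tot_te = len(test)

    defects: dict[AttributeKey, float] = {}
    for key in set(n_tr) | set(n_te):
        a = n_tr.get(key, 0)
        b = n_te.get(key, 0)
        p_tr = a / tot_tr
        p_te = b / tot_te
        defects[key] = abs(p_tr - p_te) / (a + b)

    table = DefectTable(defects, threshold=0.0, mean_training_defect=0.0,
                        multiplier=multiplier)
    train_d = [table.molecule_defect(p) for p in training]
    table.mean_training_defect = float(np.mean(train_d))
    table.threshold = multiplier * table.mean_training_defect
    return table


def in_domain(
    profile: AttributeProfile, table: DefectTable
) -> tuple[bool, float]:
    """(membership, molecule defect D).

    In domain iff D < threshold; when the threshold is exactly 0 a defect of
    0 still counts as inside (the ≤-at-zero convention).
    """
    D = table.molecule_defect(profile)
    if table.threshold == 0.0:
        return D == 0.0, D
    return D < table.threshold, D


def domain_report(
    training: list[AttributeProfile],
    test: list[AttributeProfile],
    multiplier: float = 2.0,
) -> list[dict]:
    """Per-molecule AD table (id, D, threshold, membership) for both sets."""
    table = attribute_defects(training, test, multiplier=multiplier)
    rows = []
    for set_name, profs in (("training", training), ("test", test)):
        for prof in profs:
            ok, D = in_domain(prof, table)
            rows.append({
                "id": prof.molecule_id, "set": set_name, "D": D,
                "threshold": table.threshold, "in_domain": ok,
            })
    return rows
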