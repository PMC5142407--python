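"""Deviation of Ala-X pair free energies from ideal additivity.

If residue contributions were strictly additive, the free energy of an Ala-X
dipeptide would equal dG_Ala + dG_X. The signed difference
(ideal sum - measured pair value) quantifies the hydrophobic coupling between
neighbours; a Tukey boxplot screen removes pairs whose MD values the additive
picture cannot capture at all, and from the remainder the pair with the
largest absolute deviation represents same-hydropathy coupling while the
smallest represents mixed (head-tail) coupling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import EmptyDatasetError, PepGCMError
from .parameters import ParameterSet


@dataclass(frozen=True)
class DeviationRecord:
    partner: str
    ideal_sum: float  # kJ/mol: dG_Ala + dG_partner
    dg_pair: float  # kJ/mol, measured
    deviation: float  # kJ/mol: ideal_sum - dg_pair
    outlier: bool = False


def ideality_deviation(params: ParameterSet, partner: str) -> float:
    """(dG_Ala + dG_partner) - dG_pair(Ala-partner), kJ/mol."""
    pair = params.dg_pair(partner)  # unknown partner -> ParameterError
    return (params.dg("A") + params.dg(partner)) - pair


def deviation_table(params: ParameterSet, fence_k: float = 1.5) -> list[DeviationRecord]:
    """All twenty pair deviations, ascending, with Tukey outliers flagged."""
    records = []
    for partner in params.pairs:
        ideal = params.dg("A") + params.dg(partner)
        pair = params.dg_pair(partner)
        records.append(
            DeviationRecord(partner=partner, ideal_sum=ideal, dg_pair=pair, deviation=ideal - pair)
        )
    records.sort(key=lambda r: (r.deviation, r.partner))
    flagged = tukey_outliers([r.deviation for r in records], k=fence_k)
    return [
        DeviationRecord(r.partner, r.ideal_sum, r.dg_pair, r.deviation, outlier=(i in flagged))
        for i, r in enumerate(records)
    ]


def _hinges(values: np.ndarray) -> tuple[float, float]:
    """Tukey hinges: medians of the lower/upper halves, the overall median
    shared by both halves when n is odd."""
    x = np.sort(values)
    n = x.size
    half = (n + 1) // 2  # include median in both halves for odd n
    return float(np.median(x[:half])), float(np.median(x[n - half:]))


def tukey_outliers(values: Sequence[float], k: float = 1.5) -> set[int]:
    """Indices of values outside the boxplot fences [Q1 - k*IQR, Q3 + k*IQR].

    Quartiles are Tukey hinges, matching what a boxplot draws. Requires at
    least four values and a positive fence multiplier ``k``.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise EmptyDatasetError(f"Tukey screen needs at least 4 values, got {x.size}")
    if not k > 0:
        raise PepGCMError(f"fence multiplier k must be positive, got {k}")
    if np.isinf(k):  # infinite fences admit everything, even when IQR == 0
        return set()
    q1, q3 = _hinges(x)
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    return {i for i, v in enumerate(x) if v < lo or v > hi}


def representative_pairs(records: Sequence[DeviationRecord]) -> tuple[str, str]:
    """(same-hydropathy representative, mixed representative).

    The first partner carries the largest |deviation| of the record set, the
    second the smallest; alphabetical partner code breaks exact ties.
    """
    if not records:
        raise EmptyDatasetError("representative_pairs() needs at least one record")
    largest = min(records, key=lambda r: (-abs(r.deviation), r.partner))
    smallest = min(records, key=lambda r: (abs(r.deviation), r.partner))
    return largest.partner, smallest.partner
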