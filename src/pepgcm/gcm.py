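"""Group-contribution prediction of peptide interface free energies.

The model estimates the Gibbs free-energy change of inserting a peptide at
the dodecane-water interface from sequence alone:

    dG_molecule = sum_i sum_j n_(i,j) * dG_i / alpha_(i,j)

where i runs over the twenty amino acids, j over the neighbour classes C1/C2,
n_(i,j) counts residues of type i in class j, dG_i is the MD-derived
single-residue contribution and alpha_(i,j) a fitted scale factor. An
optional folding correction (slope * r - intercept, kJ/mol) is applied when
the Pearson correlation r between residue position and the per-residue turn
propensity exceeds a threshold -- a sequence whose turn-prone residues
cluster toward one end is taken as likely to fold back on itself, which the
purely additive model cannot capture.

Two evaluation modes are exposed. ``as_printed`` divides by alpha, the
published form of the model, and is the default; ``reciprocal`` multiplies
by alpha/100, kept as an alternative convention (the two coincide under the
substitution alpha' = 100/alpha).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .classification import ResidueClassification, classify_residues, normalize_sequence
from .errors import DomainError, EmptyDatasetError, SequenceTooShortError, UnknownResidueError
from .parameters import ModelConstants, ParameterSet

MODES = ("as_printed", "reciprocal")
CORRECTION_SIGNS = ("add", "subtract", "off")


@dataclass(frozen=True)
class PredictionResult:
    """Fully decomposed model output for one peptide."""

    sequence: str
    classification: ResidueClassification
    additive_sum: float  # kJ/mol, ideal-linear baseline sum of dG_i
    gcm_energy: float  # kJ/mol, class-weighted model sum
    mode: str
    pearson_r: float
    folding_correction: float  # kJ/mol, >= 0
    correction_sign: str  # add | subtract | off
    final_energy: float  # kJ/mol


@dataclass(frozen=True)
class ValidationRecord:
    peptide_id: str
    sequence: str | None
    dg_simulated: float
    dg_calculated: float
    relative_error_pct: float


@dataclass(frozen=True)
class ValidationReport:
    records: tuple[ValidationRecord, ...]
    mean_error_pct: float
    min_error_pct: float
    max_error_pct: float


def additive_sum(params: ParameterSet, sequence: str) -> float:
    """Ideal-linear baseline: plain sum of per-residue contributions, kJ/mol."""
    seq = normalize_sequence(sequence)
    if not seq:
        raise SequenceTooShortError("empty sequence")
    total = 0.0
    for pos, code in enumerate(seq):
        if code not in params.residues:
            raise UnknownResidueError(code, position=pos)
        total += params.dg(code)
    return total


def gcm_energy(
    params: ParameterSet,
    classification: ResidueClassification,
    mode: str = "as_printed",
) -> float:
    """Evaluate the class-weighted group-contribution sum from counts, kJ/mol."""
    if mode not in MODES:
        raise DomainError(f"mode must be one of {MODES}, got {mode!r}")
    total = 0.0
    for (code, cls), n in classification.counts.items():
        dg = params.dg(code)
        a = params.alpha(code, cls)
        total += n * dg / a if mode == "as_printed" else n * dg * a / 100.0
    return total


def turn_position_correlation(params: ParameterSet, sequence: str) -> float:
    """Pearson correlation between residue position (1..n) and turn propensity.

    Returns 0.0 by convention when the propensity vector has zero variance
    (e.g. any homopolymer).
    """
    seq = normalize_sequence(sequence)
    if len(seq) < 2:
        raise SequenceTooShortError(f"need at least 2 residues, got {len(seq)}")
    props = []
    for pos, code in enumerate(seq):
        if code not in params.residues:
            raise UnknownResidueError(code, position=pos)
        props.append(params.turn_propensity(code))
    y = np.asarray(props, dtype=float)
    if np.ptp(y) == 0.0:
        return 0.0
    x = np.arange(1, len(seq) + 1, dtype=float)
    r = float(np.corrcoef(x, y)[0, 1])
    return max(-1.0, min(1.0, r))


def folding_correction(constants: ModelConstants, r: float) -> float:
    """Correction magnitude (kJ/mol): slope*r - intercept when r exceeds the
    threshold, else 0. Always positive on the applied branch because
    slope*threshold exceeds the intercept."""
    if abs(r) > 1.0 + 1e-12:
        raise DomainError(f"Pearson correlation must lie in [-1, 1], got {r}")
    if r <= constants.pearson_threshold:
        return 0.0
    return constants.correction_slope * r - constants.correction_intercept


def predict(
    params: ParameterSet,
    sequence: str,
    mode: str = "as_printed",
    correction_sign: str = "subtract",
) -> PredictionResult:
    """Full prediction pipeline for one peptide.

    Classifies residues, evaluates the group-contribution sum, computes the
    position/turn-propensity correlation and applies the folding correction
    according to ``correction_sign`` ('add', 'subtract' or 'off').
    """
    if correction_sign not in CORRECTION_SIGNS:
        raise DomainError(f"correction_sign must be one of {CORRECTION_SIGNS}, got {correction_sign!r}")
    cls = classify_residues(params, sequence)
    energy = gcm_energy(params, cls, mode=mode)
    r = turn_position_correlation(params, cls.sequence)
    corr = 0.0 if correction_sign == "off" else folding_correction(params.constants, r)
    if correction_sign == "add":
        final = energy + corr
    elif correction_sign == "subtract":
        final = energy - corr
    else:
        final = energy
    return PredictionResult(
        sequence=cls.sequence,
        classification=cls,
        additive_sum=additive_sum(params, cls.sequence),
        gcm_energy=energy,
        mode=mode,
        pearson_r=r,
        folding_correction=corr,
        correction_sign=correction_sign,
        final_energy=final,
    )


def relative_error(dg_simulated: float, dg_calculated: float) -> float:
    """Magnitude of the relative deviation between simulated and calculated
    free energies, in percent."""
    if dg_simulated == 0:
        raise DomainError("relative error undefined for dg_simulated == 0")
    return abs((dg_simulated - dg_calculated) / dg_simulated) * 100.0


def validate(records: Iterable[tuple[str, float, float] | tuple[str, str | None, float, float]]) -> ValidationReport:
    """Per-record relative errors plus mean/min/max summary.

    Accepts (id, dg_simulated, dg_calculated) triples or
    (id, sequence, dg_simulated, dg_calculated) quadruples.
    """
    out: list[ValidationRecord] = []
    for rec in records:
        if len(rec) == 3:
            pid, sim, calc = rec
            seq = None
        else:
            pid, seq, sim, calc = rec
        out.append(
            ValidationRecord(
                peptide_id=str(pid),
                sequence=seq,
                dg_simulated=float(sim),
                dg_calculated=float(calc),
                relative_error_pct=relative_error(float(sim), float(calc)),
            )
        )
    if not out:
        raise EmptyDatasetError("validate() needs at least one record")
    errs = [r.relative_error_pct for r in out]
    return ValidationReport(
        records=tuple(out),
        mean_error_pct=float(np.mean(errs)),
        min_error_pct=float(np.min(errs)),
        max_error_pct=float(np.max(errs)),
    )


def round_half_up(value: float, decimals: int = 0) -> float:
    """Decimal-style rounding used for report display (13.45 -> 13.5)."""
    factor = 10.0 ** decimals
    return math.floor(value * factor + 0.5) / factor
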