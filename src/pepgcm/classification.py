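"""Neighbour-based residue classification.

Each residue of a peptide is labelled C1 when the *following* residue shares
its binary hydropathy (nonpolar/polar) and C2 when it does not. The last
residue has no follower and is coupled backwards: it takes C1 when it matches
its predecessor, C2 otherwise. The class vector therefore depends only on
the hydropathy sequence, never on residue identities beyond their partition
membership.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping

from .errors import SequenceTooShortError, UnknownResidueError
from .parameters import ParameterSet


@dataclass(frozen=True)
class ResidueClassification:
    """Per-position C1/C2 labels and the (residue, class) occupation counts."""

    sequence: str
    classes: tuple[str, ...]
    counts: Mapping[tuple[str, str], int]

    def __post_init__(self):
        assert len(self.classes) == len(self.sequence)
        assert sum(self.counts.values()) == len(self.sequence)


def normalize_sequence(sequence: str) -> str:
    """Upper-case and strip whitespace (incl. internal) from a raw sequence."""
    return "".join(sequence.split()).upper()


def hydropathy(params: ParameterSet, code: str) -> str:
    """Binary hydropathy label ('nonpolar' or 'polar') of one residue."""
    return params.hydropathy(code)


def classify_residues(params: ParameterSet, sequence: str) -> ResidueClassification:
    """Assign C1/C2 to every residue of ``sequence``.

    Raises
    ------
    SequenceTooShortError
        For sequences shorter than two residues (the rule needs a neighbour).
    UnknownResidueError
        For symbols outside the parameter table, reported with position.
    """
    seq = normalize_sequence(sequence)
    if len(seq) < 2:
        raise SequenceTooShortError(
            f"need at least 2 residues to classify, got {len(seq)}"
        )
    labels = []
    for pos, code in enumerate(seq):
        if code not in params.residues:
            raise UnknownResidueError(code, position=pos)
        labels.append(params.hydropathy(code))

    classes = [
        "C1" if labels[k] == labels[k + 1] else "C2" for k in range(len(seq) - 1)
    ]
    # backward coupling of the final residue
    classes.append("C1" if labels[-1] == labels[-2] else "C2")

    counts = Counter(zip(seq, classes))
    return ResidueClassification(sequence=seq, classes=tuple(classes), counts=dict(counts))
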