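"""Propensity-based prediction of ligand-interacting residues.

Each position of a query sequence receives the propensity score of its
residue type for the chosen ligand; the 0-9 normalized score, rounded
half-up to an integer digit, forms a digit track displayed under the
sequence.  High-digit regions are the candidate interaction regions;
thresholding the digits yields binary calls which can be scored against
known site labels (per-residue accuracy, sensitivity, specificity).

Positions with the unknown residue 'X' score zero, are flagged, and are
excluded from evaluation counts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .amino_acids import AA_INDEX, AA_ORDER, UNKNOWN
from .site_statistics import PropensityTable

DEFAULT_THRESHOLD = 5


@dataclass
class PredictionTrack:
    sequence: str
    raw_scores: np.ndarray     # RP per position, percent scale
    digit_scores: np.ndarray   # round(NP) per position, ints 0..9
    unknown_mask: np.ndarray   # True where residue is X
    ligand_code: str = ""
    calls: np.ndarray | None = None
    threshold: int | None = None

    def __len__(self) -> int:
        return len(self.sequence)

    def digit_string(self) -> str:
        return "".join(str(int(d)) for d in self.digit_scores)

    def as_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "position": np.arange(1, len(self.sequence) + 1),
                "residue": list(self.sequence),
                "RP": self.raw_scores,
                "digit": self.digit_scores,
            }
        )
        if self.calls is not None:
            frame["call"] = self.calls.astype(int)
        return frame


@dataclass
class EvaluationReport:
    accuracy: float     # percent
    sensitivity: float  # percent; NaN when no actual positives
    specificity: float  # percent; NaN when no actual negatives
    tp: int
    fp: int
    tn: int
    fn: int
    threshold: int | None = None

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5).astype(int)


def score_sequence(
    sequence: str,
    table: PropensityTable,
    ligand_code: str | None = None,
) -> PredictionTrack:
    """Assign per-position propensity scores and 0-9 digits.

    The score at a position depends only on its residue type: RP from the
    table, digit = half-up-rounded NP.  'X' positions get 0 and a flag.
    """
    if not sequence:
        raise ValueError("empty sequence")
    if table.normalized is None:
        raise ValueError("propensity table must be normalized")
    sequence = sequence.upper()
    raw = np.zeros(len(sequence))
    npv = np.zeros(len(sequence))
    unknown = np.zeros(len(sequence), dtype=bool)
    for j, aa in enumerate(sequence):
        if aa == UNKNOWN:
            unknown[j] = True
        elif aa in AA_INDEX:
            raw[j] = table.values[AA_INDEX[aa]]
            npv[j] = table.normalized[AA_INDEX[aa]]
        else:
            raise ValueError(f"illegal residue {aa!r} at position {j + 1}")
    return PredictionTrack(
        sequence=sequence,
        raw_scores=raw,
        digit_scores=_round_half_up(npv),
        unknown_mask=unknown,
        ligand_code=ligand_code or table.ligand_code,
    )


def predict_binding(track: PredictionTrack, threshold: int = DEFAULT_THRESHOLD) -> PredictionTrack:
    """Binary calls: positive iff digit >= threshold (0-9)."""
    if not 0 <= threshold <= 9:
        raise ValueError("threshold must be a digit 0-9")
    return replace(
        track,
        calls=track.digit_scores >= threshold,
        threshold=threshold,
    )


def evaluate(
    calls: Sequence[bool] | np.ndarray,
    actual_labels: Sequence[bool] | np.ndarray,
    exclude_mask: Sequence[bool] | np.ndarray | None = None,
    threshold: int | None = None,
) -> EvaluationReport:
    """Confusion counts and percent metrics of calls vs known labels.

    ``exclude_mask`` (e.g. a track's ``unknown_mask``) removes positions
    from all counts.
    """
    calls = np.asarray(calls, dtype=bool)
    labels = np.asarray(actual_labels, dtype=bool)
    if calls.shape != labels.shape:
        raise ValueError("calls and labels differ in length")
    if exclude_mask is not None:
        keep = ~np.asarray(exclude_mask, dtype=bool)
        if keep.shape != calls.shape:
            raise ValueError("exclude mask length mismatch")
        calls, labels = calls[keep], labels[keep]
    tp = int((calls & labels).sum())
    fp = int((calls & ~labels).sum())
    tn = int((~calls & ~labels).sum())
    fn = int((~calls & labels).sum())
    total = tp + fp + tn + fn
    accuracy = 100.0 * (tp + tn) / total if total else float("nan")
    sensitivity = 100.0 * tp / (tp + fn) if tp + fn else float("nan")
    specificity = 100.0 * tn / (tn + fp) if tn + fp else float("nan")
    return EvaluationReport(
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        threshold=threshold,
    )


def evaluate_track(track: PredictionTrack, actual_labels) -> EvaluationReport:
    """Evaluate a called track, excluding its unknown ('X') positions."""
    if track.calls is None:
        raise ValueError("track has no calls; run predict_binding first")
    return evaluate(
        track.calls,
        actual_labels,
        exclude_mask=track.unknown_mask,
        threshold=track.threshold,
    )


def format_track(track: PredictionTrack, width: int = 60) -> str:
    """Two-line display: sequence with its digit track underneath."""
    lines = []
    for start in range(0, len(track.sequence), width):
        lines.append(track.sequence[start:start + width])
        lines.append(track.digit_string()[start:start + width])
    return "\n".join(lines)
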