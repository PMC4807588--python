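"""Ligand-specific residue statistics.

Three summaries are computed from a ligand's binding-site counts:

* residue composition ``RC_i = 100 * R_i / N`` where ``N = sum(R)`` — the
  percent share of each amino-acid type among interacting residues;
* residue propensity ``RP_i = 100 * R_i / N_i`` — interacting residues of
  type i relative to all residues of that type in the contributing
  chains, i.e. the per-type contact rate on a percent scale;
* physicochemical-class composition ``PC_i = 100 * P_i / N`` over eight
  overlapping classes (charged, acidic, basic, small, polar, non-polar,
  aromatic, aliphatic).

Propensities are additionally min-max normalized to the digit scale 0-9
(``NP_i = 9 * (RP_i - P_min) / (P_max - P_min)``) and bucketed into
preference categories: low (RP < 5), moderate (5 <= RP <= 12) and high
(RP > 12).
"""

from __future__ import annotations

from collections import namedtuple
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .amino_acids import AA_INDEX, AA_ORDER, PROPERTY_CLASSES, PROPERTY_ORDER
from .errors import DegenerateInputError, InconsistentDatasetError
from .structure_contacts import LigandDataset

CATEGORY_LOW_BELOW = 5.0
CATEGORY_HIGH_ABOVE = 12.0
DIGIT_MAX = 9.0


def _counts_to_array(counts) -> np.ndarray:
    """Accept a 20-vector or a {one-letter: count} mapping."""
    if isinstance(counts, Mapping):
        arr = np.zeros(20, dtype=float)
        for aa, c in counts.items():
            arr[AA_INDEX[aa]] = c
        return arr
    arr = np.asarray(counts, dtype=float)
    if arr.shape != (20,):
        raise ValueError("expected 20 residue counts")
    return arr


@dataclass
class CompositionVector:
    """Percent residue composition RC, 20 entries aligned to AA_ORDER."""

    values: np.ndarray
    ligand_code: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def __getitem__(self, aa: str) -> float:
        return float(self.values[AA_INDEX[aa]])

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(AA_ORDER), name="RC")


@dataclass
class PropensityTable:
    """Residue propensities RP (percent scale) with their normalized 0-9
    companion NP, per-residue preference category and an ``absent`` flag
    for types with no residues in the dataset (N_i = 0, RP forced 0)."""

    values: np.ndarray
    normalized: np.ndarray | None = None
    categories: list[str] = field(default_factory=list)
    absent: np.ndarray | None = None
    ligand_code: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (20,):
            raise ValueError("propensity table needs 20 RP values")
        if self.absent is None:
            self.absent = np.zeros(20, dtype=bool)

    def __getitem__(self, aa: str) -> float:
        return float(self.values[AA_INDEX[aa]])

    def digit(self, aa: str) -> int:
        if self.normalized is None:
            raise ValueError("table not normalized yet")
        return int(np.floor(self.normalized[AA_INDEX[aa]] + 0.5))

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "residue": list(AA_ORDER),
                "RP": self.values,
                "NP": self.normalized,
                "category": self.categories,
                "absent": self.absent,
            }
        )


@dataclass
class PropertyCompositionVector:
    """Percent composition over the 8 physicochemical classes.  Classes
    overlap, so entries need not sum to 100, but acidic + basic = charged
    holds exactly."""

    values: np.ndarray
    ligand_code: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(PROPERTY_ORDER),):
            raise ValueError("expected one entry per property class")

    def __getitem__(self, prop: str) -> float:
        return float(self.values[PROPERTY_ORDER.index(prop)])

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(PROPERTY_ORDER), name="PC")


ReferenceProfile = namedtuple("ReferenceProfile", ["composition", "property_composition"])


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def composition(counts, ligand_code: str = "") -> CompositionVector:
    """Percent composition RC_i = 100 R_i / sum(R) of interacting residues."""
    arr = _counts_to_array(counts)
    if (arr < 0).any():
        raise ValueError("negative counts")
    total = arr.sum()
    if total == 0:
        raise DegenerateInputError("all-zero residue counts")
    return CompositionVector(values=100.0 * arr / total, ligand_code=ligand_code)


def propensity(dataset: LigandDataset) -> PropensityTable:
    """Residue propensities RP_i = 100 R_i / N_i from a ligand dataset.

    Types absent from the dataset (N_i = 0) are given RP 0 and flagged.
    The returned table is already normalized and categorized.
    """
    R = dataset.interacting_counts.astype(float)
    N = dataset.total_counts.astype(float)
    if (R > N).any():
        bad = [AA_ORDER[i] for i in np.nonzero(R > N)[0]]
        raise InconsistentDatasetError(
            f"{dataset.ligand_code}: R_i > N_i for {','.join(bad)}"
        )
    absent = N == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        rp = np.where(absent, 0.0, 100.0 * R / np.where(absent, 1.0, N))
    table = PropensityTable(values=rp, absent=absent, ligand_code=dataset.ligand_code)
    table = normalize_propensity(table)
    table.categories = [categorize(v) for v in table.values]
    return table


def normalize_propensity(table: PropensityTable) -> PropensityTable:
    """Fill NP_i = 9 (RP_i - P_min) / (P_max - P_min); all zero when the
    RP vector is constant (no preference signal to spread)."""
    rp = table.values
    pmin, pmax = float(rp.min()), float(rp.max())
    if pmax == pmin:
        table.normalized = np.zeros(20)
    else:
        table.normalized = DIGIT_MAX * (rp - pmin) / (pmax - pmin)
    return table


def categorize(rp: float) -> str:
    """Preference category for a percent-scale propensity score."""
    if rp < 0:
        raise ValueError("propensity score cannot be negative")
    if rp < CATEGORY_LOW_BELOW:
        return "low"
    if rp <= CATEGORY_HIGH_ABOVE:
        return "moderate"
    return "high"


def property_composition(counts, ligand_code: str = "") -> PropertyCompositionVector:
    """Percent composition PC_i = 100 P_i / N over the 8 property classes."""
    arr = _counts_to_array(counts)
    total = arr.sum()
    if total == 0:
        raise DegenerateInputError("all-zero residue counts")
    values = np.array(
        [
            sum(arr[AA_INDEX[aa]] for aa in PROPERTY_CLASSES[prop])
            for prop in PROPERTY_ORDER
        ]
    )
    return PropertyCompositionVector(values=100.0 * values / total, ligand_code=ligand_code)


def reference_profile(datasets: Iterable[LigandDataset]) -> ReferenceProfile:
    """Pooled 'average ligand' reference (AVR): composition and property
    composition of the element-wise sum of interacting counts."""
    datasets = list(datasets)
    if not datasets:
        raise ValueError("need at least one dataset")
    pooled = np.sum([d.interacting_counts for d in datasets], axis=0)
    return ReferenceProfile(
        composition=composition(pooled, ligand_code="AVR"),
        property_composition=property_composition(pooled, ligand_code="AVR"),
    )


# ---------------------------------------------------------------------------
# tabular export
# ---------------------------------------------------------------------------

def statistics_table(dataset: LigandDataset) -> pd.DataFrame:
    """Per-residue R, N, RC, RP, NP and category for one ligand."""
    comp = composition(dataset.interacting_counts)
    table = propensity(dataset)
    return pd.DataFrame(
        {
            "residue": list(AA_ORDER),
            "R": dataset.interacting_counts,
            "N": dataset.total_counts,
            "RC": comp.values,
            "RP": table.values,
            "NP": table.normalized,
            "category": table.categories,
        }
    )


def property_table(dataset: LigandDataset) -> pd.DataFrame:
    """Per-class interacting count and PC for one ligand."""
    arr = dataset.interacting_counts.astype(float)
    pc = property_composition(arr)
    class_counts = [
        int(sum(arr[AA_INDEX[aa]] for aa in PROPERTY_CLASSES[prop]))
        for prop in PROPERTY_ORDER
    ]
    return pd.DataFrame(
        {"property": list(PROPERTY_ORDER), "P": class_counts, "PC": pc.values}
    )
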