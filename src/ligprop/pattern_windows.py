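"""Sequence windows around (non-)interacting residues, redundancy
filtering and position-wise residue enrichment.

Every sequence position yields one odd-length window (default 21) centred
on it, termini padded with 'X'; windows are partitioned by whether their
central residue is a labelled interacting position.  The two window sets
support logo/motif work: a greedy identity filter builds a non-redundant
chain set, a two-proportion z-test per (position, residue) cell quantifies
neighbourhood preferences (the quantity a two-sample logo displays), and
windows export to FASTA ready for WebLogo/MEME.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import Align, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .amino_acids import AA_ORDER, UNKNOWN

DEFAULT_WINDOW_LENGTH = 21
DEFAULT_IDENTITY_THRESHOLD = 0.30
WINDOW_SYMBOLS = AA_ORDER + UNKNOWN  # 21 columns of the enrichment matrix


@dataclass(frozen=True)
class Window:
    sequence: str
    source_id: str
    chain_id: str
    center: int  # 1-based position in the source sequence
    interacting: bool


@dataclass
class PatternSet:
    window_length: int
    interacting: list[Window]
    non_interacting: list[Window]

    def __len__(self) -> int:
        return len(self.interacting) + len(self.non_interacting)


@dataclass
class EnrichmentMatrix:
    """Per (position, symbol) frequencies in each window set plus the
    two-proportion z statistic and a corrected significance flag.

    Rows are window positions 1..L, columns the 20 amino acids plus 'X'.
    Tests cover the 20 amino-acid columns only (padding is never tested);
    z is NaN in the 'X' column.
    """

    window_length: int
    freq_interacting: np.ndarray   # L x 21
    freq_non_interacting: np.ndarray
    z: np.ndarray
    significant: np.ndarray        # bool, L x 21 ('X' column all False)
    alpha: float
    correction: str

    @property
    def difference(self) -> np.ndarray:
        return self.freq_interacting - self.freq_non_interacting

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for pos in range(self.window_length):
            for s, sym in enumerate(WINDOW_SYMBOLS):
                rows.append(
                    {
                        "position": pos + 1,
                        "residue": sym,
                        "freq_pos": self.freq_interacting[pos, s],
                        "freq_neg": self.freq_non_interacting[pos, s],
                        "diff": self.difference[pos, s],
                        "z": self.z[pos, s],
                        "significant": bool(self.significant[pos, s]),
                    }
                )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# window generation
# ---------------------------------------------------------------------------

def generate_windows(
    sequence: str,
    interacting_positions: Iterable[int],
    window_length: int = DEFAULT_WINDOW_LENGTH,
    source_id: str = "seq",
    chain_id: str = "A",
) -> PatternSet:
    """One window per sequence position, split by central-residue label.

    Positions are 1-based; termini are padded with 'X' so that every
    position, including the first and last, is the centre of a full-length
    window.
    """
    if window_length < 3 or window_length % 2 == 0:
        raise ValueError("window_length must be an odd integer >= 3")
    sequence = sequence.upper()
    labels = set(interacting_positions)
    if not labels <= set(range(1, len(sequence) + 1)):
        raise ValueError("interacting positions outside sequence range")
    half = window_length // 2
    padded = UNKNOWN * half + sequence + UNKNOWN * half
    pos_windows: list[Window] = []
    neg_windows: list[Window] = []
    for j in range(1, len(sequence) + 1):
        w = Window(
            sequence=padded[j - 1 : j - 1 + window_length],
            source_id=source_id,
            chain_id=chain_id,
            center=j,
            interacting=j in labels,
        )
        (pos_windows if w.interacting else neg_windows).append(w)
    return PatternSet(
        window_length=window_length,
        interacting=pos_windows,
        non_interacting=neg_windows,
    )


def windows_from_dataset(dataset, window_length: int = DEFAULT_WINDOW_LENGTH) -> PatternSet:
    """Pool windows over every binding chain of a LigandDataset."""
    pos: list[Window] = []
    neg: list[Window] = []
    for chain in dataset.chains:
        ps = generate_windows(
            chain.sequence,
            chain.interacting_positions,
            window_length=window_length,
            source_id=chain.structure_id,
            chain_id=chain.chain_id,
        )
        pos.extend(ps.interacting)
        neg.extend(ps.non_interacting)
    if not pos and not neg:
        raise ValueError("dataset has no chains")
    return PatternSet(window_length=window_length, interacting=pos, non_interacting=neg)


# ---------------------------------------------------------------------------
# redundancy filtering
# ---------------------------------------------------------------------------

def _make_aligner() -> Align.PairwiseAligner:
    return Align.PairwiseAligner(
        mode="global",
        match_score=1,
        mismatch_score=0,
        open_gap_score=-1,
        extend_gap_score=-1,
    )


def pairwise_identity(a: str, b: str, aligner: Align.PairwiseAligner | None = None) -> float:
    """Identity = matches / alignment length under global alignment with
    match 1, mismatch 0, linear gap -1."""
    aligner = aligner or _make_aligner()
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    return counts.identities / aln.length


def nonredundant_filter(
    sequences: Sequence[str],
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
) -> list[str]:
    """Greedy non-redundant subset in input order.

    A sequence is retained iff its identity to every previously retained
    sequence is strictly below the threshold (default 0.30, i.e. a 30 %
    non-redundant set).
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity threshold must be in (0, 1]")
    if not sequences:
        raise ValueError("no sequences given")
    aligner = _make_aligner()
    retained: list[str] = []
    for seq in sequences:
        if all(pairwise_identity(seq, kept, aligner) < identity_threshold for kept in retained):
            retained.append(seq)
    return retained


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def _symbol_counts(windows: Sequence[Window], window_length: int) -> np.ndarray:
    sym_index = {s: i for i, s in enumerate(WINDOW_SYMBOLS)}
    counts = np.zeros((window_length, len(WINDOW_SYMBOLS)), dtype=np.int64)
    for w in windows:
        for pos, aa in enumerate(w.sequence):
            counts[pos, sym_index[aa]] += 1
    return counts


def two_proportion_z(c1: np.ndarray, n1: int, c2: np.ndarray, n2: int) -> np.ndarray:
    """Pooled two-proportion z statistic, elementwise; 0 where the pooled
    proportion is degenerate (0 or 1)."""
    p1 = c1 / n1
    p2 = c2 / n2
    pool = (c1 + c2) / (n1 + n2)
    se = np.sqrt(pool * (1 - pool) * (1 / n1 + 1 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, (p1 - p2) / np.where(se > 0, se, 1.0), 0.0)
    return z


def position_enrichment(
    patterns: PatternSet,
    alpha: float = 0.05,
    correction: str = "bonferroni",
) -> EnrichmentMatrix:
    """Two-proportion z-test of residue frequency, interacting vs
    non-interacting windows, at every (position, residue) cell.

    Multiple testing is corrected over window_length x 20 tests
    (``correction``: any statsmodels ``multipletests`` method, or
    ``"none"``).  The 'X' padding column carries frequencies but no test.
    """
    if not patterns.interacting or not patterns.non_interacting:
        raise ValueError("both window sets must be non-empty")
    L = patterns.window_length
    c1 = _symbol_counts(patterns.interacting, L)
    c2 = _symbol_counts(patterns.non_interacting, L)
    n1, n2 = len(patterns.interacting), len(patterns.non_interacting)
    z = two_proportion_z(c1, n1, c2, n2)
    z[:, -1] = np.nan  # 'X' column untested

    z_aa = z[:, :20]
    pvals = 2.0 * norm.sf(np.abs(z_aa)).ravel()
    if correction == "none":
        reject = pvals < alpha
    else:
        reject, _, _, _ = multipletests(pvals, alpha=alpha, method=correction)
    significant = np.zeros((L, len(WINDOW_SYMBOLS)), dtype=bool)
    significant[:, :20] = reject.reshape(L, 20)
    return EnrichmentMatrix(
        window_length=L,
        freq_interacting=c1 / n1,
        freq_non_interacting=c2 / n2,
        z=z,
        significant=significant,
        alpha=alpha,
        correction=correction,
    )


# ---------------------------------------------------------------------------
# FASTA export
# ---------------------------------------------------------------------------

def export_pattern_fasta(patterns: PatternSet, which: str = "interacting") -> str:
    """Windows as FASTA text (WebLogo/MEME-ready input).

    Headers encode ``source|chain|center|pos-or-neg`` so records round-trip
    through :func:`parse_pattern_fasta`.
    """
    if which == "interacting":
        selected = patterns.interacting
    elif which == "non_interacting":
        selected = patterns.non_interacting
    elif which == "both":
        selected = patterns.interacting + patterns.non_interacting
    else:
        raise ValueError("which must be interacting|non_interacting|both")
    if not selected:
        raise ValueError(f"no {which} windows to export")
    records = [
        SeqRecord(
            Seq(w.sequence),
            id=f"{w.source_id}|{w.chain_id}|{w.center}|{'pos' if w.interacting else 'neg'}",
            description="",
        )
        for w in selected
    ]
    buf = io.StringIO()
    SeqIO.write(records, buf, "fasta")
    return buf.getvalue()


def parse_pattern_fasta(text: str) -> list[Window]:
    """Inverse of :func:`export_pattern_fasta`."""
    windows = []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        source, chain, center, tag = rec.id.split("|")
        windows.append(
            Window(
                sequence=str(rec.seq),
                source_id=source,
                chain_id=chain,
                center=int(center),
                interacting=tag == "pos",
            )
        )
    return windows
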