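"""Deterministic synthetic fixtures: toy complexes and planted datasets.

Two generative models make every other module testable without any
structure download:

* **Toy complexes** — minimal PDB files with one protein chain (a reduced
  two-atom residue model: Cα plus a side-chain centroid) and one het
  group, built so that exactly a designated set of residues lies within
  the contact cutoff of the ligand and every other residue sits beyond
  cutoff + 1 Å.  Geometry is schematic, not physical: the contact rule
  depends only on atom coordinates.

* **Planted datasets** — labelled sequence collections in which each
  position of residue type i is interacting with a fixed probability
  p_i, independently.  The per-type contact rate recovers p_i, so the
  propensity statistic RP_i/100 is the maximum-likelihood estimate of the
  planted probability, and closed-form prediction accuracies exist.

All generators are seed-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import gemmi
import numpy as np

from .amino_acids import AA_INDEX, AA_ORDER, ONE_TO_THREE
from .structure_contacts import BindingChain, LigandDataset

_AA_ARRAY = np.array(list(AA_ORDER))


def _probs_to_array(probs) -> np.ndarray:
    if isinstance(probs, Mapping):
        arr = np.zeros(20)
        for aa, p in probs.items():
            arr[AA_INDEX[aa]] = p
    else:
        arr = np.asarray(probs, dtype=float)
    if arr.shape != (20,) or (arr < 0).any() or (arr > 1).any():
        raise ValueError("contact probabilities must be 20 values in [0, 1]")
    return arr


# ---------------------------------------------------------------------------
# toy complexes
# ---------------------------------------------------------------------------

@dataclass
class ToyComplexSpec:
    length: int
    contact_positions: frozenset[int] = frozenset()
    sequence: str | None = None
    ligand_code: str = "ATP"
    cutoff: float = 4.0
    seed: int = 0
    structure_id: str = "toy1"
    chain_id: str = "A"

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("chain length must be >= 1")
        self.contact_positions = frozenset(self.contact_positions)
        if not self.contact_positions <= set(range(1, self.length + 1)):
            raise ValueError("contact positions outside chain")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError("sequence length mismatch")


def make_toy_complex(spec: ToyComplexSpec) -> str:
    """PDB text with exactly the designated residues in contact.

    The ligand sits at the origin (3 atoms within 0.8 Å of it).  Each
    residue points along its own direction: its Cα lies at cutoff + 2 Å
    or further; a contact residue additionally places its side-chain
    centroid at <= cutoff - 0.2 Å from the origin, a non-contact residue
    at >= cutoff + 2.5 Å.  Identical seeds give byte-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.length
    if spec.sequence is None:
        sequence = "".join(rng.choice(_AA_ARRAY, size=n))
    else:
        sequence = spec.sequence.upper()

    # ligand: three heavy atoms clustered at the origin
    lig_offsets = [(0.0, 0.0, 0.0), (0.8, 0.0, 0.0), (0.0, 0.8, 0.0)]

    st = gemmi.Structure()
    st.name = spec.structure_id
    model = gemmi.Model("1")
    chain = gemmi.Chain(spec.chain_id)

    def add_atom(res: gemmi.Residue, name: str, element: str, pos: np.ndarray) -> None:
        a = gemmi.Atom()
        a.name = name
        a.element = gemmi.Element(element)
        a.pos = gemmi.Position(*(float(x) for x in pos))
        a.occ = 1.0
        a.b_iso = 0.0
        res.add_atom(a)

    r_far = spec.cutoff + 2.0
    for i in range(1, n + 1):
        theta = 2.0 * np.pi * (i - 1) / max(n, 1)
        zlift = ((i % 3) - 1) * 0.3
        u = np.array([np.cos(theta), np.sin(theta), zlift])
        u /= np.linalg.norm(u)
        res = gemmi.Residue()
        res.name = ONE_TO_THREE[sequence[i - 1]]
        res.seqid = gemmi.SeqId(i, " ")
        res.het_flag = "A"
        add_atom(res, "CA", "C", (r_far + rng.uniform(0.0, 0.5)) * u)
        if i in spec.contact_positions:
            r_cb = spec.cutoff - 0.2 - rng.uniform(0.0, 1.0)
            if r_cb <= 0.9:  # keep clear of the ligand atoms themselves
                r_cb = 1.0
        else:
            r_cb = r_far + 0.5 + rng.uniform(0.0, 0.5)
        add_atom(res, "CB", "C", r_cb * u)
        chain.add_residue(res)
    model.add_chain(chain)

    lig_chain = gemmi.Chain("L")
    lig = gemmi.Residue()
    lig.name = spec.ligand_code
    lig.seqid = gemmi.SeqId(1, " ")
    lig.het_flag = "H"
    for k, off in enumerate(lig_offsets, start=1):
        add_atom(lig, f"C{k}", "C", np.array(off))
    lig_chain.add_residue(lig)
    model.add_chain(lig_chain)

    st.add_model(model)
    return st.make_pdb_string()


def random_toy_spec(seed: int, max_length: int = 40, **kwargs) -> ToyComplexSpec:
    """A randomized ToyComplexSpec (length, sequence and contact subset
    drawn from the seed) for oracle-equivalence sweeps."""
    rng = np.random.default_rng(seed)
    length = int(rng.integers(4, max_length + 1))
    n_contacts = int(rng.integers(0, max(1, length // 2) + 1))
    positions = rng.choice(np.arange(1, length + 1), size=n_contacts, replace=False)
    return ToyComplexSpec(
        length=length,
        contact_positions=frozenset(int(p) for p in positions),
        seed=seed,
        structure_id=f"toy{seed}",
        **kwargs,
    )


# ---------------------------------------------------------------------------
# planted sequence datasets
# ---------------------------------------------------------------------------

@dataclass
class PlantedProfile:
    """Generative model: position of residue type i interacts with
    probability ``contact_probs[i]``, independently.

    ``balanced=True`` builds each chain as a shuffled repetition of the
    full 20-letter alphabet (chain_length must divide by 20), giving exact
    per-type totals; otherwise residues are drawn uniformly.
    """

    contact_probs: np.ndarray
    n_chains: int = 100
    chain_length: int = 200
    seed: int = 0
    ligand_code: str = "LIG"
    balanced: bool = False

    def __post_init__(self) -> None:
        self.contact_probs = _probs_to_array(self.contact_probs)
        if self.n_chains < 1 or self.chain_length < 1:
            raise ValueError("need at least one chain of length >= 1")
        if self.balanced and self.chain_length % 20:
            raise ValueError("balanced chains need a length divisible by 20")


def make_planted_dataset(profile: PlantedProfile) -> LigandDataset:
    """Sample a labelled dataset from a planted profile.

    Every generated chain becomes one site (chains that happen to have no
    interacting position are kept: the planted model's sampling frame is
    all chains, and the zero-probability edge case must still yield a
    dataset).
    """
    rng = np.random.default_rng(profile.seed)
    p = profile.contact_probs
    R = np.zeros(20, dtype=np.int64)
    N = np.zeros(20, dtype=np.int64)
    chains: list[BindingChain] = []
    for c in range(profile.n_chains):
        if profile.balanced:
            idx = rng.permutation(np.tile(np.arange(20), profile.chain_length // 20))
        else:
            idx = rng.integers(0, 20, size=profile.chain_length)
        labels = rng.random(profile.chain_length) < p[idx]
        N += np.bincount(idx, minlength=20)
        R += np.bincount(idx[labels], minlength=20)
        chains.append(
            BindingChain(
                structure_id=f"syn{c + 1}",
                chain_id="A",
                sequence="".join(_AA_ARRAY[idx]),
                interacting_positions=frozenset(int(j) + 1 for j in np.nonzero(labels)[0]),
                ligand_instance="L1",
            )
        )
    return LigandDataset(
        ligand_code=profile.ligand_code,
        site_count=profile.n_chains,
        interacting_counts=R,
        total_counts=N,
        chains=chains,
    )


def expected_accuracy(
    contact_probs,
    positive_types: Sequence[bool] | np.ndarray,
    type_weights: Sequence[float] | np.ndarray | None = None,
) -> float:
    """Closed-form per-residue accuracy (percent) of a call rule that
    labels every residue of a 'positive' type interacting, under the
    planted model.

    A positive-type residue is correct with probability p_i, a
    negative-type one with 1 - p_i; weights default to uniform types.
    """
    p = _probs_to_array(contact_probs)
    pos = np.asarray(positive_types, dtype=bool)
    w = np.ones(20) if type_weights is None else np.asarray(type_weights, dtype=float)
    correct = np.where(pos, p, 1.0 - p)
    return float(100.0 * (w * correct).sum() / w.sum())


# ---------------------------------------------------------------------------
# planted ligand groups
# ---------------------------------------------------------------------------

#: Group signature residues, chosen for distinct physicochemical classes
#: (acidic, aromatic, basic, aliphatic, polar, small) so that planted
#: groups separate under all three comparison metrics.
GROUP_SIGNATURES: tuple[str, ...] = ("DE", "FWY", "KRH", "ILV", "STQ", "AGP")

BASE_CONTACT_PROB = 0.05


def make_planted_ligand_groups(
    k_groups: int = 2,
    ligands_per_group: int = 4,
    separation: float = 40.0,
    seed: int = 0,
    residues_per_type: int = 5000,
) -> tuple[dict[str, LigandDataset], dict[str, int]]:
    """Per-ligand datasets falling into k planted groups.

    Each group boosts the contact probability of its signature residues by
    separation/200, which puts group centroids at least ``separation``
    apart in propensity (RP percent) units; per-ligand jitter keeps the
    within-group spread below separation/5.  Counts are exact expectations
    (R_i = round(N_i p_i)), so the only randomness is the jitter.

    Returns (ligand id -> dataset, ligand id -> group index).
    """
    if k_groups < 1 or k_groups > len(GROUP_SIGNATURES):
        raise ValueError(f"k_groups must be in 1..{len(GROUP_SIGNATURES)}")
    if separation <= 0:
        raise ValueError("separation must be positive")
    rng = np.random.default_rng(seed)
    dp = separation / 200.0
    jitter = separation / (1000.0 * np.sqrt(20))
    datasets: dict[str, LigandDataset] = {}
    groups: dict[str, int] = {}
    for g in range(k_groups):
        centroid = np.full(20, BASE_CONTACT_PROB)
        for aa in GROUP_SIGNATURES[g]:
            centroid[AA_INDEX[aa]] += dp
        for m in range(ligands_per_group):
            p = np.clip(centroid + rng.uniform(-jitter, jitter, size=20), 0.005, 0.95)
            N = np.full(20, residues_per_type, dtype=np.int64)
            R = np.round(N * p).astype(np.int64)
            lid = f"G{g}L{m}"
            datasets[lid] = LigandDataset(
                ligand_code=lid,
                site_count=1,
                interacting_counts=R,
                total_counts=N,
            )
            groups[lid] = g
    return datasets, groups
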