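"""Parse protein-ligand complexes and extract binding-site residues.

A binding site is the set of protein residues having at least one heavy
atom within a distance cutoff (default 4.0 Å) of any atom of a bound
ligand instance.  Contacts are aggregated per ligand into a
:class:`LigandDataset` holding the interacting counts ``R_i`` and the
total counts ``N_i`` per residue type, the raw material for composition
and propensity statistics.

Parsing is delegated to :mod:`gemmi`; this module then applies the
conventions used throughout the package: first model only, hydrogens and
deuteriums discarded, waters never treated as ligands, and for altloc
duplicates the highest-occupancy conformer (ties: first in file).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .amino_acids import (
    AA_INDEX,
    AA_ORDER,
    STANDARD_AA3,
    THREE_TO_ONE,
    WATER_CODES,
)
from .errors import (
    EmptyDatasetError,
    EmptyStructureError,
    LigandNotFoundError,
    PDBParseError,
)

DEFAULT_CUTOFF = 4.0
DEFAULT_MIN_SITES = 30


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    x: float
    y: float
    z: float
    occupancy: float = 1.0
    altloc: str = ""

    @property
    def xyz(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)


@dataclass
class Residue:
    """One polymer residue (3-letter name, author numbering)."""

    name: str
    number: int
    icode: str
    atoms: list[Atom]

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE[self.name]


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue]

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def position_map(self) -> dict[tuple[int, str], int]:
        """(author number, insertion code) -> 1-based sequence position."""
        return {(r.number, r.icode): i + 1 for i, r in enumerate(self.residues)}


@dataclass
class HetGroup:
    """A non-polymer chemical component (candidate ligand)."""

    code: str
    chain_id: str
    number: int
    icode: str
    atoms: list[Atom]

    @property
    def instance_id(self) -> str:
        return f"{self.chain_id}{self.number}{self.icode.strip()}"


@dataclass
class StructureModel:
    """First-model content of a PDB entry, split into polymer chains and
    het groups.  Only the 20 standard amino acids populate chains; any
    other residue (modified amino acids included) lands in ``het_groups``
    and is excluded from polymer statistics."""

    structure_id: str
    chains: list[Chain]
    het_groups: list[HetGroup]


@dataclass(frozen=True)
class ContactRecord:
    """One interacting-residue observation: a residue with >= 1 heavy atom
    within the cutoff of a ligand instance."""

    ligand_code: str
    structure_id: str
    ligand_chain: str
    ligand_number: int
    residue_chain: str
    residue_name: str  # 1-letter
    residue_number: int
    insertion_code: str
    min_distance: float


@dataclass
class BindingChain:
    """One binding site's chain view: the chain sequence plus the 1-based
    positions of its ligand-contacting residues."""

    structure_id: str
    chain_id: str
    sequence: str
    interacting_positions: frozenset[int]
    ligand_instance: str = ""


@dataclass
class LigandDataset:
    """Per-ligand aggregate over binding sites.

    ``interacting_counts[i]`` (R_i) counts contact residues of type
    ``AA_ORDER[i]`` summed over sites; ``total_counts[i]`` (N_i) counts all
    standard residues of that type over each contributing site's chain.
    One site = one (structure, chain, ligand instance) with >= 1 contact.
    """

    ligand_code: str
    site_count: int
    interacting_counts: np.ndarray
    total_counts: np.ndarray
    chains: list[BindingChain] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.interacting_counts = np.asarray(self.interacting_counts, dtype=np.int64)
        self.total_counts = np.asarray(self.total_counts, dtype=np.int64)
        if self.interacting_counts.shape != (20,) or self.total_counts.shape != (20,):
            raise ValueError("count vectors must have 20 entries")

    def to_json(self) -> str:
        payload = {
            "ligand_code": self.ligand_code,
            "site_count": self.site_count,
            "aa_order": AA_ORDER,
            "interacting_counts": self.interacting_counts.tolist(),
            "total_counts": self.total_counts.tolist(),
            "chains": [
                {
                    "structure_id": c.structure_id,
                    "chain_id": c.chain_id,
                    "sequence": c.sequence,
                    "interacting_positions": sorted(c.interacting_positions),
                    "ligand_instance": c.ligand_instance,
                }
                for c in self.chains
            ],
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "LigandDataset":
        d = json.loads(text)
        return cls(
            ligand_code=d["ligand_code"],
            site_count=d["site_count"],
            interacting_counts=np.array(d["interacting_counts"]),
            total_counts=np.array(d["total_counts"]),
            chains=[
                BindingChain(
                    structure_id=c["structure_id"],
                    chain_id=c["chain_id"],
                    sequence=c["sequence"],
                    interacting_positions=frozenset(c["interacting_positions"]),
                    ligand_instance=c.get("ligand_instance", ""),
                )
                for c in d["chains"]
            ],
        )


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def _validate_coordinate_records(pdb_text: str) -> None:
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        if len(line) < 54:
            raise PDBParseError(f"line {lineno}: truncated coordinate record")
        try:
            float(line[30:38]), float(line[38:46]), float(line[46:54])
        except ValueError as exc:
            raise PDBParseError(f"line {lineno}: unparseable coordinates") from exc


def _select_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep one conformer per atom name: highest occupancy, ties first."""
    best: dict[str, Atom] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in best:
            best[a.name] = a
            order.append(a.name)
        elif a.occupancy > best[a.name].occupancy:
            best[a.name] = a
    return [best[n] for n in order]


def parse_structure(pdb_text: str, structure_id: str | None = None) -> StructureModel:
    """Parse PDB-format text into a :class:`StructureModel`.

    Keeps the first model only, drops hydrogens/deuteriums and waters,
    resolves altloc duplicates to the highest-occupancy conformer, and
    classifies residues by name: the 20 standard amino acids go to polymer
    chains, everything else becomes a het group.
    """
    _validate_coordinate_records(pdb_text)
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - gemmi message
        raise PDBParseError(str(exc)) from exc
    if len(st) == 0:
        raise EmptyStructureError("no models in structure")
    if structure_id is None:
        structure_id = (st.name or "struct").strip().lower()

    model = st[0]
    chains: dict[str, Chain] = {}
    het_groups: list[HetGroup] = []
    n_atoms = 0
    for g_chain in model:
        for g_res in g_chain:
            atoms = [
                Atom(
                    name=a.name,
                    element=a.element.name,
                    x=a.pos.x,
                    y=a.pos.y,
                    z=a.pos.z,
                    occupancy=a.occ,
                    altloc=a.altloc if a.altloc != "\x00" else "",
                )
                for a in g_res
                if not a.is_hydrogen()
            ]
            atoms = _select_altlocs(atoms)
            if not atoms:
                continue
            n_atoms += len(atoms)
            name = g_res.name.strip().upper()
            icode = g_res.seqid.icode.strip()
            if name in WATER_CODES:
                continue
            if name in STANDARD_AA3:
                chain = chains.setdefault(g_chain.name, Chain(g_chain.name, []))
                chain.residues.append(
                    Residue(name=name, number=g_res.seqid.num, icode=icode, atoms=atoms)
                )
            else:
                het_groups.append(
                    HetGroup(
                        code=name,
                        chain_id=g_chain.name,
                        number=g_res.seqid.num,
                        icode=icode,
                        atoms=atoms,
                    )
                )
    if n_atoms == 0:
        raise EmptyStructureError("structure contains no atoms")
    return StructureModel(
        structure_id=structure_id,
        chains=list(chains.values()),
        het_groups=het_groups,
    )


# ---------------------------------------------------------------------------
# contact extraction
# ---------------------------------------------------------------------------

def _coords(atoms: Sequence[Atom]) -> np.ndarray:
    return np.array([[a.x, a.y, a.z] for a in atoms], dtype=float)


def extract_contacts(
    model: StructureModel,
    ligand_instance: HetGroup,
    cutoff: float = DEFAULT_CUTOFF,
) -> list[ContactRecord]:
    """Residues with any heavy atom within ``cutoff`` Å of the ligand.

    Returns one :class:`ContactRecord` per contacting residue carrying the
    minimum heavy-atom pair distance, sorted by (chain, residue number,
    insertion code).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if ligand_instance not in model.het_groups:
        raise LigandNotFoundError(
            f"ligand {ligand_instance.code} {ligand_instance.instance_id} "
            f"not in model {model.structure_id}"
        )
    lig_xyz = _coords(ligand_instance.atoms)
    records: list[ContactRecord] = []
    for chain in model.chains:
        for res in chain.residues:
            d = cdist(_coords(res.atoms), lig_xyz).min()
            if d <= cutoff:
                records.append(
                    ContactRecord(
                        ligand_code=ligand_instance.code,
                        structure_id=model.structure_id,
                        ligand_chain=ligand_instance.chain_id,
                        ligand_number=ligand_instance.number,
                        residue_chain=chain.chain_id,
                        residue_name=res.one_letter,
                        residue_number=res.number,
                        insertion_code=res.icode,
                        min_distance=float(d),
                    )
                )
    records.sort(key=lambda r: (r.residue_chain, r.residue_number, r.insertion_code))
    return records


def build_dataset(
    models: Iterable[StructureModel],
    ligand_code: str,
    cutoff: float = DEFAULT_CUTOFF,
) -> LigandDataset:
    """Aggregate all binding sites of ``ligand_code`` across ``models``.

    One binding site per (structure, chain, ligand instance) with >= 1
    contact; each site adds its contact residues to R_i and its full chain
    residue counts to N_i, so a chain bound by k ligand copies contributes
    k times to both.  Duplicate (chain, residue) contacts from one ligand
    instance count once.
    """
    ligand_code = ligand_code.strip().upper()
    R = np.zeros(20, dtype=np.int64)
    N = np.zeros(20, dtype=np.int64)
    site_chains: list[BindingChain] = []
    seen_code = False
    for model in models:
        chain_by_id = {c.chain_id: c for c in model.chains}
        for het in model.het_groups:
            if het.code != ligand_code:
                continue
            seen_code = True
            recs = extract_contacts(model, het, cutoff)
            by_chain: dict[str, list[ContactRecord]] = {}
            for r in recs:
                by_chain.setdefault(r.residue_chain, []).append(r)
            for chain_id, crecs in sorted(by_chain.items()):
                chain = chain_by_id[chain_id]
                posmap = chain.position_map()
                positions = frozenset(
                    posmap[(r.residue_number, r.insertion_code)] for r in crecs
                )
                for r in crecs:
                    R[AA_INDEX[r.residue_name]] += 1
                for res in chain.residues:
                    N[AA_INDEX[res.one_letter]] += 1
                site_chains.append(
                    BindingChain(
                        structure_id=model.structure_id,
                        chain_id=chain_id,
                        sequence=chain.sequence,
                        interacting_positions=positions,
                        ligand_instance=het.instance_id,
                    )
                )
    if not site_chains:
        detail = "no binding sites" if seen_code else "ligand absent from all models"
        raise EmptyDatasetError(f"{ligand_code}: {detail}")
    return LigandDataset(
        ligand_code=ligand_code,
        site_count=len(site_chains),
        interacting_counts=R,
        total_counts=N,
        chains=site_chains,
    )


def filter_ligands(
    datasets: Iterable[LigandDataset],
    min_sites: int = DEFAULT_MIN_SITES,
) -> list[LigandDataset]:
    """Keep datasets with at least ``min_sites`` binding sites (order kept)."""
    if min_sites < 1:
        raise ValueError("min_sites must be >= 1")
    return [d for d in datasets if d.site_count >= min_sites]


# ---------------------------------------------------------------------------
# tabular export
# ---------------------------------------------------------------------------

def contacts_to_table(records: Sequence[ContactRecord]) -> pd.DataFrame:
    """ContactRecords as a DataFrame (TSV-ready, one row per contact)."""
    return pd.DataFrame(
        [asdict(r) for r in records],
        columns=[
            "ligand_code",
            "structure_id",
            "ligand_chain",
            "ligand_number",
            "residue_chain",
            "residue_name",
            "residue_number",
            "insertion_code",
            "min_distance",
        ],
    )
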