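from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from ligprop import ToyComplexSpec, make_toy_complex, parse_structure

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def pdb_line(
    record: str,
    serial: int,
    name: str,
    resname: str,
    chain: str,
    resnum: int,
    x: float,
    y: float,
    z: float,
    occ: float = 1.0,
    element: str = "C",
    altloc: str = " ",
    icode: str = " ",
) -> str:
    atom_name = f" {name:<3}" if len(name) < 4 else name
    return (
        f"{record:<6}{serial:>5} {atom_name}{altloc}{resname:>3} {chain}"
        f"{resnum:>4}{icode}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}"
        f"          {element:>2}"
    )


@pytest.fixture
def simple_complex_text() -> str:
    """Three residues on a line plus one ATP het group and a water."""
    lines = [
        pdb_line("ATOM", 1, "CA", "GLY", "A", 1, 0.0, 0.0, 0.0),
        pdb_line("ATOM", 2, "CA", "ALA", "A", 2, 4.0, 0.0, 0.0),
        pdb_line("ATOM", 3, "CA", "SER", "A", 3, 8.0, 0.0, 0.0),
        pdb_line("HETATM", 4, "C1", "ATP", "L", 1, 0.0, 3.5, 0.0),
        pdb_line("HETATM", 5, "O", "HOH", "W", 1, 50.0, 50.0, 50.0, element="O"),
        "END",
    ]
    return "\n".join(lines) + "\n"


@pytest.fixture
def simple_model(simple_complex_text):
    return parse_structure(simple_complex_text, structure_id="simp")


@pytest.fixture
def toy_model_factory():
    """Build (model, spec) pairs from ToyComplexSpec kwargs."""

    def factory(**kwargs):
        spec = ToyComplexSpec(**kwargs)
        model = parse_structure(make_toy_complex(spec), structure_id=spec.structure_id)
        return model, spec

    return factory


@pytest.fixture
def rng():
    return np.random.default_rng(20160325)
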