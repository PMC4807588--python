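"""Exception hierarchy for ligprop."""


class LigpropError(Exception):
    """Base class for all ligprop errors."""


class PDBParseError(LigpropError):
    """A PDB record could not be parsed; the message names the line."""


class EmptyStructureError(LigpropError):
    """Parsed structure contains no atoms."""


class LigandNotFoundError(LigpropError):
    """Requested ligand instance/code is absent from the model(s)."""


class EmptyDatasetError(LigpropError):
    """No binding site could be built for the requested ligand."""


class DegenerateInputError(LigpropError):
    """Input with no usable signal (e.g. an all-zero count vector)."""


class InconsistentDatasetError(LigpropError):
    """Dataset violates a count invariant (e.g. R_i > N_i)."""
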