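"""Exception hierarchy for opepdock."""


class OpepdockError(Exception):
    """Base class for all package errors."""


class PDBParseError(OpepdockError):
    """Malformed or empty PDB input."""


class EmptyStructureError(PDBParseError):
    """A PDB text containing no protein atoms."""


class UnknownResidueError(OpepdockError):
    """A residue name outside the 20 standard amino acids."""


class MissingAtomError(OpepdockError):
    """A residue lacking one of the required backbone atoms."""


class PartnerError(OpepdockError):
    """Invalid receptor/ligand chain assignment."""


class ParameterError(OpepdockError):
    """Invalid force-field parameter value or file."""


class GeometryError(OpepdockError):
    """Degenerate geometry (zero-length vectors, <3 superposition points...)."""


class MinimizationError(OpepdockError):
    """Non-finite energy/gradient during minimization."""


class ConstructionError(OpepdockError):
    """Unsatisfiable synthetic-complex or decoy-generation constraint."""
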