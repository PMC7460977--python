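"""Exception hierarchy. Validation errors exit the CLI with code 2, stage
failures with code 3."""


class HopcrystalError(Exception):
    """Base class for all package errors."""


class FormatError(HopcrystalError):
    """Unparseable or incomplete input file."""


class SymmetryError(FormatError):
    """Symmetry operation string or space-group label not understood."""


class NotMolecularError(HopcrystalError):
    """Bond network does not close into finite molecules (covalent solid)."""


class SupercellError(HopcrystalError):
    """Requested neighbor cutoff exceeds the guaranteed supercell radius."""


class GeometryError(HopcrystalError):
    """Physically impossible geometry (clashing or overlapping atoms)."""


class ValidationError(HopcrystalError):
    """Loaded matrices violate a structural invariant."""


class DomainError(HopcrystalError):
    """Physical parameter outside its admissible domain (λ ≤ 0, T ≤ 0 ...)."""


class AssignmentError(HopcrystalError):
    """Dimer orbitals cannot be assigned to monomer frontier orbitals."""


class AlignmentError(HopcrystalError):
    """Residual rotation/translation after Eckart alignment above tolerance."""


class StageError(HopcrystalError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
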