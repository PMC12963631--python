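"""Exception hierarchy for scforge."""


class ScforgeError(Exception):
    """Base class for all scforge errors."""


class FastaParseError(ScforgeError):
    """Malformed FASTA input; message names the offending line."""


class ResidueError(ScforgeError):
    """A sequence contains a residue disallowed by the active policy."""


class NotAnAntibodyError(ScforgeError):
    """No variable domain could be located in the input sequence."""


class AmbiguousLinkerError(ScforgeError):
    """More than one candidate interdomain linker run was found."""

    def __init__(self, spans):
        self.spans = list(spans)
        super().__init__(
            "ambiguous linker: candidate runs at " + ", ".join(map(str, self.spans))
        )


class MutationError(ScforgeError):
    """A position-addressed mutation could not be applied."""


class AssemblyError(ScforgeError):
    """Invalid scFv construct assembly request."""


class DegenerateFitError(ScforgeError):
    """Linear fit requested on degenerate data (constant x or n too small)."""


class UndefinedPIError(ScforgeError):
    """Sequence has no ionizable groups, isoelectric point undefined."""


class GenerationError(ScforgeError):
    """A synthetic fixture generator could not satisfy its target."""


class ChargeRangeError(ScforgeError):
    """Requested linker charge outside the tunable range."""
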