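"""Exception hierarchy for the fabqsar workflow.

Every stage raises a subclass of :class:`FabQsarError` so callers (and the
CLI) can distinguish workflow failures from programming errors.
"""


class FabQsarError(Exception):
    """Base class for all workflow errors."""


# --- sequence / annotation ------------------------------------------------

class UnknownResidue(FabQsarError):
    """A residue letter outside the 20 canonical amino acids was supplied."""


class AmbiguousSequence(UnknownResidue):
    """Sequence contains ambiguity codes (B, Z, X), which no property table
    defines."""


class AnchorNotFound(FabQsarError):
    """One of the conserved IMGT anchors (Cys23, Trp41, Cys104, Phe/Trp118)
    could not be located — the sequence is malformed or not an antibody
    variable domain."""


class LengthOutOfRange(FabQsarError):
    """Variable-domain sequence length outside plausible bounds."""


class LengthMismatch(FabQsarError):
    """Constant-domain sequence length deviates from the allele template."""


class EmptyRegion(FabQsarError):
    """An operation requiring residues was applied to an empty region."""


class UnknownTable(FabQsarError):
    """Requested per-residue property table is not registered."""


# --- structures -----------------------------------------------------------

class MissingRadius(FabQsarError):
    """An atom has no assigned van der Waals radius."""


class DegenerateSelection(FabQsarError):
    """Atom selection is too small or collinear for superposition."""


class EmptyInterval(FabQsarError):
    """A time-series interval contains no frames."""


# --- chemometrics ---------------------------------------------------------

class AllRemoved(FabQsarError):
    """A filter removed every descriptor."""


class TooFewSamples(FabQsarError):
    """Not enough samples for the requested operation."""


class EmptyStratum(FabQsarError):
    """A stratification label has no samples."""


class RankDeficient(FabQsarError):
    """Requested latent variables exceed the matrix rank."""


class DegenerateResponse(FabQsarError):
    """Response vector is constant; no model can be trained."""


class EmptyInput(FabQsarError):
    """Metric computation received empty inputs."""


class TooFew(FabQsarError):
    """Too few residuals for an interval estimate."""


class SampleMismatch(FabQsarError):
    """Two runs being compared do not share the same samples."""


class StageFailure(FabQsarError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception | str):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
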