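"""Exception hierarchy shared across the package."""


class SbpconfError(Exception):
    """Base class for all package-specific errors."""


class ParseError(SbpconfError):
    """A structure or curve file could not be parsed."""


class FormatError(SbpconfError):
    """Input data violates the expected column layout or units."""


class SelectionError(SbpconfError):
    """An atom/residue/chain selection could not be resolved."""


class DegenerateGeometryError(SbpconfError):
    """Point sets are too degenerate for the requested operation."""


class SingleRigidBodyError(SbpconfError):
    """Two conformers are related by one global rigid motion; no domain split exists."""


class FitError(SbpconfError):
    """A model fit failed or is underdetermined."""


class NoBindingError(FitError):
    """Titration signal shows no resolvable binding transition."""


class NoTransitionError(FitError):
    """Melt curve lacks an interior sigmoidal transition."""
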