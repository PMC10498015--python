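"""Exception hierarchy shared across the package."""


class PhtmapError(Exception):
    """Base class for all package-specific errors."""


class InvalidReadingError(PhtmapError):
    """A fluorescence reading violates the F_o/F_m preconditions."""


class CurveInputError(PhtmapError):
    """Malformed or inconsistent curve tables / sample maps."""


class FitError(PhtmapError):
    """A model fit cannot be carried out on the given data."""


class AliasedEffectsError(FitError):
    """Two random-effect factors induce the identical partition of samples."""


class GenotypeInputError(PhtmapError):
    """Malformed or inconsistent genotype matrices / maps."""
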