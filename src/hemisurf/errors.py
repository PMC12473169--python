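"""Exception and warning types shared across the package."""


class HemisurfError(Exception):
    """Base class for all errors raised by hemisurf."""


class SectionFormatError(HemisurfError):
    """A section file, manifest or coefficient-matrix file is malformed."""


class FitError(HemisurfError):
    """A least-squares stage is underdetermined or rank deficient."""


class MeshError(HemisurfError):
    """Mesh construction or a mesh-based measure failed its preconditions."""


class ImagingError(HemisurfError):
    """Silhouette binarization or profile extraction failed."""


class ExtrapolationWarning(UserWarning):
    """A fitted surface was evaluated outside the region it was fitted on."""
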