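"""Exception hierarchy shared across the package.

Every data-level failure raises a :class:`PackrateError` subclass whose message
starts with a stable, greppable phrase (e.g. ``"chain not found"``); the CLI
maps these to exit code 2.
"""


class PackrateError(Exception):
    """Base class for all data-level errors raised by packrate."""


class ChainNotFoundError(PackrateError):
    pass


class InsufficientSitesError(PackrateError):
    pass


class ParseFailureError(PackrateError):
    pass


class EmptyRateFileError(PackrateError):
    pass


class DuplicateSiteError(PackrateError):
    pass


class LengthMismatchError(PackrateError):
    pass


class NoOverlapError(PackrateError):
    pass


class DegenerateGeometryError(PackrateError):
    pass


class UnknownResidueTypeError(PackrateError):
    pass


class SasaFailureError(PackrateError):
    pass


class InvalidPerturbationError(PackrateError):
    pass


class InvalidDistributionError(PackrateError):
    pass


class NoVariationError(PackrateError):
    pass


class ZeroVarianceError(PackrateError):
    pass


class CollinearPredictorsError(PackrateError):
    pass


class NoProteinsError(PackrateError):
    pass


class PackingTooDenseError(PackrateError):
    pass


class SlopeError(PackrateError):
    pass
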