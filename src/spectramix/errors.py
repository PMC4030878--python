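"""Exception hierarchy for the spectramix pipeline.

All pipeline-contract violations derive from :class:`SpectramixError` so a
CLI layer can catch one type and turn it into a one-line diagnostic.
"""


class SpectramixError(Exception):
    """Base class for all spectramix contract violations."""


class DegenerateSpectrumError(SpectramixError):
    """A spectrum with no signal where positive signal is required."""


class GridMismatchError(SpectramixError):
    """Two objects carry incompatible wavelength grids."""


class AliasingError(SpectramixError):
    """An OPD schedule undersamples the shortest wavelength of a grid."""


class CollinearityError(SpectramixError):
    """A spectral library is numerically rank deficient."""


class SceneSpecError(SpectramixError):
    """An invalid synthetic-scene specification."""


class EmptySeedError(SpectramixError):
    """Region growing was seeded on a pixel without signal."""


class MatchingError(SpectramixError):
    """Cross-replicate object matching failed for an object/replicate pair."""


class InsufficientCellsError(SpectramixError):
    """Too few cells for a robust population statistic."""


class FormatError(SpectramixError):
    """A file does not satisfy the on-disk format contract."""
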