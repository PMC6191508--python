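"""Exception types raised across the package.

Each failure mode named by the module contracts gets its own class so
callers can react to (or test for) a specific condition instead of
string-matching generic exceptions.
"""


class AtlasFuseError(Exception):
    """Base class for all package-specific failures."""


class Non3DImageError(AtlasFuseError):
    """A loaded image is not a 3D volume."""


class NonBinaryLabelError(AtlasFuseError):
    """A label image holds values other than 0/1 beyond tolerance."""


class GridMismatchError(AtlasFuseError):
    """Two volumes expected on a common grid have different shape/spacing."""


class EmptyMaskError(AtlasFuseError):
    """An operation requiring a non-empty mask received an empty one."""


class DegenerateTrainingSetError(AtlasFuseError):
    """A training set contains samples of only one class."""


class NoReliableLabelsError(AtlasFuseError):
    """Information-balance weighting found no reliable labels on one side."""
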