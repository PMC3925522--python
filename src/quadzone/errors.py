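"""Exception hierarchy for the quadzone pipeline.

Every stage raises a subclass of :class:`QuadzoneError` so batch drivers can
distinguish pipeline failures from programming errors.
"""


class QuadzoneError(Exception):
    """Base class for all quadzone pipeline errors."""


class MeshFormatError(QuadzoneError):
    """A mesh file could not be parsed in the requested format."""


class DegenerateInputError(QuadzoneError):
    """Input geometry is empty or degenerate (no vertices/faces, zero extent)."""


class OffsetResolutionError(QuadzoneError):
    """Requested offset distance is below the voxel pitch: the offset would be
    indistinguishable from discretisation noise."""


class DegenerateIncisionError(QuadzoneError):
    """Incision endpoints coincide; no aperture segment can be built."""


class NoLandmarksError(QuadzoneError):
    """The dangerous zone is empty: the offset shells never occlude the
    analyzed region, so E/F/G/H are undefined."""


class NoIntersectionError(QuadzoneError):
    """A constructed line misses its target polyline (e.g. the brim-parallel
    line through G does not reach the obturator foramen rim)."""


class FrameError(QuadzoneError):
    """Reference-frame fit failed (collinear or insufficient points)."""


class PhantomSpecError(QuadzoneError):
    """A phantom specification is geometrically infeasible."""


class CohortError(QuadzoneError):
    """Cohort generation or aggregation failed (no feasible draws, no
    successful subjects, empty input)."""


class InputContractError(QuadzoneError):
    """A subject's input files violate the pipeline's input contract
    (missing file, missing landmark key, malformed coordinates)."""
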