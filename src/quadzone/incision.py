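"""Simulated Stoppa incision aperture.

The modified Stoppa approach is a midline longitudinal incision; a rigid
straight instrument passed through it constrains every feasible screw
trajectory to a line from some point of the incision to the entry point on
bone. The aperture is modelled as a straight 3D segment carrying a uniform
set of admissible viewpoints; index 0 is the proximal end (toward the head),
the last index the distal end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateIncisionError

#: Default number of uniformly spaced viewpoints along the incision. A fixed
#: uniform sample is reproducible (unlike the intraoperative "random vision"
#: it stands in for); zone convergence under refinement is test-verified.
DEFAULT_N_VIEWPOINTS = 21


@dataclass(frozen=True)
class IncisionAperture:
    """A straight incision segment with sampled admissible viewpoints."""

    proximal_end: np.ndarray
    distal_end: np.ndarray
    viewpoints: np.ndarray  # (n, 3); [0] == proximal_end, [-1] == distal_end

    @property
    def length(self) -> float:
        """Incision length in mm."""
        return float(np.linalg.norm(self.distal_end - self.proximal_end))

    @property
    def n_viewpoints(self) -> int:
        return len(self.viewpoints)


def make_incision(
    proximal_end: np.ndarray,
    distal_end: np.ndarray,
    n_viewpoints: int = DEFAULT_N_VIEWPOINTS,
) -> IncisionAperture:
    """Build an aperture with ``n_viewpoints`` uniformly spaced viewpoints.

    Endpoints are always included. Refining with n2 = k*(n1 - 1) + 1 yields a
    viewpoint set containing the coarser one, so zone results refine
    monotonically.
    """
    p = np.asarray(proximal_end, dtype=float).reshape(3)
    q = np.asarray(distal_end, dtype=float).reshape(3)
    if not np.isfinite(p).all() or not np.isfinite(q).all():
        raise DegenerateIncisionError("incision endpoints must be finite")
    if np.linalg.norm(q - p) < 1e-9:
        raise DegenerateIncisionError("incision endpoints coincide")
    if n_viewpoints < 2:
        raise ValueError("need at least 2 viewpoints (the two incision ends)")
    ts = np.linspace(0.0, 1.0, int(n_viewpoints))
    pts = p[None, :] + ts[:, None] * (q - p)[None, :]
    pts[0] = p
    pts[-1] = q
    return IncisionAperture(proximal_end=p, distal_end=q, viewpoints=pts)
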