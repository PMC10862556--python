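"""Crust-normalized three-component (La-V-Ni) mixing analysis.

Concentrations of a chosen element triple are multiplied by per-element
normalization factors so that the upper-continental-crust (UCC) reference
composition plots at the ternary centroid (1/3, 1/3, 1/3); samples are then
closed to sum 1.  Because closure follows a common linear scaling, binary
mass mixtures of two end-members remain exactly collinear in the ternary
diagram, which is what lets the diagram read off dust vs anthropogenic
mixing proportions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import ElementPanel
from .reference import UCC_ABUNDANCES


@dataclass
class NormalizationFactors:
    """Per-element multipliers placing the reference at the centroid."""

    elements: list
    factors: np.ndarray
    reference: np.ndarray  # the reference abundances, µg/g

    def __post_init__(self):
        self.factors = np.asarray(self.factors, dtype=float)
        self.reference = np.asarray(self.reference, dtype=float)
        if np.any(self.factors <= 0):
            raise ValueError("factors must be > 0")
        scaled = self.reference * self.factors
        if not np.allclose(scaled, scaled[0], rtol=1e-6):
            raise ValueError("reference * factors must be constant across elements")


def centroid_factors(reference=None, elements=("La", "Ni", "V"), anchor="V"):
    """Normalization factors mapping a reference composition to the centroid.

    factor_e = reference[anchor] / reference[e]; the anchor element gets
    multiplier 1.  Defaults use the packaged UCC abundances for (La, Ni, V)
    anchored at V, reproducing the conventional multipliers 3.13 (La),
    2.06 (Ni), 1 (V).
    """
    ref_map = UCC_ABUNDANCES if reference is None else reference
    if anchor not in elements:
        raise ValueError(f"anchor {anchor!r} not among elements {elements}")
    vals = np.array([ref_map[e] for e in elements], dtype=float)
    if np.any(vals <= 0):
        bad = elements[int(np.argmin(vals))]
        raise ValueError(f"reference abundance for {bad!r} must be > 0")
    factors = ref_map[anchor] / vals
    return NormalizationFactors(list(elements), factors, vals)


def _close(scaled: np.ndarray) -> np.ndarray:
    total = scaled.sum(axis=-1, keepdims=True)
    return scaled / total


def ternary_coordinates(panel: ElementPanel, factors: NormalizationFactors):
    """Closed ternary coordinates per sample for the factor's element triple.

    Returns (coords, flagged): coords has shape (n_samples, 3) and each row
    sums to 1; `flagged` marks samples with non-positive scaled values
    (their coordinates are NaN).
    """
    idx = panel.element_index(factors.elements)
    scaled = panel.conc[:, idx] * factors.factors
    flagged = np.any(~(scaled > 0), axis=1)
    coords = np.full_like(scaled, np.nan)
    ok = ~flagged
    coords[ok] = _close(scaled[ok])
    return coords, flagged


def reference_point(factors: NormalizationFactors) -> np.ndarray:
    """Ternary coordinates of the reference itself (the centroid)."""
    return _close(factors.reference * factors.factors)


def to_plane(coords: np.ndarray) -> np.ndarray:
    """Embed closed (a, b, c) coordinates in the 2-D equilateral triangle.

    Corners: a -> (0, 0), b -> (1, 0), c -> (1/2, sqrt(3)/2).
    """
    coords = np.atleast_2d(coords)
    x = coords[:, 1] + 0.5 * coords[:, 2]
    y = (np.sqrt(3) / 2.0) * coords[:, 2]
    return np.column_stack([x, y])


def mixing_line_projection(points, end_member_1, end_member_2):
    """Project ternary points onto the mixing line between two end-members.

    Returns per-point ``fraction`` (0 at end-member 1, 1 at end-member 2;
    values outside [0, 1] are returned unclamped and flagged) and
    ``deviation``, the perpendicular distance from the line in the 2-D
    simplex embedding.
    """
    P = to_plane(np.atleast_2d(points))
    e1 = to_plane(np.asarray(end_member_1))[0]
    e2 = to_plane(np.asarray(end_member_2))[0]
    seg = e2 - e1
    L2 = float(seg @ seg)
    if L2 < 1e-24:
        raise ValueError("end members coincide")
    frac = (P - e1) @ seg / L2
    foot = e1 + np.outer(frac, seg)
    dev = np.linalg.norm(P - foot, axis=1)
    outside = (frac < 0) | (frac > 1)
    return {"fraction": frac, "deviation": dev, "outside": outside}
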