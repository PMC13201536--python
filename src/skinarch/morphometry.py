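"""Histology-derived quantifications of the dermal-epidermal interface.

Papillae counts and heights are measured on an annotated interface contour:
an ordered polyline in which papilla apexes and the rete-ridge vertices
flanking them are labelled.  Each papilla base is the line connecting its two
surrounding rete ridges; the height is the perpendicular distance from the
apex to that line.  Collagen fiber parallelism is summarized by the circular
resultant of doubled orientation angles, on a 0 (isotropic) to 1 (parallel)
scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "InterfaceContour",
    "papillae_per_mm",
    "papilla_height",
    "rete_ridges_per_mm",
    "normalize_to_baseline",
    "alignment_coefficient",
    "roi_alignment_summary",
]

APEX = "apex"
RIDGE = "ridge"
PLAIN = "plain"


@dataclass
class InterfaceContour:
    """Ordered dermal-epidermal interface polyline with vertex labels.

    Attributes
    ----------
    vertices
        ``(n, 2)`` array of x/y coordinates in µm, x strictly increasing.
    labels
        Per-vertex label: ``"apex"``, ``"ridge"`` or ``"plain"``.
    width_mm
        Horizontal extent of the measured section in mm.
    """

    vertices: np.ndarray
    labels: list[str] = field(default_factory=list)
    width_mm: float = 0.0

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array")
        if len(self.labels) != len(self.vertices):
            raise ValueError("labels must match vertices in length")
        x = self.vertices[:, 0]
        if np.any(np.diff(x) <= 0):
            raise ValueError("vertex x coordinates must be strictly increasing")
        bad = set(self.labels) - {APEX, RIDGE, PLAIN}
        if bad:
            raise ValueError(f"unknown vertex labels: {sorted(bad)}")
        marks = [l for l in self.labels if l != PLAIN]
        for a, b in zip(marks, marks[1:]):
            if a == b:
                raise ValueError("apex and ridge labels must alternate")
        if APEX in marks and marks.count(RIDGE) < 2:
            raise ValueError("a contour with apexes needs >=2 ridge vertices")

    @property
    def apexes(self) -> np.ndarray:
        idx = [i for i, l in enumerate(self.labels) if l == APEX]
        return self.vertices[idx]

    @property
    def ridges(self) -> np.ndarray:
        idx = [i for i, l in enumerate(self.labels) if l == RIDGE]
        return self.vertices[idx]

    def papilla_triplets(self) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
        """(apex, left ridge, right ridge) for every labelled papilla."""
        marked = [(i, l) for i, l in enumerate(self.labels) if l != PLAIN]
        out = []
        for (i0, l0), (i1, l1), (i2, l2) in zip(marked, marked[1:], marked[2:]):
            if (l0, l1, l2) == (RIDGE, APEX, RIDGE):
                out.append((self.vertices[i1], self.vertices[i0], self.vertices[i2]))
        return out

    def papilla_heights(self) -> np.ndarray:
        return np.array(
            [papilla_height(a, l, r) for a, l, r in self.papilla_triplets()]
        )


def papillae_per_mm(contour: InterfaceContour) -> float:
    """Number of labelled papilla apexes per mm of section width."""
    if contour.width_mm <= 0:
        raise ValueError("section width must be positive")
    return contour.labels.count(APEX) / contour.width_mm


def rete_ridges_per_mm(contour: InterfaceContour) -> float:
    """Number of labelled rete-ridge vertices per mm of section width."""
    if contour.width_mm <= 0:
        raise ValueError("section width must be positive")
    return contour.labels.count(RIDGE) / contour.width_mm


def papilla_height(apex, ridge_left, ridge_right) -> float:
    """Perpendicular distance (µm) from apex to the line through both ridges."""
    apex = np.asarray(apex, dtype=float)
    a = np.asarray(ridge_left, dtype=float)
    b = np.asarray(ridge_right, dtype=float)
    base = b - a
    norm = np.hypot(*base)
    if norm == 0:
        raise ValueError("ridge points coincide; papilla base is undefined")
    cross = base[0] * (apex[1] - a[1]) - base[1] * (apex[0] - a[0])
    return abs(cross) / norm


def normalize_to_baseline(value_followup: float, value_baseline: float) -> float:
    """Fold change of a follow-up measurement over its baseline."""
    if value_baseline <= 0:
        raise ValueError("baseline value must be positive")
    return value_followup / value_baseline


def alignment_coefficient(angles_deg) -> float:
    """Fiber parallelism on a 0-1 scale.

    Computed as the length of the mean resultant vector of the doubled
    angles: ``|mean(exp(2i*theta))|``.  Equals 1 iff all angles are equal
    modulo 180 degrees, and 0 for a balanced isotropic sample.
    """
    theta = np.asarray(angles_deg, dtype=float)
    if theta.size == 0:
        raise ValueError("orientation sample is empty")
    doubled = np.deg2rad(2.0 * theta)
    return float(np.hypot(np.mean(np.cos(doubled)), np.mean(np.sin(doubled))))


def roi_alignment_summary(roi_samples) -> float:
    """Median alignment coefficient across regions of interest."""
    coeffs = [alignment_coefficient(s) for s in roi_samples]
    if not coeffs:
        raise ValueError("no ROI samples provided")
    return float(np.median(coeffs))
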