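"""Synthetic layered skin tissue with known ground truth.

Generates a segmented-cell view of a skin section: an epidermal band bounded
below by a sinusoidal dermal-epidermal interface, a papillary and a reticular
dermal compartment split at a configurable depth from the interface, vessels
planted as elongated Gaussian point clouds at controlled orientations, and
negative-binomial expression counts with per-type marker enrichments and a
per-time-point planted treatment shift.

Coordinate convention: ``y`` increases downward from the tissue surface
(depth), all lengths in µm.  The interface sits at depth
``epidermis_thickness_um + A * sin(2*pi*x / P)``; epidermal cells lie above
it (smaller y), dermal cells below.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.special import erfinv

from .morphometry import APEX, PLAIN, RIDGE, InterfaceContour

__all__ = [
    "VesselSpec",
    "TissueConfig",
    "GroundTruth",
    "generate_tissue",
    "generate_interface_contour",
    "generate_orientation_field",
]

COMPARTMENTS = ("epidermis", "papillary", "reticular")


@dataclass(frozen=True)
class VesselSpec:
    """An elongated endothelial patch planted at a fixed orientation."""

    n_cells: int
    centroid: tuple[float, float]
    orientation_deg: float
    length_um: float
    aspect_ratio: float = 8.0  # long-axis s.d. over short-axis s.d.


@dataclass
class TissueConfig:
    width_um: float = 1000.0
    height_um: float = 500.0
    papilla_amplitude_um: float = 20.0
    papilla_period_um: float = 200.0
    epidermis_thickness_um: float = 50.0
    #: compartment -> {cell type -> count}; drawn exactly, per sample.
    cells_per_type: dict[str, dict[str, int]] = field(default_factory=dict)
    vessel_specs: list[VesselSpec] = field(default_factory=list)
    vessel_type: str = "endothelial"
    nb_mean: float = 2.0
    nb_dispersion: float = 5.0
    #: (cell type, gene) -> log2 enrichment over the baseline mean.
    marker_log2fc: dict[tuple[str, str], float] = field(default_factory=dict)
    #: gene -> log2 shift applied at every non-baseline time point.
    treatment_log2fc: dict[str, float] = field(default_factory=dict)
    timepoints: list[str] = field(default_factory=lambda: ["baseline", "followup"])
    samples_per_timepoint: int = 1
    n_background_genes: int = 20
    n_negctrl: int = 5
    negctrl_rate: float = 0.05
    compartment_border_um: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("width_um", "height_um", "epidermis_thickness_um",
                     "papilla_period_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.papilla_amplitude_um < 0:
            raise ValueError("papilla_amplitude_um must be >= 0")
        if self.papilla_amplitude_um > 0 and self.papilla_period_um >= self.width_um:
            raise ValueError(
                "papilla_period_um must be smaller than width_um when the "
                "interface undulates"
            )
        for comp in self.cells_per_type:
            if comp not in COMPARTMENTS:
                raise ValueError(f"unknown compartment {comp!r}")
            for t, n in self.cells_per_type[comp].items():
                if n < 0:
                    raise ValueError(f"negative count for {comp}/{t}")
        for spec in self.vessel_specs:
            self._check_vessel(spec)

    def _check_vessel(self, spec: VesselSpec) -> None:
        cx, cy = spec.centroid
        half = spec.length_um / 2.0
        if not (half <= cx <= self.width_um - half) or not (
            0 <= cy - half and cy + half <= self.height_um
        ):
            raise ValueError(
                f"vessel at {spec.centroid} with length {spec.length_um} µm "
                f"extends outside the {self.width_um}x{self.height_um} µm tissue"
            )

    def interface_depth(self, x) -> np.ndarray:
        """Depth of the dermal-epidermal interface at horizontal position x."""
        x = np.asarray(x, dtype=float)
        return self.epidermis_thickness_um + self.papilla_amplitude_um * np.sin(
            2.0 * np.pi * x / self.papilla_period_um
        )


@dataclass
class GroundTruth:
    """Planted truth for every generated cell, keyed like the cell table."""

    compartment: pd.Series  # cell_id -> epidermis/papillary/reticular
    distance_um: pd.Series  # cell_id -> true distance to the interface
    papilla_count: int
    papilla_heights: list[float]
    vessels: list[dict]  # {sample, cell_ids, orientation_deg}
    composition: dict[str, dict[str, float]]  # sample -> type -> frequency
    signature_genes: list[str]

    def to_json_dict(self) -> dict:
        return {
            "compartment": self.compartment.to_dict(),
            "distance_um": self.distance_um.to_dict(),
            "papilla_count": self.papilla_count,
            "papilla_heights": self.papilla_heights,
            "vessels": self.vessels,
            "composition": self.composition,
            "signature_genes": self.signature_genes,
        }


def _interface_points(config: TissueConfig, spacing_um: float = 1.0) -> np.ndarray:
    x = np.arange(0.0, config.width_um + spacing_um, spacing_um)
    return np.column_stack([x, config.interface_depth(x)])


def _sample_compartment(
    rng: np.random.Generator,
    config: TissueConfig,
    compartment: str,
    n: int,
    interface_tree: cKDTree,
) -> np.ndarray:
    """Uniform rejection sampling of n points within one compartment."""
    if n == 0:
        return np.empty((0, 2))
    out = []
    need = n
    border = config.compartment_border_um
    while need > 0:
        batch = max(4 * need, 256)
        x = rng.uniform(0.0, config.width_um, batch)
        y = rng.uniform(0.0, config.height_um, batch)
        iface = config.interface_depth(x)
        pts = np.column_stack([x, y])
        if compartment == "epidermis":
            keep = y < iface
        else:
            below = y > iface
            dist, _ = interface_tree.query(pts)
            if compartment == "papillary":
                keep = below & (dist < border)
            else:
                keep = below & (dist >= border)
        got = pts[keep][:need]
        out.append(got)
        need -= len(got)
    return np.vstack(out)


def _vessel_points(rng: np.random.Generator, spec: VesselSpec) -> np.ndarray:
    theta = math.radians(spec.orientation_deg)
    sd_long = spec.length_um / 4.0
    sd_short = max(sd_long / spec.aspect_ratio, 0.25)
    # stratified Gaussian along the axis: same marginal law, but the sample
    # spread of small patches cannot collapse by chance
    n = spec.n_cells
    u = (rng.permutation(n) + rng.uniform(0.0, 1.0, n)) / n
    along = sd_long * np.sqrt(2.0) * erfinv(2.0 * u - 1.0)
    across = rng.normal(0.0, sd_short, n)
    x = spec.centroid[0] + along * math.cos(theta) - across * math.sin(theta)
    y = spec.centroid[1] + along * math.sin(theta) + across * math.cos(theta)
    return np.column_stack([x, y])


def _gene_panel(config: TissueConfig) -> pd.DataFrame:
    genes: list[str] = []
    for (_t, g) in config.marker_log2fc:
        if g not in genes:
            genes.append(g)
    for g in config.treatment_log2fc:
        if g not in genes:
            genes.append(g)
    genes += [f"BG{i:04d}" for i in range(1, config.n_background_genes + 1)]
    ctrl = [f"NegCtrl{i:03d}" for i in range(1, config.n_negctrl + 1)]
    return pd.DataFrame(
        {
            "gene": genes + ctrl,
            "is_negctrl": [False] * len(genes) + [True] * len(ctrl),
        }
    )


def _papilla_truth(config: TissueConfig) -> tuple[int, list[float]]:
    if config.papilla_amplitude_um == 0:
        return 0, []
    # one apex per full sine period, at phase 3/4 (minimum depth)
    count = 0
    x = 0.75 * config.papilla_period_um
    while x < config.width_um:
        count += 1
        x += config.papilla_period_um
    heights = [2.0 * config.papilla_amplitude_um] * count
    return count, heights


def generate_tissue(
    config: TissueConfig,
) -> tuple[pd.DataFrame, tuple[np.ndarray, pd.DataFrame, pd.DataFrame], GroundTruth]:
    """Generate the cell table, expression matrix and ground truth.

    Returns
    -------
    cells : pandas.DataFrame
        Columns ``cell_id, sample, timepoint, x_um, y_um, area_um2, true_type``.
    expression : (counts, genes, cell_index)
        ``counts`` is a dense ``(n_cells, n_features)`` integer array;
        ``genes`` a frame with ``gene`` and ``is_negctrl`` columns;
        ``cell_index`` a frame with a ``cell_id`` column aligned to rows.
    truth : GroundTruth
    """
    rng = np.random.default_rng(config.seed)
    iface_tree = cKDTree(_interface_points(config))
    genes = _gene_panel(config)
    baseline_tp = config.timepoints[0] if config.timepoints else "baseline"

    rows = []
    truth_comp: dict[str, str] = {}
    truth_dist: dict[str, float] = {}
    vessels: list[dict] = []
    composition: dict[str, dict[str, float]] = {}
    cid = 0

    for tp in config.timepoints:
        for rep in range(config.samples_per_timepoint):
            sample = f"{tp}_s{rep + 1}"
            type_counts: dict[str, int] = {}
            for comp in COMPARTMENTS:
                for ctype, n in config.cells_per_type.get(comp, {}).items():
                    pts = _sample_compartment(rng, config, comp, n, iface_tree)
                    for p in pts:
                        cell_id = f"c{cid:06d}"
                        cid += 1
                        rows.append((cell_id, sample, tp, p[0], p[1], ctype))
                        truth_comp[cell_id] = comp
                    type_counts[ctype] = type_counts.get(ctype, 0) + n
            for spec in config.vessel_specs:
                pts = _vessel_points(rng, spec)
                ids = []
                for p in pts:
                    cell_id = f"c{cid:06d}"
                    cid += 1
                    rows.append((cell_id, sample, tp, p[0], p[1], config.vessel_type))
                    ids.append(cell_id)
                vessels.append(
                    {
                        "sample": sample,
                        "cell_ids": ids,
                        "orientation_deg": spec.orientation_deg,
                    }
                )
                type_counts[config.vessel_type] = (
                    type_counts.get(config.vessel_type, 0) + spec.n_cells
                )
            total = sum(type_counts.values())
            composition[sample] = {
                t: n / total for t, n in sorted(type_counts.items())
            } if total else {}

    cells = pd.DataFrame(
        rows, columns=["cell_id", "sample", "timepoint", "x_um", "y_um", "true_type"]
    )
    cells["area_um2"] = np.round(
        rng.lognormal(mean=np.log(80.0), sigma=0.4, size=len(cells)), 3
    )
    cells = cells[
        ["cell_id", "sample", "timepoint", "x_um", "y_um", "area_um2", "true_type"]
    ]

    # ground-truth compartment for vessel cells from their actual position
    pts = cells[["x_um", "y_um"]].to_numpy()
    dist, _ = iface_tree.query(pts)
    below = pts[:, 1] > config.interface_depth(pts[:, 0])
    for i, cell_id in enumerate(cells["cell_id"]):
        truth_dist[cell_id] = float(dist[i])
        if cell_id not in truth_comp:
            if not below[i]:
                truth_comp[cell_id] = "epidermis"
            elif dist[i] < config.compartment_border_um:
                truth_comp[cell_id] = "papillary"
            else:
                truth_comp[cell_id] = "reticular"

    counts = _expression_counts(rng, config, cells, genes, baseline_tp)
    cell_index = cells[["cell_id"]].copy()

    papilla_count, papilla_heights = _papilla_truth(config)
    truth = GroundTruth(
        compartment=pd.Series(truth_comp).loc[cells["cell_id"]],
        distance_um=pd.Series(truth_dist).loc[cells["cell_id"]],
        papilla_count=papilla_count,
        papilla_heights=papilla_heights,
        vessels=vessels,
        composition=composition,
        signature_genes=sorted(config.treatment_log2fc),
    )
    return cells, (counts, genes, cell_index), truth


def _expression_counts(
    rng: np.random.Generator,
    config: TissueConfig,
    cells: pd.DataFrame,
    genes: pd.DataFrame,
    baseline_tp: str,
) -> np.ndarray:
    n_cells = len(cells)
    n_feat = len(genes)
    counts = np.zeros((n_cells, n_feat), dtype=np.int64)
    gene_idx = {g: j for j, g in enumerate(genes["gene"])}
    real = ~genes["is_negctrl"].to_numpy()

    log2fc = np.zeros((n_cells, n_feat))
    types = cells["true_type"].to_numpy()
    treated = (cells["timepoint"] != baseline_tp).to_numpy()
    for (ctype, gene), lfc in config.marker_log2fc.items():
        j = gene_idx[gene]
        log2fc[types == ctype, j] += lfc
    for gene, lfc in config.treatment_log2fc.items():
        j = gene_idx[gene]
        log2fc[treated, j] += lfc

    mu = config.nb_mean * np.power(2.0, log2fc[:, real])
    r = config.nb_dispersion
    p = r / (r + mu)
    counts[:, real] = rng.negative_binomial(r, p)
    counts[:, ~real] = rng.poisson(config.negctrl_rate, (n_cells, int((~real).sum())))
    return counts


def generate_interface_contour(
    n_papillae: int,
    amplitude_um: float,
    period_um: float,
    seed: int = 0,
    vertices_per_papilla: int = 16,
) -> InterfaceContour:
    """Construct a labelled interface polyline with known papillae.

    Rete-ridge vertices sit on a flat base line at depth 0 at multiples of
    the period; each papilla apex rises ``amplitude_um`` above the base
    midway between its two ridges, following a smooth ``sin^2`` profile, so
    every constructed papilla height equals the amplitude exactly.
    The contour carries ``n_papillae`` apex labels and ``n_papillae + 1``
    ridge labels.
    """
    if n_papillae < 0:
        raise ValueError("n_papillae must be >= 0")
    if amplitude_um < 0:
        raise ValueError("amplitude must be >= 0")
    if period_um <= 0:
        raise ValueError("period must be positive")
    del seed  # reserved for future vertex jitter; contour is deterministic

    if n_papillae == 0:
        vertices = np.array([[0.0, 0.0], [period_um, 0.0]])
        return InterfaceContour(vertices, [RIDGE, PLAIN], width_mm=period_um / 1000.0)

    xs: list[float] = []
    ys: list[float] = []
    labels: list[str] = []
    m = vertices_per_papilla
    for k in range(n_papillae):
        for j in range(m):
            x = (k + j / m) * period_um
            # apex displaced -amplitude (toward the epidermis) at mid-period
            y = -amplitude_um * math.sin(math.pi * j / m) ** 2
            xs.append(x)
            ys.append(y)
            if j == 0:
                labels.append(RIDGE)
            elif 2 * j == m:
                labels.append(APEX)
            else:
                labels.append(PLAIN)
    xs.append(n_papillae * period_um)
    ys.append(0.0)
    labels.append(RIDGE)
    if vertices_per_papilla % 2 != 0:
        raise ValueError("vertices_per_papilla must be even to place apexes")
    vertices = np.column_stack([xs, ys])
    return InterfaceContour(vertices, labels, width_mm=n_papillae * period_um / 1000.0)


def generate_orientation_field(
    n: int, kappa: float, mu_deg: float = 90.0, seed: int = 0
) -> np.ndarray:
    """Draw fiber orientations in [0, 180) with controlled parallelism.

    Doubled angles ``2*theta`` follow a von Mises distribution with mean
    ``2*mu_deg`` and concentration ``kappa``; ``kappa = 0`` gives the
    isotropic (uniform) limit.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    rng = np.random.default_rng(seed)
    if kappa == 0:
        doubled = rng.uniform(-np.pi, np.pi, n)
    else:
        doubled = rng.vonmises(0.0, kappa, n)
    theta = (mu_deg + np.rad2deg(doubled) / 2.0) % 180.0
    return theta
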