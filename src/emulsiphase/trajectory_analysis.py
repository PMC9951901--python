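"""Structural observables of spherical droplet configurations.

Given an ensemble of labelled droplet frames, this module computes the
radial probability profile of each species with respect to the oil-core
centre of mass, estimates the core/interface/water region boundaries from
the oleic-acid and water profiles, classifies antioxidant molecules into
regions, measures per-oxygen insertion distances, and characterizes the
antioxidant's orientation at the interface through three angles between the
radial vector R (molecule COM -> droplet COM) and molecular reference
vectors:

* alpha — angle to the para axis O4-C4-C1-C7 (oriented O4 -> C7);
* beta  — angle to the COM -> C6 vector;
* gamma — angle to the aromatic plane, in [0, 90]; gamma = 90 when the ring
  plane is parallel to the droplet surface.

"Probability" profiles are normalized histograms of reference-point
distances (probability per Angstrom), not volume-corrected pair
distributions; a volume-corrected variant is available behind a flag.
Frames are treated as an unordered ensemble — no dynamical observables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .droplet import GAL_LABELS, DropletFrame, DropletTrajectory
from .errors import (
    BoundaryEstimationError,
    EmptyTrajectoryError,
    GeometryError,
    MissingSpeciesError,
    TemplateMismatchError,
)

__all__ = [
    "RadialProfile",
    "RegionBoundaries",
    "OrientationRecord",
    "AngleDistribution",
    "JointAngleDistribution",
    "droplet_com",
    "radial_profile",
    "surfactant_profiles",
    "estimate_regions",
    "region_fractions",
    "oxygen_distances",
    "orientation_angles",
    "orientation_records",
    "angle_distribution",
    "joint_angle_distribution",
]

ANGLE_RANGES = {"alpha": (0.0, 180.0), "beta": (0.0, 180.0), "gamma": (0.0, 90.0)}


@dataclass(frozen=True)
class RadialProfile:
    """Normalized radial probability density of one species."""

    species: str
    bin_edges: np.ndarray  # Angstrom, length n_bins + 1
    density: np.ndarray    # probability per Angstrom, length n_bins
    n_samples: int

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    def mode(self) -> float:
        return float(self.bin_centers[int(np.argmax(self.density))])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "r_lo": self.bin_edges[:-1], "r_hi": self.bin_edges[1:],
            "density_per_A": self.density,
        })


@dataclass(frozen=True)
class RegionBoundaries:
    """Radial boundaries of the oil core and interfacial shell (Angstrom)."""

    core_radius: float
    interface_thickness: float

    def __post_init__(self) -> None:
        if not (0 < self.core_radius < self.water_onset):
            raise BoundaryEstimationError(
                f"invalid boundaries: core={self.core_radius}, "
                f"thickness={self.interface_thickness}"
            )

    @property
    def water_onset(self) -> float:
        return self.core_radius + self.interface_thickness


@dataclass(frozen=True)
class OrientationRecord:
    """Orientation angles of one antioxidant molecule in one frame."""

    frame_index: int
    mol_id: int
    alpha: float  # degrees, [0, 180]
    beta: float   # degrees, [0, 180]
    gamma: float  # degrees, [0, 90]
    com_radius: float  # Angstrom


@dataclass(frozen=True)
class AngleDistribution:
    """Normalized 1-D orientation-angle density with its local maxima."""

    angle: str
    bin_edges: np.ndarray
    density: np.ndarray  # probability per degree
    maxima: tuple[float, ...]

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "angle_lo": self.bin_edges[:-1], "angle_hi": self.bin_edges[1:],
            "density_per_deg": self.density,
        })


@dataclass(frozen=True)
class JointAngleDistribution:
    """Normalized joint (alpha, beta) density with ranked local maxima.

    ``maxima`` are (alpha_center, beta_center, density) triples for bins
    strictly dominating their 8-neighborhood, ranked by density.
    """

    alpha_edges: np.ndarray
    beta_edges: np.ndarray
    density: np.ndarray  # probability per square degree, shape (n_alpha, n_beta)
    maxima: tuple[tuple[float, float, float], ...]


# --------------------------------------------------------------------------
# reference geometry
# --------------------------------------------------------------------------

def droplet_com(frame: DropletFrame) -> np.ndarray:
    """Mass-weighted centre of the oil core (oleic-acid atoms only).

    Using only the oil keeps the reference point independent of how much
    bulk water the box happens to contain.
    """
    m = frame.mask("OLE")
    if not m.any():
        raise MissingSpeciesError("frame contains no oleic-acid atoms")
    w = frame.mass[m]
    return w @ frame.coords[m] / w.sum()


def _reference_radii(frame: DropletFrame, species: str) -> np.ndarray:
    """Distances of the species' per-molecule reference points to the oil COM."""
    center = droplet_com(frame)
    if ":" in species:
        sp, site = species.split(":", 1)
        sel = frame.select(sp, site)
        pts = sel.coords
    elif species == "TW80":
        raise ValueError(
            "surfactant profiles are per reference site: use 'TW80:RNG', "
            "'TW80:EOH' or 'TW80:TAIL' (or surfactant_profiles())"
        )
    else:
        pts = frame.molecule_coms(species)
    return np.linalg.norm(pts - center, axis=1)


def radial_profile(
    traj: DropletTrajectory,
    species: str,
    bin_width: float = 1.0,
    r_max: float | None = None,
    volume_corrected: bool = False,
) -> RadialProfile:
    """Pooled radial probability density of one species over all frames.

    Reference points are molecule COMs (oleic acid, gallic acid, water) or a
    single surfactant site selected as ``"TW80:RNG"`` etc.  ``volume_corrected``
    divides each bin by its shell volume before renormalizing (a number-density
    profile up to a constant); default is the raw per-Angstrom histogram.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    radii = np.concatenate([_reference_radii(fr, species) for fr in traj])
    if radii.size == 0:
        raise MissingSpeciesError(f"no reference points for species {species!r}")
    top = r_max if r_max is not None else float(radii.max())
    n_bins = max(1, int(np.ceil(top / bin_width + 1e-9)))
    edges = bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(radii, bins=edges)
    density = counts / (radii.size * bin_width)
    if volume_corrected:
        centers = 0.5 * (edges[:-1] + edges[1:])
        shell = 4.0 * np.pi * centers**2
        density = density / shell
        density = density / (density.sum() * bin_width)
    return RadialProfile(species, edges, density, int(radii.size))


def surfactant_profiles(
    traj: DropletTrajectory, bin_width: float = 1.0, r_max: float | None = None
) -> dict[str, RadialProfile]:
    """Radial profiles of the three surfactant reference sites, separately."""
    return {
        site: radial_profile(traj, f"TW80:{site}", bin_width, r_max)
        for site in ("RNG", "EOH", "TAIL")
    }


# --------------------------------------------------------------------------
# regions
# --------------------------------------------------------------------------

def estimate_regions(
    oleic: RadialProfile,
    water: RadialProfile,
    core_cut: float = 0.95,
    bulk_cut: float = 0.90,
    plateau_fraction: float = 0.20,
) -> RegionBoundaries:
    """Locate the oil-core radius and interfacial thickness from profiles.

    The core radius is the first bin edge at which the oleic cumulative
    distribution strictly exceeds ``core_cut`` (so a sharp-edged core whose
    cumulative touches the cut exactly at an interior edge still reports its
    full support).  The water onset is the left edge of
    the first bin whose density reaches ``bulk_cut`` of the bulk plateau,
    the plateau being the mean density over the outer ``plateau_fraction``
    of bins.  Raises when the water profile is still rising at the box edge
    (no plateau to calibrate against).
    """
    if not (0 < core_cut < 1 and 0 < bulk_cut < 1):
        raise ValueError("core_cut and bulk_cut must lie in (0, 1)")
    cum = np.cumsum(oleic.density) * oleic.bin_width
    idx = np.nonzero(cum > core_cut + 1e-12)[0]
    if idx.size == 0:
        raise BoundaryEstimationError("oleic cumulative never reaches core_cut")
    core_radius = float(oleic.bin_edges[idx[0] + 1])

    n = water.density.size
    k = max(3, int(np.ceil(plateau_fraction * n)))
    outer = water.density[-k:]
    plateau = float(outer.mean())
    if plateau <= 0:
        raise BoundaryEstimationError("water profile vanishes near the box edge")
    # linear trend across the outer window: a rising profile has no plateau yet
    x = np.arange(k, dtype=float)
    slope = float(np.polyfit(x, outer, 1)[0])
    if slope * k > 0.15 * plateau:
        raise BoundaryEstimationError(
            "water profile still rising at the box edge; no bulk plateau detected"
        )
    hit = np.nonzero(water.density >= bulk_cut * plateau)[0]
    if hit.size == 0:
        raise BoundaryEstimationError("water density never reaches the plateau cut")
    water_onset = float(water.bin_edges[hit[0]])
    return RegionBoundaries(core_radius, water_onset - core_radius)


def region_fractions(
    traj: DropletTrajectory,
    boundaries: RegionBoundaries,
    species: str = "GAL",
) -> tuple[float, float, float]:
    """Percentage of molecules in the oil core, interface and bulk water.

    Molecule COM radii are classified into [0, core), [core, onset) and
    [onset, inf) per frame; per-frame percentages are averaged over frames.
    The three percentages sum to 100.
    """
    if len(traj) == 0:
        raise EmptyTrajectoryError("empty trajectory")
    pcts = np.zeros(3)
    for fr in traj:
        r = _reference_radii(fr, species)
        n = r.size
        in_core = np.count_nonzero(r < boundaries.core_radius)
        in_interf = np.count_nonzero(
            (r >= boundaries.core_radius) & (r < boundaries.water_onset))
        pcts += 100.0 / n * np.array([in_core, in_interf, n - in_core - in_interf])
    pcts /= len(traj)
    return float(pcts[0]), float(pcts[1]), float(pcts[2])


# --------------------------------------------------------------------------
# insertion depth per oxygen
# --------------------------------------------------------------------------

def oxygen_distances(traj: DropletTrajectory) -> pd.DataFrame:
    """Mean and sd distance of each gallic-acid oxygen to the droplet COM.

    Pooled over molecules and frames; rows indexed O0..O4.  The ordering of
    the means reveals the tilt of the molecule: hydroxyl oxygens pointing at
    the core sit closer than the carboxyl oxygens.
    """
    labels = ("O0", "O1", "O2", "O3", "O4")
    pools: dict[str, list[np.ndarray]] = {l: [] for l in labels}
    for fr in traj:
        center = droplet_com(fr)
        gal = fr.mask("GAL")
        if not gal.any():
            raise MissingSpeciesError("no gallic acid in frame")
        present = set(fr.label[gal].tolist())
        missing = set(labels) - present
        if missing:
            raise TemplateMismatchError(f"gallic acid lacks oxygen labels {sorted(missing)}")
        for l in labels:
            sel = gal & (fr.label == l)
            pools[l].append(np.linalg.norm(fr.coords[sel] - center, axis=1))
    rows = []
    for l in labels:
        d = np.concatenate(pools[l])
        rows.append({"oxygen": l, "mean_A": float(d.mean()),
                     "sd_A": float(d.std(ddof=0)), "n": int(d.size)})
    return pd.DataFrame(rows).set_index("oxygen")


# --------------------------------------------------------------------------
# orientation angles
# --------------------------------------------------------------------------

def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    c = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def _tls_axis(points: np.ndarray) -> np.ndarray:
    """First principal axis of a point set (total least squares line)."""
    centered = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return vt[0]


def _ring_normal(points: np.ndarray) -> np.ndarray:
    """Unit normal of the least-squares plane through the ring carbons."""
    centered = points - points.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise GeometryError("ring atoms are collinear; plane undefined")
    return vt[2]


def orientation_angles(
    frame: DropletFrame, mol_id: int, frame_index: int = 0
) -> OrientationRecord:
    """Compute (alpha, beta, gamma) for one gallic-acid molecule.

    R is the vector from the molecule COM to the droplet COM.  The para
    axis is the total-least-squares line through O4, C4, C1, C7 oriented
    O4 -> C7; gamma is folded to [0, 90] because the plane is unsigned.
    """
    sel = frame.mask("GAL") & (frame.mol_id == mol_id)
    if not sel.any():
        raise MissingSpeciesError(f"no gallic-acid molecule with id {mol_id}")
    labels = frame.label[sel]
    xyz = frame.coords[sel]
    masses = frame.mass[sel]
    have = {str(l): i for i, l in enumerate(labels)}
    missing = set(GAL_LABELS) - set(have)
    if missing:
        raise TemplateMismatchError(f"molecule {mol_id} lacks labels {sorted(missing)}")

    com = masses @ xyz / masses.sum()
    r_vec = droplet_com(frame) - com
    if np.linalg.norm(r_vec) < 1e-9:
        raise GeometryError("molecule COM coincides with the droplet COM")

    axis_pts = xyz[[have[l] for l in ("O4", "C4", "C1", "C7")]]
    a_vec = _tls_axis(axis_pts)
    if np.dot(a_vec, xyz[have["C7"]] - xyz[have["O4"]]) < 0:
        a_vec = -a_vec
    alpha = _angle_deg(r_vec, a_vec)

    beta = _angle_deg(r_vec, xyz[have["C6"]] - com)

    ring = xyz[[have[f"C{i}"] for i in range(1, 7)]]
    normal = _ring_normal(ring)
    ang_n = _angle_deg(r_vec, normal)
    gamma = 90.0 - min(ang_n, 180.0 - ang_n)

    return OrientationRecord(frame_index, int(mol_id), alpha, beta, gamma,
                             float(np.linalg.norm(r_vec)))


def orientation_records(traj: DropletTrajectory) -> list[OrientationRecord]:
    """Orientation angles for every gallic-acid molecule in every frame."""
    out: list[OrientationRecord] = []
    for i, fr in enumerate(traj):
        for mol in fr.molecule_ids("GAL"):
            out.append(orientation_angles(fr, int(mol), i))
    if not out:
        raise EmptyTrajectoryError("no gallic-acid molecules in trajectory")
    return out


# --------------------------------------------------------------------------
# angle histograms
# --------------------------------------------------------------------------

def _local_maxima_1d(density: np.ndarray, centers: np.ndarray) -> tuple[float, ...]:
    out = []
    for i, d in enumerate(density):
        left = density[i - 1] if i > 0 else -np.inf
        right = density[i + 1] if i < density.size - 1 else -np.inf
        if d > left and d > right and d > 0:
            out.append(float(centers[i]))
    return tuple(out)


def angle_distribution(
    traj: DropletTrajectory, angle: str, bin_width: float = 3.0
) -> AngleDistribution:
    """Pooled, unit-integral histogram of one orientation angle.

    Default 3-degree bins put every half-degree bin centre (1.5, 4.5, ...)
    on the reporting grid.  Maxima are centres of bins exceeding both
    neighbors.
    """
    if angle not in ANGLE_RANGES:
        raise ValueError(f"angle must be one of {sorted(ANGLE_RANGES)}")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lo, hi = ANGLE_RANGES[angle]
    values = np.array([getattr(r, angle) for r in orientation_records(traj)])
    n_bins = int(np.ceil((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(np.clip(values, lo, hi - 1e-12), bins=edges)
    density = counts / (values.size * bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return AngleDistribution(angle, edges, density,
                             _local_maxima_1d(density, centers))


def joint_angle_distribution(
    traj: DropletTrajectory, bin_width: float = 3.0
) -> JointAngleDistribution:
    """Joint (alpha, beta) density with ranked 8-neighborhood maxima."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    recs = orientation_records(traj)
    alpha = np.array([r.alpha for r in recs])
    beta = np.array([r.beta for r in recs])
    n_bins = int(np.ceil(180.0 / bin_width))
    edges = bin_width * np.arange(n_bins + 1)
    counts, _, _ = np.histogram2d(
        np.clip(alpha, 0, 180 - 1e-12), np.clip(beta, 0, 180 - 1e-12),
        bins=(edges, edges))
    density = counts / (alpha.size * bin_width**2)
    centers = 0.5 * (edges[:-1] + edges[1:])

    padded = np.full((n_bins + 2, n_bins + 2), -np.inf)
    padded[1:-1, 1:-1] = density
    maxima = []
    for i in range(n_bins):
        for j in range(n_bins):
            d = density[i, j]
            if d <= 0:
                continue
            nb = padded[i:i + 3, j:j + 3].copy()
            nb[1, 1] = -np.inf
            if d > nb.max():
                maxima.append((float(centers[i]), float(centers[j]), float(d)))
    maxima.sort(key=lambda t: -t[2])
    return JointAngleDistribution(edges, edges.copy(), density, tuple(maxima))
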