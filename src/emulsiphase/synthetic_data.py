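"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators emulate the data a wet lab and an MD engine would supply:

* a spherical oil-in-water droplet builder — a dense oleic-acid core
  (~20 Angstrom radius), a surfactant shell whose three reference sites
  (sorbitan ring, ethylene-oxide hydroxyl termini, oleate tail) reproduce
  the layering of polysorbate 80 at the interface, bulk water beyond, and
  rigid gallic-acid molecules placed with prescribed radial and
  orientation-angle laws;
* observed-rate-constant series drawn from the pseudophase rate law with
  multiplicative noise;
* two-phase (lag -> propagation) lipid-oxidation curves integrated from a
  mass-action initiation / propagation / termination / inhibition scheme.

All generators are deterministic given their seed.  Geometry note: the
builder emulates *radial structure*, not molecular packing — water radii are
drawn with uniform radial density so the per-Angstrom radial histogram (the
default profile normalization downstream) is flat in bulk, and oleic-acid
sites are volume-uniform within the core.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from ._rng import rng_for
from .droplet import SPECIES_MASSES, DropletFrame, DropletTrajectory
from .emulsion_model import EmulsionComposition, KobsSeries, predict_kobs
from .errors import (
    EmptyTrajectoryError,
    GeometryError,
    InsufficientDataError,
    SolverError,
)
from .oxidation_kinetics import OxidationCurve

__all__ = [
    "Law",
    "AngleLaws",
    "SpeciesSpec",
    "GallicAcidTemplate",
    "KineticSchemeParams",
    "build_droplet",
    "sample_trajectory",
    "generate_kobs_series",
    "simulate_oxidation",
    "piecewise_linear_curve",
]


# --------------------------------------------------------------------------
# distribution descriptors
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Law:
    """One-dimensional sampling law: gaussian, uniform-shell or delta.

    ``gaussian`` takes (mean, sd); ``uniform-shell`` (low, high); ``delta``
    (value).  Samples are rejection-truncated to the legal range of the
    quantity being drawn.
    """

    family: str
    mean: float = 0.0
    sd: float = 1.0
    low: float = 0.0
    high: float = 1.0
    value: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "uniform-shell", "delta"):
            raise ValueError(f"unknown law family {self.family!r}")
        if self.family == "gaussian" and self.sd < 0:
            raise ValueError("gaussian sd must be non-negative")
        if self.family == "uniform-shell" and self.high < self.low:
            raise ValueError("uniform-shell requires high >= low")

    @classmethod
    def gaussian(cls, mean: float, sd: float) -> "Law":
        return cls("gaussian", mean=mean, sd=sd)

    @classmethod
    def uniform(cls, low: float, high: float) -> "Law":
        return cls("uniform-shell", low=low, high=high)

    @classmethod
    def delta(cls, value: float) -> "Law":
        return cls("delta", value=value)

    def sample(self, rng: np.random.Generator, n: int,
               lo: float = -np.inf, hi: float = np.inf) -> np.ndarray:
        if self.family == "delta":
            if not (lo <= self.value <= hi):
                raise ValueError(f"delta value {self.value} outside [{lo}, {hi}]")
            return np.full(n, float(self.value))
        if self.family == "uniform-shell":
            if self.low < lo or self.high > hi:
                raise ValueError("uniform-shell bounds outside the legal range")
            return rng.uniform(self.low, self.high, n)
        out = rng.normal(self.mean, self.sd, n)
        bad = (out < lo) | (out > hi)
        tries = 0
        while bad.any():  # rejection truncation
            out[bad] = rng.normal(self.mean, self.sd, int(bad.sum()))
            bad = (out < lo) | (out > hi)
            tries += 1
            if tries > 1000:
                raise ValueError("gaussian law lies essentially outside the legal range")
        return out


@dataclass(frozen=True)
class AngleLaws:
    """Orientation-angle laws for the antioxidant placements.

    A rigid orientation has three degrees of freedom, and the radial
    direction expressed in the molecular body frame fixes alpha, beta and
    gamma simultaneously (the spin about the radial vector changes none of
    them), so the three angles cannot be imposed independently.  Modes:

    * ``components`` given — a mixture over joint (alpha, beta) laws; per
      molecule one component is drawn, then (alpha, beta), and gamma is
      implied by the molecular geometry;
    * else ``alpha`` and ``beta`` given — one joint draw, gamma implied;
    * else ``gamma`` given — gamma realized exactly, in-plane azimuth
      uniform, alpha/beta implied;
    * all ``None`` — isotropic random orientation.

    Infeasible (alpha, beta) pairs (impossible for the rigid template) are
    rejection-resampled.
    """

    alpha: Law | None = None
    beta: Law | None = None
    gamma: Law | None = None
    components: tuple[tuple[float, Law, Law], ...] | None = None  # (weight, alpha, beta)


# --------------------------------------------------------------------------
# gallic acid rigid template
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GallicAcidTemplate:
    """Idealized heavy-atom gallic-acid geometry in a planar body frame.

    Ring carbons C1..C6 on a regular hexagon (z = 0), carboxyl carbon C7 on
    the C4->C1 extension, carboxyl oxygens O1/O2 flanking C7, hydroxyl
    oxygens O0 (meta, on C3), O3 (meta, on C5) and O4 (para, on C4).  The
    para axis O4-C4-C1-C7 is exactly collinear.  Bond lengths are idealized
    (aromatic C-C 1.39, C-O 1.36, C-C7 1.50, carboxyl C-O 1.25 Angstrom);
    only relative geometry matters downstream.
    """

    labels: tuple[str, ...]
    coords: np.ndarray  # (12, 3), Angstrom, COM *not* at origin
    masses: np.ndarray

    @classmethod
    def ideal(cls) -> "GallicAcidTemplate":
        rc, ro, rc7, rcoo = 1.39, 1.36, 1.50, 1.25
        ang = {f"C{i}": math.radians(60.0 * (i - 1)) for i in range(1, 7)}
        pos: dict[str, np.ndarray] = {}
        for lbl, a in ang.items():
            pos[lbl] = np.array([rc * math.cos(a), rc * math.sin(a), 0.0])
        pos["C7"] = pos["C1"] + np.array([rc7, 0.0, 0.0])
        pos["O4"] = pos["C4"] - np.array([ro, 0.0, 0.0])       # para hydroxyl
        for lbl, src in (("O0", "C3"), ("O3", "C5")):          # meta hydroxyls
            u = pos[src] / np.linalg.norm(pos[src])
            pos[lbl] = pos[src] + ro * u
        for lbl, s in (("O1", 1.0), ("O2", -1.0)):             # carboxyl oxygens
            a = math.radians(60.0)
            pos[lbl] = pos["C7"] + rcoo * np.array([math.cos(a), s * math.sin(a), 0.0])
        labels = ("C1", "C2", "C3", "C4", "C5", "C6", "C7",
                  "O0", "O1", "O2", "O3", "O4")
        coords = np.array([pos[l] for l in labels])
        masses = np.array([SPECIES_MASSES[("GAL", l)] for l in labels])
        return cls(labels, coords, masses)

    @property
    def com(self) -> np.ndarray:
        return self.masses @ self.coords / self.masses.sum()

    def centered(self) -> np.ndarray:
        """Coordinates with the centre of mass at the origin."""
        return self.coords - self.com

    # body-frame reference vectors -----------------------------------------
    @property
    def a_axis(self) -> np.ndarray:
        """Unit vector of the para axis, oriented O4 -> C7."""
        i4, i7 = self.labels.index("O4"), self.labels.index("C7")
        v = self.coords[i7] - self.coords[i4]
        return v / np.linalg.norm(v)

    @property
    def b_axis(self) -> np.ndarray:
        """Unit vector from the COM to C6."""
        v = self.coords[self.labels.index("C6")] - self.com
        return v / np.linalg.norm(v)

    @property
    def normal(self) -> np.ndarray:
        """Unit normal of the aromatic plane (body frame: +z)."""
        return np.array([0.0, 0.0, 1.0])


# --------------------------------------------------------------------------
# droplet spec
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SpeciesSpec:
    """Composition and generative laws of one synthetic droplet.

    Defaults mirror the reference formulation: 200 oleic acid, 20
    polysorbate 80 and 8 gallic-acid molecules with 33,804 water sites, an
    oil core of radius 20 Angstrom and a 17 Angstrom interfacial shell;
    gallic-acid radii Gaussian with the observed 31 Angstrom mode (sd 6
    Angstrom, chosen so the core/interface/water occupancy is close to the
    reported ~79/19/<2 split), and a two-component joint (alpha, beta)
    orientation mixture centred on the two reported orientational maxima.
    """

    n_oleic: int = 200
    n_surfactant: int = 20
    n_antioxidant: int = 8
    n_water: int = 33804
    core_radius: float = 20.0
    interface_thickness: float = 17.0
    water_extent: float = 23.0  # bulk-water shell thickness beyond the interface
    antioxidant_radial_law: Law = field(default_factory=lambda: Law.gaussian(31.0, 6.0))
    antioxidant_angle_laws: AngleLaws = field(
        default_factory=lambda: AngleLaws(
            components=(
                (0.5, Law.gaussian(55.5, 12.0), Law.gaussian(64.5, 12.0)),
                (0.5, Law.gaussian(82.5, 12.0), Law.gaussian(154.5, 12.0)),
            )
        )
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_oleic, self.n_surfactant, self.n_antioxidant, self.n_water) < 0:
            raise GeometryError("species counts must be non-negative")
        if self.core_radius <= 0 or self.interface_thickness <= 0:
            raise GeometryError("core_radius and interface_thickness must be positive")
        if self.water_extent <= 0:
            raise GeometryError(
                "water_extent must be positive: the interfacial shell would reach "
                "the box bound and leave no bulk water"
            )

    @property
    def water_onset(self) -> float:
        return self.core_radius + self.interface_thickness

    @property
    def box_bound(self) -> float:
        return self.water_onset + self.water_extent


# --------------------------------------------------------------------------
# rotation helpers
# --------------------------------------------------------------------------

def _unit_sphere(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector a onto unit vector b (Rodrigues)."""
    c = float(np.dot(a, b))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:  # antipodal: rotate pi about any axis orthogonal to a
        axis = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-9:
            axis = np.cross(a, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        return _axis_rotation(axis, math.pi)
    axis = np.cross(a, b)
    s = np.linalg.norm(axis)
    axis = axis / s
    return _axis_rotation(axis, math.atan2(s, c))


def _axis_rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    x, y, z = axis
    k = np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])
    return np.eye(3) + math.sin(angle) * k + (1.0 - math.cos(angle)) * (k @ k)


def _radial_body_vector(
    template: GallicAcidTemplate,
    laws: AngleLaws,
    rng: np.random.Generator,
    max_tries: int = 10000,
) -> np.ndarray:
    """Draw the droplet-pointing radial direction in the molecular body frame.

    The returned unit vector v satisfies angle(v, a_axis) = alpha and
    angle(v, b_axis) = beta for draws from the configured laws (gamma is
    then implied), or realizes gamma exactly in gamma mode.
    """
    a_hat = template.a_axis
    b_hat = template.b_axis
    n_hat = template.normal
    c_ab = float(np.dot(a_hat, b_hat))
    s_ab = math.sqrt(max(0.0, 1.0 - c_ab * c_ab))
    c_hat = (b_hat - c_ab * a_hat) / s_ab  # in-plane, orthogonal to a_hat

    if laws.components is None and laws.alpha is None and laws.beta is None \
            and laws.gamma is not None:
        gamma = math.radians(float(laws.gamma.sample(rng, 1, 0.0, 90.0)[0]))
        psi = rng.uniform(0.0, 2.0 * math.pi)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        return (math.cos(gamma) * (math.cos(psi) * a_hat + math.sin(psi) * c_hat)
                + sign * math.sin(gamma) * n_hat)

    # single-angle modes: realize the one constrained angle, uniform azimuth
    # about the corresponding reference vector
    if laws.components is None and (laws.alpha is None) != (laws.beta is None):
        law, ref = ((laws.alpha, a_hat) if laws.alpha is not None
                    else (laws.beta, b_hat))
        theta = math.radians(float(law.sample(rng, 1, 0.0, 180.0)[0]))
        perp = c_hat if ref is a_hat else (a_hat - c_ab * b_hat) / s_ab
        perp2 = np.cross(ref, perp)
        psi = rng.uniform(0.0, 2.0 * math.pi)
        return (math.cos(theta) * ref
                + math.sin(theta) * (math.cos(psi) * perp + math.sin(psi) * perp2))

    if laws.components is not None:
        weights = np.array([w for w, _, _ in laws.components], float)
        weights = weights / weights.sum()
    for _ in range(max_tries):
        if laws.components is not None:
            i = int(rng.choice(len(laws.components), p=weights))
            _, alpha_law, beta_law = laws.components[i]
        elif laws.alpha is not None and laws.beta is not None:
            alpha_law, beta_law = laws.alpha, laws.beta
        else:  # isotropic
            return _unit_sphere(rng, 1)[0]
        alpha = math.radians(float(alpha_law.sample(rng, 1, 0.0, 180.0)[0]))
        beta = math.radians(float(beta_law.sample(rng, 1, 0.0, 180.0)[0]))
        x = math.cos(alpha)
        y = (math.cos(beta) - c_ab * x) / s_ab
        z2 = 1.0 - x * x - y * y
        if z2 < -1e-12:
            continue  # geometrically infeasible pair; redraw
        z = math.sqrt(max(0.0, z2))
        if rng.random() < 0.5:
            z = -z
        return x * a_hat + y * c_hat + z * n_hat
    raise GeometryError("could not draw a feasible (alpha, beta) pair for the template")


# --------------------------------------------------------------------------
# droplet builder
# --------------------------------------------------------------------------

_TW80_SITES = (("TAIL", -3.0), ("RNG", 2.0))  # radial offsets from the core surface


def _build_frame(spec: SpeciesSpec, rng: np.random.Generator,
                 template: GallicAcidTemplate) -> DropletFrame:
    species: list[str] = []
    mol_id: list[int] = []
    label: list[str] = []
    coords: list[np.ndarray] = []
    mass: list[float] = []
    next_mol = 0

    def add(sp: str, mol: int, lbl: str, xyz: np.ndarray) -> None:
        species.append(sp)
        mol_id.append(mol)
        label.append(lbl)
        coords.append(xyz)
        mass.append(SPECIES_MASSES[(sp, lbl)])

    # oleic acid: volume-uniform sites inside the core sphere, recentred so
    # the empirical oil COM (the analysis reference point) sits exactly at
    # the origin — placement laws for the other species are then exact
    if spec.n_oleic:
        r = spec.core_radius * rng.random(spec.n_oleic) ** (1.0 / 3.0)
        u = _unit_sphere(rng, spec.n_oleic)
        pts = r[:, None] * u
        pts -= pts.mean(axis=0)
        for i in range(spec.n_oleic):
            add("OLE", next_mol, "COM", pts[i])
            next_mol += 1

    # surfactant: three reference sites along one radial direction per molecule
    if spec.n_surfactant:
        u = _unit_sphere(rng, spec.n_surfactant)
        for i in range(spec.n_surfactant):
            for lbl, off in _TW80_SITES:
                rr = spec.core_radius + off + rng.normal(0.0, 0.8)
                add("TW80", next_mol, lbl, max(rr, 0.1) * u[i])
            rr = spec.water_onset - 2.0 + rng.normal(0.0, 0.8)
            add("TW80", next_mol, "EOH", max(rr, 0.1) * u[i])
            next_mol += 1

    # antioxidant: rigid-body placements of the gallic acid template
    if spec.n_antioxidant:
        radii = spec.antioxidant_radial_law.sample(
            rng, spec.n_antioxidant, 0.0, spec.box_bound)
        u = _unit_sphere(rng, spec.n_antioxidant)  # outward COM directions
        body = template.centered()
        for i in range(spec.n_antioxidant):
            inward = -u[i]  # radial vector points from the molecule to the droplet COM
            v_body = _radial_body_vector(template, spec.antioxidant_angle_laws, rng)
            rot = _rotation_between(v_body, inward)
            rot = _axis_rotation(inward, rng.uniform(0.0, 2.0 * math.pi)) @ rot
            placed = body @ rot.T + radii[i] * u[i]
            for lbl, xyz in zip(template.labels, placed):
                add("GAL", next_mol, lbl, xyz)
            next_mol += 1

    # water: uniform radial density in the bulk shell (flat per-Angstrom profile)
    if spec.n_water:
        r = rng.uniform(spec.water_onset, spec.box_bound, spec.n_water)
        u = _unit_sphere(rng, spec.n_water)
        for i in range(spec.n_water):
            add("HOH", next_mol, "O", r[i] * u[i])
            next_mol += 1

    return DropletFrame(np.array(species, dtype=object), np.array(mol_id),
                        np.array(label, dtype=object), np.array(coords),
                        np.array(mass))


def build_droplet(spec: SpeciesSpec,
                  template: GallicAcidTemplate | None = None) -> DropletFrame:
    """Build one droplet configuration; deterministic given ``spec.seed``."""
    template = template or GallicAcidTemplate.ideal()
    return _build_frame(spec, rng_for(spec.seed, "droplet-frame-0"), template)


def sample_trajectory(spec: SpeciesSpec, n_frames: int,
                      template: GallicAcidTemplate | None = None) -> DropletTrajectory:
    """Independent per-frame draws from the same generative laws."""
    if n_frames < 1:
        raise EmptyTrajectoryError("n_frames must be at least 1")
    template = template or GallicAcidTemplate.ideal()
    frames = [
        _build_frame(spec, rng_for(spec.seed, f"droplet-frame-{i}"), template)
        for i in range(n_frames)
    ]
    return DropletTrajectory(frames)


# --------------------------------------------------------------------------
# kinetic series generator
# --------------------------------------------------------------------------

def generate_kobs_series(
    p_wi: float,
    k_i: float,
    ao_total: float,
    phi_oil: float,
    phi_list: Sequence[float],
    noise_cv: float = 0.0,
    seed: int = 0,
) -> KobsSeries:
    """Noisy observed-rate-constant series from the pseudophase rate law.

    k_obs = model * (1 + eps) with eps ~ Normal(0, noise_cv), redrawn until
    every k_obs is positive.
    """
    if len(phi_list) == 0:
        raise InsufficientDataError("phi_list must not be empty")
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    phi = np.asarray(phi_list, float)
    clean = np.array([
        predict_kobs(p_wi, k_i, ao_total, EmulsionComposition.from_phi(phi_oil, f))
        for f in phi
    ])
    if noise_cv == 0:
        return KobsSeries(phi, clean, ao_total, phi_oil)
    rng = rng_for(seed, "kobs-noise")
    eps = rng.normal(0.0, noise_cv, phi.size)
    bad = 1.0 + eps <= 0
    while bad.any():
        eps[bad] = rng.normal(0.0, noise_cv, int(bad.sum()))
        bad = 1.0 + eps <= 0
    return KobsSeries(phi, clean * (1.0 + eps), ao_total, phi_oil)


# --------------------------------------------------------------------------
# oxidation simulator
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class KineticSchemeParams:
    """Mass-action parameters of the oxidation scheme (hours, mol/L).

    Steps: initiation (constant radical influx ``r_init``), propagation
    ROO. + RH -> ROOH + R. with the alkyl -> peroxyl oxygen addition taken
    as instantaneous (``k_prop``), radical-radical termination (``k_term``),
    and inhibition ArOH + ROO. -> ROOH + ArO. (``k_inh``), each antioxidant
    molecule trapping ``n_stoich`` radicals.  Defaults give a lipid pool of
    0.32 M (10 % v/v oleic oil), 1e-4 M antioxidant and an antioxidant
    depletion time n*[AOH]_0/r_init of about 30 h.
    """

    r_init: float = 6.7e-6    # M/h
    k_prop: float = 200.0     # 1/(M h)
    k_term: float = 1.0e6     # 1/(M h)
    k_inh: float = 1.0e7      # 1/(M h)
    rh0: float = 0.32         # M
    aoh0: float = 1.0e-4      # M
    n_stoich: float = 2.0

    def __post_init__(self) -> None:
        if min(self.r_init, self.k_prop, self.k_term, self.k_inh) < 0:
            raise ValueError("rate parameters must be non-negative")
        if min(self.rh0, self.aoh0) < 0:
            raise ValueError("initial concentrations must be non-negative")
        if self.n_stoich <= 0:
            raise ValueError("n_stoich must be positive")

    @property
    def depletion_time(self) -> float | None:
        """Approximate antioxidant-depletion time n*[AOH]_0/r_init (h)."""
        if self.aoh0 > 0 and self.r_init > 0 and self.k_inh > 0:
            return self.n_stoich * self.aoh0 / self.r_init
        return None


def simulate_oxidation(
    params: KineticSchemeParams,
    t_grid: Sequence[float],
    signal_scale: float = 1.0,
    return_states: bool = False,
):
    """Integrate the oxidation scheme; signal = hydroperoxide * scale.

    State vector [ROO., ROOH, ArOH, RH]; conjugated dienes are taken
    proportional to cumulative hydroperoxide.  With antioxidant present the
    curve shows a lag ending near the depletion time; without, none.
    Returns an :class:`OxidationCurve` (plus the state matrix when
    ``return_states``).
    """
    t = np.asarray(t_grid, float)
    if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be a strictly increasing 1-D array")
    p = params

    def rhs(_t: float, y: np.ndarray) -> list[float]:
        roo, _rooh, aoh, rh = np.maximum(y, 0.0)
        prop = p.k_prop * rh * roo
        inh = p.k_inh * aoh * roo
        return [
            p.r_init - 2.0 * p.k_term * roo * roo - inh,
            prop + inh,
            -inh / p.n_stoich,
            -prop,
        ]

    sol = solve_ivp(rhs, (t[0], t[-1]), [0.0, 0.0, p.aoh0, p.rh0],
                    t_eval=t, method="LSODA", rtol=1e-8,
                    atol=[1e-14, 1e-12, 1e-12, 1e-10])
    if not sol.success:
        raise SolverError(f"oxidation ODE failed: {sol.message}; params={p!r}")
    signal = signal_scale * sol.y[1]
    label = "antioxidant" if p.aoh0 > 0 and p.k_inh > 0 else "control"
    curve = OxidationCurve(t, signal, label=label,
                           true_induction_time=p.depletion_time)
    if return_states:
        return curve, sol.y.T
    return curve


def piecewise_linear_curve(
    tau: float,
    t_max: float,
    n_points: int = 40,
    lag_slope: float = 0.001,
    prop_slope: float = 0.05,
    baseline: float = 0.2,
    noise_sd: float = 0.0,
    seed: int = 0,
    label: str = "",
) -> OxidationCurve:
    """Two-segment piecewise-linear oxidation curve with a known breakpoint.

    Useful as ground truth for the induction-time extractor: the lag line
    (slope ``lag_slope``) meets the propagation line (slope ``prop_slope``)
    exactly at t = ``tau``.
    """
    if not (0 < tau < t_max):
        raise ValueError("tau must lie strictly inside (0, t_max)")
    t = np.linspace(0.0, t_max, n_points)
    y = np.where(t <= tau,
                 baseline + lag_slope * t,
                 baseline + lag_slope * tau + prop_slope * (t - tau))
    if noise_sd > 0:
        y = y + rng_for(seed, "piecewise-noise").normal(0.0, noise_sd, t.size)
    return OxidationCurve(t, y, label=label, true_induction_time=tau)
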