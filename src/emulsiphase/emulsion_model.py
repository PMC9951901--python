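"""Pseudophase kinetic model of antioxidant partitioning in O/W emulsions.

An oil-in-water emulsion is treated as three notional pseudophases — oil,
interfacial and aqueous — in dynamic equilibrium.  For a water-soluble,
oil-insoluble antioxidant (the case of gallic acid) a single partition
constant describes its distribution between the aqueous and interfacial
regions,

    P_W^I = (AO_I) / (AO_W),

where parentheses denote *effective* concentrations: moles of antioxidant in
a region per litre of that region's volume.  The observed rate constant of a
probe reaction run at several surfactant volume fractions Phi_I obeys

    k_obs = [AO_T] * k_I * P_W^I / (Phi_I * P_W^I + Phi_W),

which is fitted here (directly, or on its reciprocal, which is linear in
Phi_I) to estimate P_W^I and the interfacial rate parameter k_I.  From
P_W^I follow the percentage of antioxidant in the interfacial region,

    %AO_I = 100 * Phi_I * P_W^I / (Phi_W + Phi_I * P_W^I),

and its effective interfacial concentration

    (AO_I) = [AO_T] * (%AO_I / 100) / Phi_I,

which can exceed the stoichiometric concentration [AO_T] by orders of
magnitude because the interfacial volume is small.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from ._rng import rng_for
from .errors import DegenerateCompositionError, FitFailureError, InsufficientDataError

__all__ = [
    "EmulsionComposition",
    "KobsSeries",
    "PartitionFit",
    "DistributionResult",
    "predict_kobs",
    "fit_partition",
    "percent_interfacial",
    "distribution",
    "distribution_table",
]

FitMethod = Literal["nonlinear", "reciprocal-linear"]


@dataclass(frozen=True)
class EmulsionComposition:
    """Volume fractions of the oil, interfacial and aqueous pseudophases.

    The three fractions must each lie in [0, 1] and sum to 1.  ``from_phi``
    builds the composition from the oil and surfactant fractions, assigning
    the remainder to water.
    """

    phi_oil: float
    phi_interfacial: float
    phi_water: float

    def __post_init__(self) -> None:
        fr = (self.phi_oil, self.phi_interfacial, self.phi_water)
        if any(not (0.0 <= f <= 1.0) for f in fr):
            raise DegenerateCompositionError(f"volume fractions outside [0, 1]: {fr}")
        if abs(sum(fr) - 1.0) > 1e-12:
            raise DegenerateCompositionError(f"volume fractions must sum to 1, got {sum(fr)!r}")

    @classmethod
    def from_phi(cls, phi_oil: float, phi_interfacial: float) -> "EmulsionComposition":
        return cls(phi_oil, phi_interfacial, 1.0 - phi_oil - phi_interfacial)


@dataclass(frozen=True)
class KobsSeries:
    """Observed rate constants versus surfactant volume fraction.

    ``phi_interfacial`` and ``k_obs`` are parallel arrays; ``sigma`` is an
    optional per-point uncertainty (same units as ``k_obs``).  ``ao_total``
    is the stoichiometric antioxidant concentration in mol/L; ``phi_oil`` the
    fixed oil volume fraction of the formulation.
    """

    phi_interfacial: np.ndarray
    k_obs: np.ndarray
    ao_total: float
    phi_oil: float
    sigma: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "phi_interfacial", np.asarray(self.phi_interfacial, float))
        object.__setattr__(self, "k_obs", np.asarray(self.k_obs, float))
        if self.sigma is not None:
            object.__setattr__(self, "sigma", np.asarray(self.sigma, float))
        if self.phi_interfacial.shape != self.k_obs.shape:
            raise ValueError("phi_interfacial and k_obs must have equal length")
        if np.unique(self.phi_interfacial).size < 3:
            raise InsufficientDataError("need at least 3 distinct phi_interfacial values")
        if np.any(self.k_obs <= 0) or np.any(self.phi_interfacial <= 0):
            raise ValueError("k_obs and phi_interfacial must be strictly positive")

    def __len__(self) -> int:
        return self.phi_interfacial.size

    def to_frame(self) -> pd.DataFrame:
        d = {"phi_I": self.phi_interfacial, "k_obs": self.k_obs}
        if self.sigma is not None:
            d["sigma_kobs"] = self.sigma
        return pd.DataFrame(d)

    @classmethod
    def from_csv(cls, path, ao_total: float, phi_oil: float) -> "KobsSeries":
        df = pd.read_csv(path)
        sigma = df["sigma_kobs"].to_numpy() if "sigma_kobs" in df.columns else None
        return cls(df["phi_I"].to_numpy(), df["k_obs"].to_numpy(), ao_total, phi_oil, sigma)


@dataclass(frozen=True)
class PartitionFit:
    """Fitted partition constant and interfacial rate parameter."""

    p_wi: float
    k_i: float
    se_p_wi: float
    se_k_i: float
    method: str
    residual_sum_squares: float
    n_points: int = 0

    def __post_init__(self) -> None:
        if self.p_wi <= 0 or self.k_i <= 0:
            raise FitFailureError(
                f"non-physical fit: p_wi={self.p_wi!r}, k_i={self.k_i!r} (method={self.method})"
            )

    def to_dict(self) -> dict:
        return {
            "p_wi": self.p_wi,
            "k_i": self.k_i,
            "se_p_wi": self.se_p_wi,
            "se_k_i": self.se_k_i,
            "method": self.method,
            "residual_sum_squares": self.residual_sum_squares,
            "n_points": self.n_points,
        }


@dataclass(frozen=True)
class DistributionResult:
    """Antioxidant distribution between aqueous and interfacial regions."""

    percent_interfacial: float
    percent_aqueous: float
    effective_conc_interfacial: float
    effective_conc_aqueous: float
    composition: EmulsionComposition = field(repr=False, default=None)  # type: ignore[assignment]


def predict_kobs(
    p_wi: float, k_i: float, ao_total: float, comp: EmulsionComposition
) -> float:
    """Observed rate constant predicted by the pseudophase model.

    k_obs = [AO_T] * k_I * P / (Phi_I * P + Phi_W).  Returns 0 when the
    partition constant is 0 (no antioxidant reaches the interface).
    """
    if p_wi < 0:
        raise ValueError("p_wi must be non-negative")
    denom = comp.phi_interfacial * p_wi + comp.phi_water
    if denom <= 0:
        raise DegenerateCompositionError(
            "Phi_I * P + Phi_W = 0: no phase can host the antioxidant"
        )
    return ao_total * k_i * p_wi / denom


def percent_interfacial(p_wi: float, comp: EmulsionComposition) -> float:
    """Percentage of antioxidant located in the interfacial region.

    %AO_I = 100 * Phi_I * P / (Phi_W + Phi_I * P), in [0, 100]; monotone
    increasing in both the partition constant and Phi_I.
    """
    if p_wi < 0:
        raise ValueError("p_wi must be non-negative")
    denom = comp.phi_water + comp.phi_interfacial * p_wi
    if denom <= 0:
        raise DegenerateCompositionError("Phi_W + Phi_I * P = 0")
    return 100.0 * comp.phi_interfacial * p_wi / denom


def distribution(
    p_wi: float, ao_total: float, comp: EmulsionComposition
) -> DistributionResult:
    """Full distribution: percentages and effective concentrations.

    The effective interfacial concentration divides the interfacial moles by
    the interfacial volume: (AO_I) = [AO_T] * (%AO_I/100) / Phi_I, and
    likewise for water.  Mass balance Phi_I*(AO_I) + Phi_W*(AO_W) = [AO_T]
    holds by construction.
    """
    if ao_total <= 0:
        raise ValueError("ao_total must be positive")
    if comp.phi_interfacial <= 0:
        raise DegenerateCompositionError(
            "Phi_I = 0: effective interfacial concentration undefined"
        )
    pct_i = percent_interfacial(p_wi, comp)
    pct_w = 100.0 - pct_i
    conc_i = ao_total * (pct_i / 100.0) / comp.phi_interfacial
    conc_w = (
        ao_total * (pct_w / 100.0) / comp.phi_water if comp.phi_water > 0 else 0.0
    )
    return DistributionResult(pct_i, pct_w, conc_i, conc_w, comp)


def distribution_table(
    p_wi: float, ao_total: float, phi_oil: float, phi_list: Sequence[float]
) -> pd.DataFrame:
    """Distribution results over a grid of surfactant volume fractions.

    One row per Phi_I, columns phi_I, phi_W, pct_interfacial, pct_aqueous,
    conc_interfacial_M, conc_aqueous_M.
    """
    rows = []
    for phi_i in phi_list:
        comp = EmulsionComposition.from_phi(phi_oil, phi_i)
        r = distribution(p_wi, ao_total, comp)
        rows.append(
            {
                "phi_I": phi_i,
                "phi_W": comp.phi_water,
                "pct_interfacial": r.percent_interfacial,
                "pct_aqueous": r.percent_aqueous,
                "conc_interfacial_M": r.effective_conc_interfacial,
                "conc_aqueous_M": r.effective_conc_aqueous,
            }
        )
    return pd.DataFrame(rows)


def _reciprocal_linear_fit(series: KobsSeries) -> tuple[float, float, float, float, float]:
    """OLS of 1/k_obs on Phi_I, back-transformed to (P, k_I).

    With Phi_W = 1 - Phi_O - Phi_I the reciprocal model is linear in Phi_I:

        1/k_obs = [(P - 1) * Phi_I + (1 - Phi_O)] / ([AO_T] * k_I * P)

    so P = 1 + (1 - Phi_O) * slope / intercept and
    k_I = (1 - Phi_O) / (intercept * [AO_T] * P).  Standard errors follow by
    the delta method from the OLS (slope, intercept) covariance.
    """
    x = series.phi_interfacial
    y = 1.0 / series.k_obs
    coeffs, cov = np.polyfit(x, y, 1, cov=True)
    slope, intercept = coeffs
    if intercept <= 0:
        raise FitFailureError("reciprocal-linear fit produced non-positive intercept")
    c = 1.0 - series.phi_oil
    p = 1.0 + c * slope / intercept
    if p <= 0:
        raise FitFailureError(f"reciprocal-linear fit produced non-positive P = {p!r}")
    k_i = c / (intercept * series.ao_total * p)
    # delta method: gradients of (P, k_I) w.r.t. (slope, intercept)
    dp = np.array([c / intercept, -c * slope / intercept**2])
    a = series.ao_total
    dk = np.array(
        [
            -c / (a * intercept * p**2) * dp[0],
            -c / (a * intercept**2 * p) - c / (a * intercept * p**2) * dp[1],
        ]
    )
    se_p = float(np.sqrt(dp @ cov @ dp))
    se_k = float(np.sqrt(dk @ cov @ dk))
    rss = float(np.sum((np.polyval(coeffs, x) - y) ** 2))
    return p, k_i, se_p, se_k, rss


def fit_partition(
    series: KobsSeries,
    method: FitMethod = "nonlinear",
    n_restarts: int = 5,
    restart_seed: int = 0,
) -> PartitionFit:
    """Estimate (P_W^I, k_I) from a k_obs-versus-Phi_I series.

    ``nonlinear`` performs unweighted least squares of the pseudophase rate
    law directly on k_obs, initialized from the reciprocal-linear estimates
    with seeded multiplicative restarts; ``reciprocal-linear`` is ordinary
    least squares on 1/k_obs (exact on noiseless data, but it reweights
    multiplicative noise — both are therefore exposed).
    """
    if method not in ("nonlinear", "reciprocal-linear"):
        raise ValueError(f"unknown method {method!r}")
    if len(series) < 3:
        raise InsufficientDataError("need at least 3 points to fit two parameters")

    p0, k0, se_p0, se_k0, rss0 = _reciprocal_linear_fit(series)
    if method == "reciprocal-linear":
        return PartitionFit(p0, k0, se_p0, se_k0, method, rss0, len(series))

    x = series.phi_interfacial
    y = series.k_obs
    a, phi_o = series.ao_total, series.phi_oil

    def model(phi_i: np.ndarray, p: float, k_i: float) -> np.ndarray:
        return a * k_i * p / (phi_i * p + (1.0 - phi_o - phi_i))

    rng = rng_for(restart_seed, "fit-partition-restarts")
    starts = [(p0, k0)]
    starts += [
        (p0 * float(np.exp(rng.normal(0, 0.3))), k0 * float(np.exp(rng.normal(0, 0.3))))
        for _ in range(n_restarts)
    ]
    best = None
    failures: list[str] = []
    for start in starts:
        try:
            popt, pcov = curve_fit(
                model, x, y, p0=start, bounds=([1e-12, 1e-300], [np.inf, np.inf]),
                maxfev=20000,
            )
        except (RuntimeError, ValueError) as exc:  # pragma: no cover - rare
            failures.append(f"start={start}: {exc}")
            continue
        rss = float(np.sum((model(x, *popt) - y) ** 2))
        if best is None or rss < best[2]:
            best = (popt, pcov, rss)
    if best is None:
        raise FitFailureError(
            f"nonlinear fit failed from all {len(starts)} starts", failures
        )
    (p, k_i), pcov, rss = best
    se = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    return PartitionFit(float(p), float(k_i), float(se[0]), float(se[1]),
                        "nonlinear", rss, len(series))
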