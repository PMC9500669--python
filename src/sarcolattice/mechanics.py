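"""Passive and active muscle biomechanics.

Passive: a stress-relaxation protocol steps the muscle to increasing strains;
at each step the stress is separated into a *dynamic* component (initial peak
after the stretch) and an *elastic* component (steady-state after
visco-elastic relaxation).  Each component is fitted with an origin-constrained
quadratic sigma = a*eps^2 + b*eps over strain, and stiffness is reported as the
tangent d(sigma)/d(eps) at 10% stretch (an interior point of the 5-12.5%
protocol), in kPa per unit strain.

Active: specific tension is peak force per physiological cross-sectional area,

    PCSA = m / (L0 * (Lf/L0) * rho),

with muscle mass m (g), optimal length L0 (cm), fiber-to-muscle length ratio
Lf/L0 (0.45 for EDL, 1.0 for diaphragm strips) and muscle density
rho = 1.06 g/cm^3.  Unit chain: 1 mN/cm^2 = 0.01 kPa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import MechTrace

__all__ = [
    "MuscleGeometry",
    "StiffnessResult",
    "pcsa",
    "extract_dynamic_elastic",
    "fit_quadratic_stiffness",
    "analyze_stress_relaxation",
    "specific_tension",
    "MN_PER_CM2_TO_KPA",
]

#: 1 mN/cm^2 = 10 Pa = 0.01 kPa
MN_PER_CM2_TO_KPA = 0.01


@dataclass(frozen=True)
class MuscleGeometry:
    """Whole-muscle geometry for PCSA; masses in g, lengths in cm."""

    m_g: float
    l0_cm: float
    lf_ratio: float
    rho_g_cm3: float = 1.06

    def __post_init__(self):
        for name in ("m_g", "l0_cm", "lf_ratio", "rho_g_cm3"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.lf_ratio > 1.5:
            raise ValueError("lf_ratio above 1.5 is not physiological")


def pcsa(geom: MuscleGeometry) -> float:
    """Physiological cross-sectional area in cm^2: m / (L0 * Lf/L0 * rho)."""
    return geom.m_g / (geom.l0_cm * geom.lf_ratio * geom.rho_g_cm3)


@dataclass
class StiffnessResult:
    """Dynamic/elastic stress-strain points, quadratic fits and tangents."""

    dynamic_points: np.ndarray  # (n, 2): strain fraction, stress kPa
    elastic_points: np.ndarray
    dynamic_coeffs: tuple[float, float]  # (a, b) of sigma = a e^2 + b e
    elastic_coeffs: tuple[float, float]
    dynamic_stiffness_kpa: float  # tangent at eps = 0.10, kPa per unit strain
    elastic_stiffness_kpa: float

    def to_record(self) -> dict:
        return {
            "dynamic_stiffness_kpa": self.dynamic_stiffness_kpa,
            "elastic_stiffness_kpa": self.elastic_stiffness_kpa,
            "dynamic_a_kpa": self.dynamic_coeffs[0],
            "dynamic_b_kpa": self.dynamic_coeffs[1],
            "elastic_a_kpa": self.elastic_coeffs[0],
            "elastic_b_kpa": self.elastic_coeffs[1],
            # convenience: stiffness per percent strain
            "dynamic_stiffness_kpa_per_pct": self.dynamic_stiffness_kpa / 100.0,
            "elastic_stiffness_kpa_per_pct": self.elastic_stiffness_kpa / 100.0,
        }


def extract_dynamic_elastic(
    trace: MechTrace,
    pcsa_cm2: float | None = None,
    dyn_window_s: float = 0.5,
    elastic_tail_frac: float = 0.1,
) -> list[tuple[float, float, float]]:
    """Per-step (strain, sigma_dyn, sigma_el) in kPa from an annotated trace.

    The dynamic stress is the maximum within ``dyn_window_s`` of the step
    onset (the initial exerted peak); the elastic stress is the mean over the
    final ``elastic_tail_frac`` of the hold (steady state after relaxation).
    """
    if not trace.steps:
        raise ValueError("trace has no annotated strain steps")
    if pcsa_cm2 is None:
        pcsa_cm2 = trace.pcsa_cm2
    if pcsa_cm2 is None or pcsa_cm2 <= 0:
        raise ValueError("a positive PCSA reference is required for stress conversion")
    stress = trace.force_mn / pcsa_cm2 * MN_PER_CM2_TO_KPA
    t = trace.time_s
    onsets = [onset for onset, _ in trace.steps] + [t[-1] + (t[-1] - t[-2])]
    out = []
    for i, (onset, strain) in enumerate(trace.steps):
        end = onsets[i + 1]
        hold = end - onset
        dyn_sel = (t >= onset) & (t <= onset + min(dyn_window_s, hold))
        el_sel = (t >= end - elastic_tail_frac * hold) & (t < end)
        if not dyn_sel.any() or not el_sel.any():
            raise ValueError(f"empty analysis window for step at t={onset}")
        out.append(
            (float(strain), float(stress[dyn_sel].max()), float(stress[el_sel].mean()))
        )
    return out


def fit_quadratic_stiffness(
    points: list[tuple[float, float]] | np.ndarray,
    eval_strain: float = 0.10,
    intercept: bool = False,
) -> tuple[tuple[float, float], float]:
    """Least-squares fit sigma = a*eps^2 + b*eps; tangent 2a*eps + b at eval_strain.

    The fit is origin-constrained by default (zero passive stress at the
    reference length); ``intercept=True`` adds a free constant as an escape
    hatch for offset-contaminated data (the constant does not enter the
    tangent).  Returns ``((a, b), stiffness)``.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (strain, stress) pairs")
    eps, sig = pts[:, 0], pts[:, 1]
    if np.unique(eps).size < 3:
        raise ValueError("need at least 3 distinct strains for a quadratic fit")
    if np.any(eps <= 0) or np.any(eps > 0.2):
        raise ValueError("strains must lie in (0, 0.2] (stored as fractions)")
    cols = [eps**2, eps] + ([np.ones_like(eps)] if intercept else [])
    design = np.column_stack(cols)
    coef, _, rank, _ = np.linalg.lstsq(design, sig, rcond=None)
    if rank < design.shape[1]:
        raise ValueError("rank-deficient design: strains do not identify the quadratic")
    a, b = float(coef[0]), float(coef[1])
    stiffness = 2.0 * a * eval_strain + b
    return (a, b), float(stiffness)


def analyze_stress_relaxation(
    trace: MechTrace,
    pcsa_cm2: float | None = None,
    eval_strain: float = 0.10,
    dyn_window_s: float = 0.5,
    elastic_tail_frac: float = 0.1,
    intercept: bool = False,
) -> StiffnessResult:
    """Full passive analysis: decomposition per step, then quadratic tangents."""
    rows = extract_dynamic_elastic(
        trace, pcsa_cm2, dyn_window_s=dyn_window_s, elastic_tail_frac=elastic_tail_frac
    )
    dyn_pts = np.array([(e, d) for e, d, _ in rows])
    el_pts = np.array([(e, s) for e, _, s in rows])
    dyn_coef, dyn_stiff = fit_quadratic_stiffness(dyn_pts, eval_strain, intercept)
    el_coef, el_stiff = fit_quadratic_stiffness(el_pts, eval_strain, intercept)
    return StiffnessResult(
        dynamic_points=dyn_pts,
        elastic_points=el_pts,
        dynamic_coeffs=dyn_coef,
        elastic_coeffs=el_coef,
        dynamic_stiffness_kpa=dyn_stiff,
        elastic_stiffness_kpa=el_stiff,
    )


def specific_tension(
    twitch: MechTrace | None,
    tetanus: MechTrace | None,
    pcsa_cm2: float,
) -> dict:
    """Peak force per PCSA, in kPa, for a twitch/tetanus trace pair."""
    if pcsa_cm2 <= 0:
        raise ValueError("PCSA must be positive")
    out: dict[str, float] = {}
    for name, tr in (("twitch_kpa", twitch), ("tetanus_kpa", tetanus)):
        if tr is None:
            continue
        if tr.force_mn.size == 0:
            raise ValueError("empty trace")
        out[name] = float(tr.force_mn.max()) / pcsa_cm2 * MN_PER_CM2_TO_KPA
    if not out:
        raise ValueError("at least one trace is required")
    return out
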