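"""Local growth rate, maintenance allocation and metabolite source terms.

The local biomass growth rate is a weighted sum over three growth modes,

    lambda = lambda_1 * theta_o + lambda_2 * (1 - theta_o)
             + lambda_3 * (1 - theta_g) * theta_o,

where lambda_1 (aerobic on glucose), lambda_2 (anaerobic on glucose) and
lambda_3 (aerobic on acetate) are Monod laws in the respective substrate,
theta_x = C_x / (C_x + K_x) are Monod fractions, theta_o weights the
aerobic/anaerobic branches and (1 - theta_g) encodes the hierarchical
preference of glucose over acetate.

Maintenance enters in two ways.  First, each mode's Monod law is shifted by
a threshold concentration C* at which the maximal Monod-limited uptake
exactly covers the maintenance carbon flux m: growth is zero at or below C*
and follows lambda_max*(C - C*)/((C - C*) + K) above it (continuous at C*,
plain Monod when C* = 0).  Second, carbon uptake is allocated to
maintenance before growth; a cell whose achievable carbon uptake falls
short of m is *starving*.

All functions are pure and vectorized over grid points; concentrations may
be scalars or numpy arrays of a common shape.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np

from .params import ParameterSet

__all__ = [
    "GrowthRates",
    "SourceTerms",
    "MaintenanceState",
    "monod",
    "maintenance_threshold",
    "shifted_monod_rate",
    "local_growth_rate",
    "maintenance_allocation",
    "source_terms",
    "acetate_yield_bound",
    "CARBONS_PER_GLUCOSE",
    "CARBONS_PER_ACETATE",
]

#: carbon atoms per molecule, used to convert uptake rates to carbon flux
CARBONS_PER_GLUCOSE = 6.0
CARBONS_PER_ACETATE = 2.0


@dataclass
class GrowthRates:
    """Composed growth rate and its mode components (all 1/h)."""

    lambda_total: Any
    lambda1: Any  # aerobic on glucose
    lambda2: Any  # anaerobic on glucose
    lambda3: Any  # aerobic on acetate
    theta_g: Any
    theta_o: Any
    theta_a: Any


@dataclass
class SourceTerms:
    """Uptake (Q) and excretion (P) rates in mmol/gdw/h.

    Component fields (``Qg_aer``, ``Qg_ana``, ``Qa_growth``) keep the
    aerobic/anaerobic and growth/maintenance splits for flux-partition
    bookkeeping; ``P_g`` and ``P_o`` are identically zero.
    """

    Q_g: Any
    Q_o: Any
    Q_a: Any
    P_a: Any
    Q_g_maint: Any
    Q_o_maint: Any
    Q_a_maint: Any
    P_a_maint: Any
    Qg_aer: Any
    Qg_ana: Any
    Qa_growth: Any
    Qg_maint_ana: Any = 0.0

    P_g: float = 0.0
    P_o: float = 0.0


@dataclass
class MaintenanceState:
    """Maintenance uptake components plus starvation/anoxia flags."""

    Q_g_maint: Any  # mmol glucose /gdw/h
    Q_o_maint: Any
    Q_a_maint: Any  # mmol acetate /gdw/h
    P_a_maint: Any
    starving: Any   # bool: achievable carbon uptake < m_carbon
    anaerobic: Any  # bool: C_o below the anoxia cutoff (K_o)
    ana_frac: Any = 0.0  # anaerobic share of the glucose maintenance uptake


def monod(C, K):
    """Monod fraction C/(C+K), in [0, 1), monotone increasing in C."""
    C = np.asarray(C, dtype=float)
    if np.any(C < 0):
        raise ValueError("negative concentration")
    if np.any(np.asarray(K, dtype=float) <= 0):
        raise ValueError("Monod constant must be positive")
    out = C / (C + K)
    return out if out.ndim else float(out)


def maintenance_threshold(q_max: float, m: float, K: float) -> float:
    """Concentration C* at which maximal Monod-limited uptake covers maintenance.

    Solves q_max * C/(C + K) = m for C:  C* = K*m/(q_max - m); zero when
    m = 0.  Raises if m >= q_max (maintenance unreachable at any
    concentration).
    """
    if m < 0:
        raise ValueError("maintenance flux must be nonnegative")
    if m == 0:
        return 0.0
    if m >= q_max:
        raise ValueError(
            f"maintenance flux m={m} not coverable: uptake capacity q_max={q_max}")
    return K * m / (q_max - m)


def shifted_monod_rate(lambda_max: float, C, K: float, C_star: float):
    """Maintenance-shifted Monod growth rate.

    Zero for C <= C*; lambda_max*(C - C*)/((C - C*) + K) above.  Continuous
    at C = C* and identical to plain Monod when C* = 0.
    """
    C = np.asarray(C, dtype=float)
    if lambda_max < 0 or C_star < 0 or np.any(C < 0):
        raise ValueError("inputs must be nonnegative")
    if K <= 0:
        raise ValueError("Monod constant must be positive")
    x = np.maximum(C - C_star, 0.0)
    out = lambda_max * x / (x + K)
    return out if out.ndim else float(out)


def _thresholds(p: ParameterSet) -> tuple[float, float, float]:
    """Per-mode maintenance thresholds (aerobic-glc, anaerobic-glc, acetate)."""
    m = p.m_carbon
    if m == 0:
        return 0.0, 0.0, 0.0
    cap_g_aer = CARBONS_PER_GLUCOSE * p.q_g_aer * p.lambda_g_aer
    cap_g_ana = CARBONS_PER_GLUCOSE * p.q_g_ana * p.lambda_g_ana
    cap_a = CARBONS_PER_ACETATE * p.q_a_aer * p.lambda_a_aer
    return (maintenance_threshold(cap_g_aer, m, p.K_g),
            maintenance_threshold(cap_g_ana, m, p.K_g),
            maintenance_threshold(cap_a, m, p.K_a))


def local_growth_rate(C_g, C_o, C_a, p: ParameterSet) -> GrowthRates:
    """Compose the local growth rate from the three maintenance-shifted modes."""
    theta_g = monod(C_g, p.K_g)
    theta_o = monod(C_o, p.K_o)
    theta_a = monod(C_a, p.K_a)
    cs1, cs2, cs3 = _thresholds(p)
    lam1 = shifted_monod_rate(p.lambda_g_aer, C_g, p.K_g, cs1)
    lam2 = shifted_monod_rate(p.lambda_g_ana, C_g, p.K_g, cs2)
    lam3 = shifted_monod_rate(p.lambda_a_aer, C_a, p.K_a, cs3)
    lam = lam1 * theta_o + lam2 * (1.0 - theta_o) + lam3 * (1.0 - theta_g) * theta_o
    return GrowthRates(lam, lam1, lam2, lam3, theta_g, theta_o, theta_a)


def maintenance_allocation(C_g, C_o, C_a, p: ParameterSet) -> MaintenanceState:
    """Allocate achievable carbon uptake to maintenance, glucose first.

    The uptake capacity of each substrate uses the same Monod transporter
    kinetics as growth uptake (q_max * theta(C)); the aerobic and anaerobic
    glucose capacities are mixed by theta_o, and acetate capacity is gated
    by (1 - theta_g)*theta_o exactly as in the growth law (acetate needs
    oxygen and is only used when glucose is scarce).  Maintenance is paid
    from glucose first, then acetate; ``starving`` is true wherever total
    achievable carbon uptake is below ``m_carbon``.  Anaerobically consumed
    maintenance glucose excretes ``acetate_per_glucose_maint`` acetate.
    """
    C_g = np.asarray(C_g, dtype=float)
    C_o = np.asarray(C_o, dtype=float)
    C_a = np.asarray(C_a, dtype=float)
    theta_g = np.asarray(monod(C_g, p.K_g))
    theta_o = np.asarray(monod(C_o, p.K_o))
    theta_a = np.asarray(monod(C_a, p.K_a))
    m = p.m_carbon

    # carbon uptake capacities, mmol C /gdw/h
    cap_g = CARBONS_PER_GLUCOSE * theta_g * (
        p.q_g_aer * p.lambda_g_aer * theta_o
        + p.q_g_ana * p.lambda_g_ana * (1.0 - theta_o))
    cap_a = CARBONS_PER_ACETATE * p.q_a_aer * p.lambda_a_aer * theta_a \
        * (1.0 - theta_g) * theta_o

    from_g = np.minimum(cap_g, m)          # carbon taken from glucose
    from_a = np.minimum(cap_a, m - from_g)  # remainder from acetate
    starving = (cap_g + cap_a) < m
    anaerobic = C_o < p.K_o  # anoxia cutoff for the death clock

    Q_g_maint = from_g / CARBONS_PER_GLUCOSE
    Q_a_maint = from_a / CARBONS_PER_ACETATE
    # anaerobic share of glucose maintenance ferments and excretes acetate
    ana_frac = np.where(cap_g > 0,
                        p.q_g_ana * p.lambda_g_ana * (1.0 - theta_o)
                        / np.maximum(p.q_g_aer * p.lambda_g_aer * theta_o
                                     + p.q_g_ana * p.lambda_g_ana * (1.0 - theta_o),
                                     1e-300),
                        0.0)
    P_a_maint = p.acetate_per_glucose_maint * Q_g_maint * ana_frac
    # oxygen demand of the aerobic maintenance shares
    Q_o_maint = (p.q_o_g / p.q_g_aer) * Q_g_maint * (1.0 - ana_frac) \
        + (p.q_o_a / p.q_a_aer) * Q_a_maint

    if C_g.ndim == 0 and C_o.ndim == 0 and C_a.ndim == 0:
        return MaintenanceState(float(Q_g_maint), float(Q_o_maint),
                                float(Q_a_maint), float(P_a_maint),
                                bool(starving), bool(anaerobic),
                                float(ana_frac))
    return MaintenanceState(Q_g_maint, Q_o_maint, Q_a_maint, P_a_maint,
                            starving, anaerobic, ana_frac)


def source_terms(g: GrowthRates, maint: MaintenanceState,
                 p: ParameterSet) -> SourceTerms:
    """Assemble the PDE uptake/excretion rates from growth and maintenance.

    Q_g = q_g_aer*lambda1*theta_o + q_g_ana*lambda2*(1-theta_o) + Q_g_maint
    Q_o = q_o_g*lambda1*theta_o + q_o_a*lambda3*(1-theta_g)*theta_o + Q_o_maint
    P_a = p_a_aer*lambda1*theta_o + p_a_ana*lambda2*(1-theta_o) + P_a_maint
    Q_a = q_a_aer*lambda3*(1-theta_g)*theta_o + Q_a_maint

    P_g and P_o are identically zero.
    """
    to = g.theta_o
    Qg_aer = p.q_g_aer * g.lambda1 * to
    Qg_ana = p.q_g_ana * g.lambda2 * (1.0 - to)
    Qa_growth = p.q_a_aer * g.lambda3 * (1.0 - g.theta_g) * to
    Q_g = Qg_aer + Qg_ana + maint.Q_g_maint
    Q_o = p.q_o_g * g.lambda1 * to + p.q_o_a * g.lambda3 * (1.0 - g.theta_g) * to \
        + maint.Q_o_maint
    P_a = p.p_a_aer * g.lambda1 * to + p.p_a_ana * g.lambda2 * (1.0 - to) \
        + maint.P_a_maint
    Q_a = Qa_growth + maint.Q_a_maint
    return SourceTerms(Q_g=Q_g, Q_o=Q_o, Q_a=Q_a, P_a=P_a,
                       Q_g_maint=maint.Q_g_maint, Q_o_maint=maint.Q_o_maint,
                       Q_a_maint=maint.Q_a_maint, P_a_maint=maint.P_a_maint,
                       Qg_aer=Qg_aer, Qg_ana=Qg_ana, Qa_growth=Qa_growth,
                       Qg_maint_ana=maint.Q_g_maint * maint.ana_frac)


def acetate_yield_bound(C_g_init: float) -> float:
    """Stoichiometric upper bound on excretable acetate, mM.

    Homoacetate fermentation yields at most 2 mol acetate per mol glucose,
    so an agar prepared with C_g_init glucose can never accumulate more
    than 2*C_g_init acetate.
    """
    if C_g_init < 0:
        raise ValueError("initial glucose concentration must be nonnegative")
    return 2.0 * C_g_init
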