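"""Ligand-receptor reaction-diffusion model family (variants T1-T5) and
the linear stability analysis deciding diffusion-driven (Turing)
instability of a parameter set.

The two-species core has a receptor R confined to the epithelium and a
diffusible ligand L:

  epithelium:  dR/dt = D_R lap R + rho_R - delta_R R + (v - m mu) R^m L^n
  epithelium:  dL/dt = D_L lap L - n mu R^m L^n - delta_L L
  mesenchyme:  dL/dt = D_L lap L + rho_L - delta_L L

Variant T5 adds a second, epithelially produced ligand L1 that feeds back
on mesenchymal ligand production (saturating).

The stability analysis runs on the compartment-collapsed system: the
epithelial pair (R, L) with the mesenchymal ligand source added to the
ligand equation (well-mixed ligand reservoir convention).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from .errors import InputError, SteadyStateError

VARIANTS = ("T1", "T2", "T3", "T4", "T5")

__all__ = [
    "ParameterSet",
    "ModelSpec",
    "StabilityResult",
    "reaction_terms",
    "steady_state_wellmixed",
    "dispersion_relation",
    "turing_conditions",
    "VARIANTS",
]


@dataclass(frozen=True)
class ParameterSet:
    """Kinetic and transport constants (non-dimensional units).

    ``rho_L`` is the constitutive mesenchymal ligand production rate
    (alias ``b``); the T5 extras (``b_1``, ``gamma``, ``K_fb``,
    ``D_L1``, ``delta_L1``) control the second-ligand feedback loop.
    """

    D_R: float = 1.0
    D_L: float = 20.0
    rho_R: float = 0.1
    rho_L: float = 0.9
    delta_R: float = 1.0
    delta_L: float = 0.01
    mu: float = 1.0
    v: float = 3.0
    m: int = 2
    n: int = 1
    # T5 extras
    D_L1: float | None = None
    b_1: float = 0.0
    delta_L1: float = 0.1
    gamma: float = 0.0
    K_fb: float = 1.0

    def __post_init__(self):
        if self.D_R <= 0 or self.D_L <= 0:
            raise InputError("diffusion coefficients must be positive")
        for name in ("rho_R", "rho_L", "delta_R", "delta_L", "mu", "v",
                     "b_1", "delta_L1", "gamma", "K_fb"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be non-negative")
        if self.m < 1 or self.n < 1:
            raise InputError("stoichiometry m, n must be >= 1")
        if self.m + self.n > 3 or self.m > 2 or self.n > 2:
            raise InputError("supported stoichiometries: m, n in {1, 2}, m + n <= 3")
        if self.D_L1 is None:
            object.__setattr__(self, "D_L1", self.D_L)

    @property
    def b(self) -> float:
        """Constitutive ligand production (alias of rho_L)."""
        return self.rho_L

    @property
    def w(self) -> float:
        """Net receptor gain per complex, v - m*mu."""
        return self.v - self.m * self.mu

    def to_dict(self) -> dict:
        return asdict(self)


def _apply_variant(variant: str, p: ParameterSet) -> ParameterSet:
    if variant in ("T1", "T2", "T3", "T5"):
        p = replace(p, m=2, n=1)
    if variant == "T2":
        p = replace(p, v=0.0)
    elif variant == "T3":
        # equal diffusivities at the ligand's value: receptors become as
        # mobile as the ligand (the slow-slow alternative adds a
        # diffusion-limited boundary instability unrelated to patterning)
        p = replace(p, D_R=p.D_L)
    elif variant == "T4":
        p = replace(p, m=1, n=1)
    return p


@dataclass(frozen=True)
class ModelSpec:
    """A model variant bound to a parameter set.

    Construction enforces the variant's defining constraint (T2: v=0,
    T3: D_L=D_R, T4: m=n=1, T1/T5: m=2, n=1). ``readout_exponents``
    are the (m, n) used for the signalling readout R^m L^n; by default
    the model's own stoichiometry.
    """

    variant: str
    params: ParameterSet
    readout_exponents: tuple[int, int] | None = None

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise InputError(f"unknown variant {self.variant!r}; use one of {VARIANTS}")
        p = _apply_variant(self.variant, self.params)
        object.__setattr__(self, "params", p)
        if self.readout_exponents is None:
            object.__setattr__(self, "readout_exponents", (p.m, p.n))

    @property
    def has_second_ligand(self) -> bool:
        return self.variant == "T5"

    def readout(self, R, L):
        m, n = self.readout_exponents
        return np.asarray(R) ** m * np.asarray(L) ** n

    def to_json(self, path=None) -> str:
        payload = {"variant": self.variant, "params": self.params.to_dict(),
                   "readout_exponents": list(self.readout_exponents)}
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, path) -> "ModelSpec":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(variant=payload["variant"],
                   params=ParameterSet(**payload["params"]),
                   readout_exponents=tuple(payload["readout_exponents"]))


@dataclass(frozen=True)
class StabilityResult:
    steady_state: tuple
    turing_unstable: bool
    k_max: float
    max_growth_rate: float
    necessary_conditions: dict = field(default_factory=dict)
    growth_at_zero: float = np.nan


# ---------------------------------------------------------------------------
# reaction kinetics


def effective_ligand_production(model: ModelSpec, L1):
    """Mesenchymal ligand production: b for T1-T4; b + gamma*L1/(K_fb+L1)
    under the T5 feedback."""
    p = model.params
    if model.has_second_ligand and p.gamma > 0:
        L1 = np.asarray(L1, dtype=float)
        return p.rho_L + p.gamma * L1 / (p.K_fb + L1)
    return p.rho_L


def reaction_terms(model: ModelSpec, R, L, L1=0.0, subdomain: str = "epithelium"):
    """Per-species reaction rates in one subdomain.

    Returns a dict with keys 'R', 'L' (and 'L1' for T5). The receptor
    exists only in the epithelium; the mesenchyme only produces and
    degrades ligand.
    """
    R = np.asarray(R, dtype=float)
    L = np.asarray(L, dtype=float)
    if np.any(R < 0) or np.any(L < 0):
        raise InputError("concentrations must be non-negative")
    p = model.params
    if subdomain == "epithelium":
        q = R ** p.m * L ** p.n
        out = {"R": p.rho_R - p.delta_R * R + p.w * q,
               "L": -p.n * p.mu * q - p.delta_L * L}
        if model.has_second_ligand:
            out["L1"] = p.b_1 * q - p.delta_L1 * np.asarray(L1, dtype=float)
        return out
    if subdomain == "mesenchyme":
        rho_eff = effective_ligand_production(model, L1)
        out = {"L": rho_eff - p.delta_L * L}
        if model.has_second_ligand:
            out["L1"] = -p.delta_L1 * np.asarray(L1, dtype=float)
        return out
    raise InputError(f"unknown subdomain {subdomain!r}")


# ---------------------------------------------------------------------------
# collapsed (well-mixed) steady state


def _collapsed_rhs(model: ModelSpec, R, L, L1=0.0):
    """Reaction terms of the compartment-collapsed system: epithelial
    kinetics with the mesenchymal ligand source added."""
    p = model.params
    q = R ** p.m * L ** p.n
    rho_eff = effective_ligand_production(model, L1)
    dR = p.rho_R - p.delta_R * R + p.w * q
    dL = rho_eff - p.delta_L * L - p.n * p.mu * q
    if model.has_second_ligand:
        dL1 = p.b_1 * q - p.delta_L1 * L1
        return dR, dL, dL1
    return dR, dL


def _solve_core_fixed_point(p: ParameterSet, rho_L_eff: float):
    """Positive root of the collapsed two-species kinetics with ligand
    source ``rho_L_eff``."""
    if p.mu == 0 and p.v == 0:
        return p.rho_R / p.delta_R, rho_L_eff / p.delta_L
    if p.mu > 0:
        # From dL = 0: q = (rho_L_eff - delta_L L) / (n mu) >= 0, so
        # L in (0, rho_L_eff/delta_L]; dR = 0 then gives R(L) in closed
        # form and the defining residual changes sign on the bracket.
        if rho_L_eff <= 0:
            raise SteadyStateError("no ligand source: only trivial L* = 0")
        L_hi = rho_L_eff / p.delta_L

        def r_of_l(L):
            q = (rho_L_eff - p.delta_L * L) / (p.n * p.mu)
            return (p.rho_R + p.w * q) / p.delta_R

        def phi(L):
            R = r_of_l(L)
            if R <= 0:
                return -1.0
            q = (rho_L_eff - p.delta_L * L) / (p.n * p.mu)
            return R ** p.m * L ** p.n - q

        lo, hi = 1e-14 * L_hi, L_hi
        if phi(lo) * phi(hi) > 0:
            raise SteadyStateError("no positive fixed point found",
                                   bracket=(lo, hi))
        L_star = brentq(phi, lo, hi, rtol=1e-15, maxiter=200)
        return r_of_l(L_star), L_star
    # mu == 0, v > 0: L decouples; R from a scalar root
    L_star = rho_L_eff / p.delta_L

    def psi(R):
        return p.rho_R - p.delta_R * R + p.v * R ** p.m * L_star ** p.n

    R0 = p.rho_R / p.delta_R
    lo, hi = 0.0, R0
    grow = R0 if R0 > 0 else 1.0
    for _ in range(200):
        hi = hi + grow
        if psi(hi) < 0:
            return brentq(psi, lo, hi, rtol=1e-15), L_star
        grow *= 1.5
    raise SteadyStateError("receptor production diverges (v R^m L^n unbounded)",
                           bracket=(lo, hi))


def steady_state_wellmixed(model: ModelSpec):
    """Homogeneous fixed point (R*, L*) (plus L1* for T5) of the
    compartment-collapsed kinetics; residual < 1e-10 relative."""
    p = model.params
    if not model.has_second_ligand or (p.gamma == 0 and p.b_1 == 0):
        R, L = _solve_core_fixed_point(p, p.rho_L)
        if model.has_second_ligand:
            q = R ** p.m * L ** p.n
            return R, L, p.b_1 * q / p.delta_L1
        return R, L
    # T5: iterate on the effective ligand source (monotone, saturating,
    # bounded by rho_L + gamma, hence convergent)
    rho_eff = p.rho_L
    for _ in range(500):
        R, L = _solve_core_fixed_point(p, rho_eff)
        q = R ** p.m * L ** p.n
        L1 = p.b_1 * q / p.delta_L1
        new = p.rho_L + p.gamma * L1 / (p.K_fb + L1)
        if abs(new - rho_eff) <= 1e-14 * max(1.0, abs(new)):
            break
        rho_eff = 0.5 * rho_eff + 0.5 * new
    R, L = _solve_core_fixed_point(p, rho_eff)
    q = R ** p.m * L ** p.n
    L1 = p.b_1 * q / p.delta_L1
    res = _collapsed_rhs(model, R, L, L1)
    scale = max(p.rho_R, p.rho_L, 1e-30)
    if max(abs(r) for r in res) > 1e-8 * scale:
        raise SteadyStateError("T5 feedback fixed-point iteration did not converge")
    return R, L, L1


# ---------------------------------------------------------------------------
# linear stability


def _jacobian_collapsed(model: ModelSpec, state):
    """Reaction Jacobian of the collapsed system at ``state``."""
    p = model.params
    if model.has_second_ligand:
        R, L, L1 = state
    else:
        R, L = state
    qR = p.m * R ** (p.m - 1) * L ** p.n
    qL = p.n * R ** p.m * L ** (p.n - 1)
    if model.has_second_ligand:
        drho = p.gamma * p.K_fb / (p.K_fb + L1) ** 2 if p.gamma > 0 else 0.0
        return np.array([
            [-p.delta_R + p.w * qR, p.w * qL, 0.0],
            [-p.n * p.mu * qR, -p.delta_L - p.n * p.mu * qL, drho],
            [p.b_1 * qR, p.b_1 * qL, -p.delta_L1],
        ])
    return np.array([
        [-p.delta_R + p.w * qR, p.w * qL],
        [-p.n * p.mu * qR, -p.delta_L - p.n * p.mu * qL],
    ])


def dispersion_relation(model: ModelSpec, k, state=None):
    """Dominant eigenvalue lambda(k) of J - k^2 diag(D) at the collapsed
    steady state; vectorised over ``k``."""
    if state is None:
        state = steady_state_wellmixed(model)
    J = _jacobian_collapsed(model, state)
    p = model.params
    if model.has_second_ligand:
        D = np.array([p.D_R, p.D_L, p.D_L1])
    else:
        D = np.array([p.D_R, p.D_L])
    k = np.asarray(k, dtype=float)
    scalar = k.ndim == 0
    kv = np.atleast_1d(k)
    lam = np.empty(len(kv), dtype=complex)
    for i, ki in enumerate(kv):
        ev = np.linalg.eigvals(J - ki ** 2 * np.diag(D))
        lam[i] = ev[np.argmax(ev.real)]
    return lam[0] if scalar else lam


def default_k_grid(length_scale: float = 100.0, n: int = 400) -> np.ndarray:
    """Wavenumber grid spanning [0, 10] (units of inverse length at the
    nominal domain scale) with a log-fine region near zero."""
    k_hi = 10.0 * (100.0 / length_scale)
    return np.concatenate([[0.0], np.geomspace(1e-3, k_hi, n - 1)])


def turing_conditions(model: ModelSpec, k_grid=None) -> StabilityResult:
    """Evaluate the necessary conditions and the dispersion relation.

    Necessary conditions: (i) D_L > D_R, (ii) v > m*mu, (iii)
    cooperative complex formation (not m = n = 1). The instability
    verdict comes from the dispersion relation: Re lambda(0) < 0 and
    max_{k>0} Re lambda(k) > 0.
    """
    p = model.params
    conditions = {
        "diffusion": p.D_L > p.D_R,
        "feedback": p.v > p.m * p.mu,
        "cooperativity": not (p.m == 1 and p.n == 1),
    }
    if k_grid is None:
        k_grid = default_k_grid()
    k_grid = np.asarray(k_grid, dtype=float)
    try:
        state = steady_state_wellmixed(model)
    except SteadyStateError:
        return StabilityResult(steady_state=(np.nan, np.nan), turing_unstable=False,
                               k_max=np.nan, max_growth_rate=np.nan,
                               necessary_conditions=conditions)
    lam = np.atleast_1d(dispersion_relation(model, k_grid, state=state))
    re = lam.real
    if np.any(np.isnan(re)):
        raise SteadyStateError("dispersion relation produced NaN")
    re0 = re[np.argmin(k_grid)]
    pos = k_grid > 0
    i_best = int(np.argmax(re[pos]))
    k_best = k_grid[pos][i_best]
    g_best = float(re[pos][i_best])
    unstable = bool(re0 < 0 and g_best > 0)
    return StabilityResult(steady_state=state, turing_unstable=unstable,
                           k_max=float(k_best) if unstable else 0.0,
                           max_growth_rate=g_best,
                           necessary_conditions=conditions,
                           growth_at_zero=float(re0))
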