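"""Domain types and reaction--diffusion right-hand sides.

The model describes a quasi-twodimensional biochip discretised into ``M``
well-mixed boxes along its length.  Proteins are synthesised cell-free at a
constant rate ``alpha_syn`` in a subset of "source" boxes (the DNA-brush
region), hop between neighbouring boxes at the diffusion rate
``D_tilde = D / l**2`` (diffusion constant scaled by the squared box
length), and bind quasi-irreversibly to surface traps with binding affinity
``kappa_bin``.  Each box ``i`` carries a finite number of traps, so the
bound count ``N_b[i]`` can never exceed the trap capacity ``N_b_max[i]``.

Counts are continuous non-negative reals (a mean-field reading of the
kinetics; no stochastic birth--death dynamics).  For a single box the
bound-protein time course has a closed form in terms of the Gauss error
function, implemented in :func:`onebox_bound_analytical`; the degenerate
zero-synthesis case has a separate logistic-type closed form in
:func:`onebox_bound_pure_binding`.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
from scipy import special

__all__ = [
    "ConfigError",
    "StepSizeError",
    "SystemConfig",
    "TrapPattern",
    "SynthesisPattern",
    "BoxState",
    "AnalyticalAux",
    "analytical_aux",
    "onebox_bound_analytical",
    "onebox_bound_pure_binding",
    "onebox_rhs",
    "multibox_rhs",
]

#: explicit-diffusion stability bound on D_tilde * dt
DIFFUSION_STABILITY_LIMIT = 0.5

#: bound on kappa_bin * dt * max(capacity) preventing per-step trap overshoot
BINDING_DEPLETION_LIMIT = 1.0

#: |lambda * C_zeta| beyond which the closed form saturates to capacity
_ERF_SATURATION = 26.0


class ConfigError(ValueError):
    """A run configuration violates a validity or stability guard."""


class StepSizeError(RuntimeError):
    """The Euler step produced counts outside their physical bounds."""


# ---------------------------------------------------------------------------
# configuration and pattern types
# ---------------------------------------------------------------------------

_RATE_UNITS = ("per_time", "per_dt")


@dataclass(frozen=True)
class SystemConfig:
    """Kinetic parameters and discretisation settings for one run.

    Parameters
    ----------
    alpha_syn
        Synthesis rate per source box (proteins per unit time, or per time
        step when ``rate_units="per_dt"``).
    kappa_bin
        Binding affinity; mean-field second-order coefficient multiplying
        ``N_u * (N_b_max - N_b)``, units per (protein * trap * time).
    D_tilde
        Diffusion rate ``D / l**2``, the inter-box hopping rate.
    dt
        Explicit-Euler time step.
    n_steps
        Number of Euler steps (integer horizon).
    M
        Number of boxes (>= 1).
    record_every
        Output decimation: every ``record_every``-th step is stored (the
        final step is always stored).  Regime analysis requires 1.
    rate_units
        ``"per_time"``: the three rates are per unit time ``[t]`` and ``dt``
        is in ``[t]``.  ``"per_dt"``: the rates are per time step (the
        convention used for dimensionless chip-scale runs).
    """

    alpha_syn: float
    kappa_bin: float
    D_tilde: float
    dt: float
    n_steps: int
    M: int
    record_every: int = 1
    rate_units: str = "per_time"

    def __post_init__(self) -> None:
        if self.rate_units not in _RATE_UNITS:
            raise ConfigError(
                f"rate_units must be one of {_RATE_UNITS}, got {self.rate_units!r}"
            )
        for name in ("alpha_syn", "kappa_bin", "D_tilde"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not self.dt > 0:
            raise ConfigError(f"dt must be > 0, got {self.dt}")
        if int(self.M) != self.M or self.M < 1:
            raise ConfigError(f"M must be an integer >= 1, got {self.M}")
        if int(self.n_steps) != self.n_steps or self.n_steps < 1:
            raise ConfigError(f"n_steps must be an integer >= 1, got {self.n_steps}")
        if int(self.record_every) != self.record_every or self.record_every < 1:
            raise ConfigError(
                f"record_every must be an integer >= 1, got {self.record_every}"
            )
        if self.D_step > DIFFUSION_STABILITY_LIMIT:
            raise ConfigError(
                "explicit-diffusion stability violated: "
                f"D_tilde*dt = {self.D_step:g} > {DIFFUSION_STABILITY_LIMIT}"
            )

    # rates per unit time [t]
    @property
    def alpha_per_t(self) -> float:
        return self.alpha_syn / self.dt if self.rate_units == "per_dt" else self.alpha_syn

    @property
    def kappa_per_t(self) -> float:
        return self.kappa_bin / self.dt if self.rate_units == "per_dt" else self.kappa_bin

    @property
    def D_per_t(self) -> float:
        return self.D_tilde / self.dt if self.rate_units == "per_dt" else self.D_tilde

    # rates per Euler step (the simulator's internal scale)
    @property
    def alpha_step(self) -> float:
        return self.alpha_per_t * self.dt

    @property
    def kappa_step(self) -> float:
        return self.kappa_per_t * self.dt

    @property
    def D_step(self) -> float:
        return self.D_per_t * self.dt

    @property
    def horizon(self) -> float:
        """Total simulated time ``n_steps * dt``."""
        return self.n_steps * self.dt

    def validate_against_traps(self, traps: "TrapPattern") -> None:
        """Check the per-step binding-depletion guard for a trap pattern.

        ``kappa_bin * dt * max(capacity) <= 1`` bounds the fraction of a
        box's unbound pool that a single Euler step can move onto traps and
        prevents immediate overshoot past the capacity ceiling.
        """
        if traps.capacities.shape[0] != self.M:
            raise ConfigError(
                f"trap pattern has {traps.capacities.shape[0]} boxes, config has M={self.M}"
            )
        cap_max = float(traps.capacities.max(initial=0.0))
        if self.kappa_step * cap_max > BINDING_DEPLETION_LIMIT * (1 + 1e-12):
            raise ConfigError(
                "binding-depletion guard violated: kappa_bin*dt*max(capacity) = "
                f"{self.kappa_step * cap_max:g} > {BINDING_DEPLETION_LIMIT}"
            )

    def replace(self, **changes) -> "SystemConfig":
        return replace(self, **changes)


@dataclass(frozen=True)
class TrapPattern:
    """Per-box trap capacities ``N_b_max[i]`` (maximal bound counts)."""

    capacities: np.ndarray

    def __post_init__(self) -> None:
        cap = np.asarray(self.capacities, dtype=float)
        if cap.ndim != 1:
            raise ConfigError("capacities must be a 1-D vector")
        if np.any(cap < 0) or not np.all(np.isfinite(cap)):
            raise ConfigError("capacities must be finite and >= 0")
        object.__setattr__(self, "capacities", cap)

    @property
    def M(self) -> int:
        return self.capacities.shape[0]

    @property
    def total_capacity(self) -> float:
        return float(self.capacities.sum())

    def __eq__(self, other) -> bool:  # ndarray field needs elementwise compare
        if not isinstance(other, TrapPattern):
            return NotImplemented
        return np.array_equal(self.capacities, other.capacities)


@dataclass(frozen=True)
class SynthesisPattern:
    """Set of source boxes (1-based indices, matching i = 1, ..., M)."""

    source_boxes: frozenset

    def __init__(self, source_boxes: Iterable[int] = ()) -> None:
        boxes = frozenset(int(i) for i in source_boxes)
        object.__setattr__(self, "source_boxes", boxes)

    def validate(self, M: int) -> None:
        bad = sorted(i for i in self.source_boxes if not 1 <= i <= M)
        if bad:
            raise ConfigError(f"source boxes out of range 1..{M}: {bad}")

    def mask(self, M: int) -> np.ndarray:
        """Iverson-bracket indicator vector, 1.0 for source boxes."""
        self.validate(M)
        m = np.zeros(M)
        for i in self.source_boxes:
            m[i - 1] = 1.0
        return m

    def __len__(self) -> int:
        return len(self.source_boxes)

    @classmethod
    def block(cls, first: int, last: int) -> "SynthesisPattern":
        """Contiguous source region ``first..last`` (1-based, inclusive)."""
        return cls(range(first, last + 1))


@dataclass
class BoxState:
    """Instantaneous per-box unbound/bound counts at time ``t``."""

    N_u: np.ndarray
    N_b: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.N_u = np.atleast_1d(np.asarray(self.N_u, dtype=float)).copy()
        self.N_b = np.atleast_1d(np.asarray(self.N_b, dtype=float)).copy()
        if self.N_u.shape != self.N_b.shape:
            raise ConfigError("N_u and N_b must have the same length")
        if np.any(self.N_u < 0) or np.any(self.N_b < 0):
            raise ConfigError("counts must be >= 0")

    @property
    def M(self) -> int:
        return self.N_u.shape[0]

    @classmethod
    def empty(cls, M: int, t: float = 0.0) -> "BoxState":
        return cls(np.zeros(M), np.zeros(M), t)

    def copy(self) -> "BoxState":
        return BoxState(self.N_u, self.N_b, self.t)


# ---------------------------------------------------------------------------
# one-box closed forms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnalyticalAux:
    """Auxiliary quantities of the one-box closed form.

    ``lam = sqrt(kappa_bin / (2 alpha_syn))``, ``eta = 1 - N_b(0)/N_b_max``
    and ``C_zeta(t) = -N_b_max + N_b(0) + N_u(0) + alpha_syn t``.
    """

    lam: float
    eta: float
    c_zeta0: float
    alpha: float

    def c_zeta(self, t):
        return self.c_zeta0 + self.alpha * np.asarray(t, dtype=float)


def analytical_aux(
    config: SystemConfig, capacity: float, N_b0: float = 0.0, N_u0: float = 0.0
) -> AnalyticalAux:
    alpha, kappa = config.alpha_per_t, config.kappa_per_t
    if alpha <= 0:
        raise ConfigError(
            "lambda = sqrt(kappa/(2 alpha)) is undefined for alpha_syn = 0; "
            "use onebox_bound_pure_binding or the integrator"
        )
    if capacity <= 0:
        raise ConfigError("capacity must be > 0 for the analytical form")
    return AnalyticalAux(
        lam=math.sqrt(kappa / (2.0 * alpha)),
        eta=1.0 - N_b0 / capacity,
        c_zeta0=-capacity + N_b0 + N_u0,
        alpha=alpha,
    )


def _bound_ratio(x0: np.ndarray, x1: np.ndarray, cap: float, eta: float, lam: float):
    """Evaluate eta*exp(-x1^2) / (exp(-x0^2) + cap*eta*lam*sqrt(pi)*(erf(x1)-erf(x0))).

    Piecewise evaluation keeps the ratio finite where the direct expression
    underflows: for strongly negative arguments both numerator and
    denominator vanish like exp(-x^2) and are rescaled through the scaled
    complementary error function; for large positive ``x1`` the system is
    saturated and the ratio is 0 to machine precision.
    """
    x0 = np.asarray(x0, dtype=float)
    x1 = np.asarray(x1, dtype=float)
    x0b, x1b = np.broadcast_arrays(*np.broadcast_arrays(x0, x1))
    out = np.empty(x1b.shape)

    pref = cap * eta * lam * math.sqrt(math.pi)

    sat = x1b >= _ERF_SATURATION
    neg = ~sat & (x1b <= 0.0)  # x0 <= x1 <= 0
    pos = ~sat & (x0b >= 0.0) & (x1b > 0.0)  # 0 <= x0 <= x1
    mid = ~(sat | neg | pos)  # x0 < 0 < x1 < saturation

    out[sat] = 0.0

    if np.any(neg):
        # multiply through by exp(x1^2); d <= 0, erfcx args >= 0
        a0, a1 = x0b[neg], x1b[neg]
        d = (a1 - a0) * (a1 + a0)
        ed = np.exp(d)
        den = ed + pref * (special.erfcx(-a1) - special.erfcx(-a0) * ed)
        out[neg] = eta / den

    if np.any(pos):
        # multiply through by exp(x0^2); d >= 0, erfcx args >= 0
        a0, a1 = x0b[pos], x1b[pos]
        d = (a1 - a0) * (a1 + a0)
        emd = np.exp(-d)
        den = 1.0 + pref * (special.erfcx(a0) - special.erfcx(a1) * emd)
        out[pos] = eta * emd / den

    if np.any(mid):
        # opposite signs: erf(x1) - erf(x0) adds two positive terms
        a0, a1 = x0b[mid], x1b[mid]
        num = eta * np.exp(-a1 * a1)
        den = np.exp(-a0 * a0) + pref * (special.erf(a1) - special.erf(a0))
        out[mid] = num / den

    return out


def onebox_bound_analytical(
    config: SystemConfig,
    capacity: float,
    N_b0: float = 0.0,
    N_u0: float = 0.0,
    t=0.0,
):
    """Closed-form bound-protein count ``N_b(t)`` of the one-box system.

    Solves ``dN_u/dt = -kappa N_u (cap - N_b) + alpha`` and
    ``dN_b/dt = kappa N_u (cap - N_b)`` for constant synthesis
    ``alpha = alpha_syn > 0``:

    ``N_b(t)/cap = 1 - eta exp(-lam^2 C(t)^2) /
    (exp(-lam^2 C(0)^2) + cap eta lam sqrt(pi) (erf(lam C(t)) - erf(lam C(0))))``

    with ``lam``, ``eta``, ``C = C_zeta`` from :func:`analytical_aux`.
    Accepts scalar or array ``t``; the result is nondecreasing in ``t`` and
    lies in ``[N_b0, capacity]``.

    Raises
    ------
    ConfigError
        If ``alpha_syn == 0`` (use :func:`onebox_bound_pure_binding`) or
        the initial state is inconsistent.
    """
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    if np.any(t < 0):
        raise ConfigError("t must be >= 0")
    if capacity == 0:
        out = np.zeros_like(t, dtype=float)
        return float(out) if scalar else out
    if N_b0 > capacity:
        raise ConfigError("N_b0 must be <= capacity")
    aux = analytical_aux(config, capacity, N_b0, N_u0)
    if config.kappa_per_t == 0.0:
        out = np.full_like(t, float(N_b0), dtype=float)
        return float(out) if scalar else out
    x0 = aux.lam * aux.c_zeta0
    x1 = aux.lam * aux.c_zeta(t)
    nb = capacity * (1.0 - _bound_ratio(x0, x1, capacity, aux.eta, aux.lam))
    nb = np.clip(nb, min(N_b0, capacity), capacity)
    return float(nb) if scalar else nb


def onebox_bound_pure_binding(
    config: SystemConfig,
    capacity: float,
    N_b0: float = 0.0,
    N_u0: float = 0.0,
    t=0.0,
):
    """Closed-form ``N_b(t)`` for the one-box system without synthesis.

    With ``alpha_syn = 0`` the total count ``N0 = N_b0 + N_u0`` is fixed and
    ``dN_b/dt = kappa (N0 - N_b)(cap - N_b)`` integrates to the two-fixed-
    point logistic-type solution

    ``(N0 - N_b)/(cap - N_b) = h(t)``,  ``h(t) = (N_u0/(cap-N_b0)) exp(kappa (N0-cap) t)``

    i.e. ``N_b(t) = (cap h - N0)/(h - 1)``; for the degenerate balance
    ``N0 == cap`` the decay is algebraic,
    ``N_b = cap - 1/(1/(cap-N_b0) + kappa t)``.  As ``t -> inf`` the bound
    count approaches ``min(N0, cap)``.
    """
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    if np.any(t < 0):
        raise ConfigError("t must be >= 0")
    kappa = config.kappa_per_t
    if capacity == 0:
        out = np.zeros_like(t, dtype=float)
        return float(out) if scalar else out
    if N_b0 > capacity:
        raise ConfigError("N_b0 must be <= capacity")
    N0 = N_b0 + N_u0
    if kappa == 0.0 or N_u0 == 0.0:
        out = np.full_like(t, float(N_b0), dtype=float)
        return float(out) if scalar else out
    if abs(N0 - capacity) <= 1e-12 * max(1.0, capacity):
        nb = capacity - 1.0 / (1.0 / (capacity - N_b0) + kappa * t)
    else:
        expo = kappa * (N0 - capacity) * t
        h0 = N_u0 / (capacity - N_b0)
        limit = min(N0, capacity)
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            h = h0 * np.exp(expo)
            nb = np.where(
                np.isfinite(h) & (np.abs(h - 1.0) > 1e-300),
                (capacity * h - N0) / (h - 1.0),
                limit,
            )
    nb = np.clip(nb, min(N_b0, capacity), min(max(N0, N_b0), capacity))
    return float(nb) if scalar else nb


# ---------------------------------------------------------------------------
# right-hand sides
# ---------------------------------------------------------------------------


def onebox_rhs(state: BoxState, config: SystemConfig, capacity: float):
    """Time derivatives ``(dN_u/dt, dN_b/dt)`` of the one-box system.

    ``dN_b/dt = kappa N_u (cap - N_b)`` and ``dN_u/dt = -dN_b/dt + alpha``;
    the two derivatives always sum to ``alpha_syn``.
    """
    if state.M != 1:
        raise ConfigError("onebox_rhs requires a single-box state")
    nu, nb = float(state.N_u[0]), float(state.N_b[0])
    dnb = config.kappa_per_t * nu * (capacity - nb)
    return -dnb + config.alpha_per_t, dnb


def multibox_rhs(
    state: BoxState,
    config: SystemConfig,
    traps: TrapPattern,
    sources: SynthesisPattern,
):
    """Time derivatives ``(dN_u/dt, dN_b/dt)`` of the M-box system.

    Interior boxes couple through the discrete Laplacian
    ``D_tilde (N_u[i+1] + N_u[i-1] - 2 N_u[i])``; the end boxes have a
    single neighbour (no-flux boundaries).  Binding acts per box as in
    :func:`onebox_rhs`; synthesis ``+alpha_syn`` applies only in source
    boxes.  Summed over boxes the derivatives add up to
    ``alpha_syn * |sources|`` (the differential mass balance).
    """
    M = state.M
    if traps.M != M:
        raise ConfigError("trap pattern length must equal state size")
    nu, nb = state.N_u, state.N_b
    bind = config.kappa_per_t * nu * (traps.capacities - nb)
    lap = np.zeros_like(nu)
    if M > 1:
        lap[1:-1] = nu[2:] + nu[:-2] - 2.0 * nu[1:-1]
        lap[0] = nu[1] - nu[0]
        lap[-1] = nu[-2] - nu[-1]
    dnu = config.D_per_t * lap - bind + config.alpha_per_t * sources.mask(M)
    return dnu, bind
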