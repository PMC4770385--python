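"""Right-hand sides of the swarmbot population models.

Three model families, all pure functions of state and parameters (no
integration, no I/O):

* a one-variable collective-survival model — logistic growth minus a
  density-dependent (Hill-repressed) death term, which is bistable for
  suitable parameters and defines the critical survival density ``N_CT``;
* its two-compartment extension with gradient-driven cell exchange between
  a capsule ("swarmbot", volume V1) and the surrounding chamber (V2);
* the full beta-lactamase (BlaM) circuit model — cell density, nutrient,
  antibiotic (carbenicillin) and extracellular BlaM — in dimensional and
  dimensionless form, single-compartment and two-compartment with pulsed
  dosing of the chamber.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

__all__ = [
    "SimplifiedParams",
    "TwoCompartmentSimplifiedParams",
    "BlamDimensionalParams",
    "BlamDimensionlessParams",
    "TransportParams",
    "SwarmbotState",
    "simplified_rate",
    "two_compartment_simplified_rates",
    "blam_growth",
    "blam_lysis",
    "blam_rhs",
    "blam_dimensional_rhs",
    "swarmbot_rhs",
    "dimensionless_from_dimensional",
    "clip_small_negatives",
]

#: states more negative than this indicate a real error, not solver jitter
HARD_NEGATIVE_LIMIT = -1e-9


def clip_small_negatives(x: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Clamp solver-induced tiny negative values to zero.

    Values in ``[HARD_NEGATIVE_LIMIT, tol)`` are set to 0; anything below
    ``HARD_NEGATIVE_LIMIT`` raises, because a genuinely negative density or
    concentration means the integration has gone wrong.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < HARD_NEGATIVE_LIMIT):
        raise ValueError(
            f"state has negative component(s) below {HARD_NEGATIVE_LIMIT}: {x}"
        )
    return np.where(x < tol, np.maximum(x, 0.0), x)


def _require_finite(x: np.ndarray, name: str = "state") -> None:
    if not np.all(np.isfinite(x)):
        raise ValueError(f"non-finite {name}: {x}")


# ---------------------------------------------------------------------------
# collective-survival (simplified density) model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimplifiedParams:
    """Parameters of the one-variable collective-survival model.

    dN/dt = mu*N*(1 - N/n_max) - death_max * K^alpha/(N^alpha + K^alpha) * N

    Growth is logistic; the per-capita death rate is maximal at low density
    and repressed (Hill, coefficient ``hill_alpha``) above the survival
    threshold ``survival_k``.  Defaults are the printed bistable set
    (mu=1.75, n_max=1, d=2, K=0.5, alpha=4).
    """

    mu: float = 1.75
    n_max: float = 1.0
    death_max: float = 2.0
    survival_k: float = 0.5
    hill_alpha: float = 4.0

    def __post_init__(self) -> None:
        for name in ("mu", "n_max", "death_max", "survival_k", "hill_alpha"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be positive and finite, got {v}")
        if self.hill_alpha < 1:
            raise ValueError(f"hill_alpha must be >= 1, got {self.hill_alpha}")

    def to_dict(self) -> dict:
        return asdict(self)


def simplified_rate(n, p: SimplifiedParams):
    """dN/dt of the collective-survival model; accepts scalar or array N."""
    n = np.asarray(n, dtype=float)
    _require_finite(n, "density")
    if np.any(n < 0):
        raise ValueError(f"density must be >= 0, got {n}")
    ka = p.survival_k**p.hill_alpha
    growth = p.mu * n * (1.0 - n / p.n_max)
    death = p.death_max * ka / (n**p.hill_alpha + ka) * n
    out = growth - death
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class TwoCompartmentSimplifiedParams:
    """Collective-survival model in capsule + chamber, coupled by cell escape.

    ``f_n_cells`` is the gradient-driven cell transport rate constant;
    ``v_ratio`` is V2/V1 (chamber over capsule), which scales the flux as
    seen by the chamber.
    """

    base: SimplifiedParams = field(default_factory=SimplifiedParams)
    f_n_cells: float = 0.1
    v_ratio: float = 10.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.f_n_cells) or self.f_n_cells < 0:
            raise ValueError(f"f_n_cells must be >= 0, got {self.f_n_cells}")
        if not np.isfinite(self.v_ratio) or self.v_ratio <= 0:
            raise ValueError(f"v_ratio must be > 0, got {self.v_ratio}")

    def to_dict(self) -> dict:
        return asdict(self)


def two_compartment_simplified_rates(state, p: TwoCompartmentSimplifiedParams):
    """(dN_MSB/dt, dN_Out/dt) for the two-compartment collective-survival model.

    Each compartment follows the one-variable model on its local density; the
    capsule loses cells at rate f_N*(N_MSB - N_Out) and the chamber receives
    the same flux scaled by 1/V_R.
    """
    state = np.asarray(state, dtype=float)
    _require_finite(state)
    if state.shape != (2,):
        raise ValueError(f"state must be (N_MSB, N_Out), got shape {state.shape}")
    n_in, n_out = state
    flux = p.f_n_cells * (n_in - n_out)
    d_in = simplified_rate(n_in, p.base) - flux
    d_out = simplified_rate(n_out, p.base) + flux / p.v_ratio
    return np.array([d_in, d_out])


# ---------------------------------------------------------------------------
# full BlaM circuit model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BlamDimensionalParams:
    """Dimensional parameters of the BlaM circuit model (N, S, A, B).

    Growth G is Monod in nutrient S (half-constant ``k_s``) times logistic
    crowding; lysis L is Michaelis-Menten in antibiotic A (half-constant
    ``k_lysis``) times the growth excess over the threshold fraction
    ``g0_frac`` of mu_max (beta-lactams kill growing cells only).  BlaM is
    released by lysis (``k_bla``), decays at ``d_b`` and degrades antibiotic
    with catalytic rate ``v_max`` / half-constant ``k_amp``.

    Note: ``alpha_consume`` is the nutrient consumption yield, unrelated to
    the Hill exponent of :class:`SimplifiedParams`.
    """

    mu_max: float = 1.0
    k_s: float = 1.0
    n_m: float = 1.0
    d_a_max: float = 6.75
    k_lysis: float = 1.0
    g0_frac: float = 0.1
    alpha_consume: float = 1.0
    k_release: float = 0.2
    v_max: float = 1.0
    k_amp: float = 1.0
    d_b: float = 1.0
    k_bla: float = 2.0

    def __post_init__(self) -> None:
        positive = (
            "mu_max", "k_s", "n_m", "d_a_max", "k_lysis",
            "alpha_consume", "k_release", "v_max", "k_amp", "d_b", "k_bla",
        )
        for name in positive:
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be positive and finite, got {v}")
        if not 0 <= self.g0_frac < 1:
            raise ValueError(f"g0_frac must be in [0, 1), got {self.g0_frac}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class BlamDimensionlessParams:
    """Dimensionless groups of the BlaM circuit model.

    gamma1: maximum lysis rate over mu_max; gamma2: nutrient consumption per
    unit growth; gamma3: BlaM decay; beta1: nutrient recycled per lysed cell;
    beta2: BlaM released per lysed cell; sigma: lysis efficiency factor;
    g0: growth threshold below which antibiotic cannot lyse.

    The defaults are this package's documented base set (see the methods
    note): they place the antibiotic growth threshold near a ~ 0.2 and make
    the static capsule bistable at a = 0.4.
    """

    gamma1: float = 6.75
    gamma2: float = 1.0
    gamma3: float = 1.0
    beta1: float = 0.2
    beta2: float = 2.0
    sigma: float = 1.0
    g0: float = 0.1

    def __post_init__(self) -> None:
        for name in ("gamma1", "gamma2", "gamma3", "beta1", "beta2", "sigma", "g0"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be >= 0 and finite, got {v}")
        if self.g0 >= 1:
            raise ValueError(f"g0 must be < 1, got {self.g0}")

    def to_dict(self) -> dict:
        return asdict(self)


def blam_growth(s, n):
    """Dimensionless growth rate g = s/(1+s) * (1-n)."""
    s = np.asarray(s, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(s < 0) or np.any(n < 0):
        raise ValueError("nutrient and density must be >= 0")
    out = s / (1.0 + s) * (1.0 - n)
    return out if out.ndim else float(out)


def blam_lysis(a, g, p: BlamDimensionlessParams):
    """Dimensionless lysis rate l = max(sigma * a/(1+a) * (g - g0), 0).

    Zero whenever the population grows slower than g0 or there is no
    antibiotic: beta-lactam killing requires active wall synthesis.
    """
    a = np.asarray(a, dtype=float)
    g = np.asarray(g, dtype=float)
    if np.any(a < 0):
        raise ValueError("antibiotic concentration must be >= 0")
    out = np.maximum(p.sigma * a / (1.0 + a) * (g - p.g0), 0.0)
    return out if out.ndim else float(out)


def blam_rhs(state, p: BlamDimensionlessParams) -> np.ndarray:
    """d(n, s, a, b)/dtau of the dimensionless single-compartment BlaM model."""
    state = np.asarray(state, dtype=float)
    _require_finite(state)
    n, s, a, b = clip_small_negatives(state)
    # the logistic factor may go slightly negative if n overshoots 1
    g = s / (1.0 + s) * (1.0 - n)
    l = blam_lysis(a, g, p)
    dn = g * n - p.gamma1 * l * n
    ds = -p.gamma2 * g * n + p.beta1 * p.gamma1 * l * n
    da = -b * a / (1.0 + a)
    db = -p.gamma3 * b + p.beta2 * p.gamma1 * l * n
    return np.array([dn, ds, da, db])


def blam_dimensional_rhs(state, p: BlamDimensionalParams) -> np.ndarray:
    """d(N, S, A, B)/dt of the dimensional single-compartment BlaM model."""
    state = np.asarray(state, dtype=float)
    _require_finite(state)
    N, S, A, B = clip_small_negatives(state)
    G = p.mu_max * S / (p.k_s + S) * (1.0 - N / p.n_m)
    L = p.d_a_max * A / (p.k_lysis + A) * max(G / p.mu_max - p.g0_frac, 0.0)
    dN = G * N - L * N
    dS = -p.alpha_consume * G * N + p.k_release * L * N
    dA = -p.v_max * B * A / (p.k_amp + A)
    dB = -p.d_b * B + p.k_bla * L * N
    return np.array([dN, dS, dA, dB])


def dimensionless_from_dimensional(p: BlamDimensionalParams) -> BlamDimensionlessParams:
    """Dimensionless groups implied by a dimensional parameter set.

    Uses the scalings n=N/N_m, s=S/K_s, a=A/K_amp, b=v_max*B/(mu_max*K_amp),
    tau=mu_max*t, and requires K_lysis == K_amp so the lysis saturation
    becomes a/(1+a).  The lysis efficiency sigma is folded into gamma1
    (sigma = 1).
    """
    if not np.isclose(p.k_lysis, p.k_amp):
        raise ValueError(
            "the dimensionless reduction assumes k_lysis == k_amp "
            f"(got {p.k_lysis} vs {p.k_amp})"
        )
    return BlamDimensionlessParams(
        gamma1=p.d_a_max / p.mu_max,
        gamma2=p.alpha_consume * p.n_m / p.k_s,
        gamma3=p.d_b / p.mu_max,
        beta1=p.k_release * p.n_m / p.k_s,
        beta2=p.k_bla * p.v_max * p.n_m / (p.mu_max * p.k_amp),
        sigma=1.0,
        g0=p.g0_frac,
    )


# ---------------------------------------------------------------------------
# two-compartment BlaM model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TransportParams:
    """Per-species transport rate constants across the capsule shell.

    Rates are gradient-driven: compartment 1 (capsule) sees f_x*(x2-x1),
    compartment 2 (chamber) sees (f_x/v_ratio)*(x1-x2).  Cells are ~3 orders
    of magnitude larger than the molecules, so f_n must not exceed the
    molecular rates.
    """

    f_n: float = 0.01
    f_s: float = 0.5
    f_a: float = 0.3
    f_b: float = 0.1
    v_ratio: float = 10.0

    def __post_init__(self) -> None:
        for name in ("f_n", "f_s", "f_a", "f_b"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if not np.isfinite(self.v_ratio) or self.v_ratio <= 0:
            raise ValueError(f"v_ratio must be > 0, got {self.v_ratio}")
        if not (self.f_n <= self.f_b <= self.f_s and self.f_n <= self.f_a):
            raise ValueError(
                "transport rates must satisfy f_n <= f_b <= f_s and f_n <= f_a "
                f"(cells are far larger than molecules); got f_n={self.f_n}, "
                f"f_b={self.f_b}, f_s={self.f_s}, f_a={self.f_a}"
            )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class SwarmbotState:
    """State of the two-compartment BlaM model (dimensionless).

    Index 1 = inside the capsule, index 2 = chamber; per compartment: cell
    density n, nutrient s, antibiotic a, BlaM b.
    """

    n1: float = 0.0
    s1: float = 0.0
    a1: float = 0.0
    b1: float = 0.0
    n2: float = 0.0
    s2: float = 0.0
    a2: float = 0.0
    b2: float = 0.0

    ORDER = ("n1", "s1", "a1", "b1", "n2", "s2", "a2", "b2")

    def __post_init__(self) -> None:
        arr = self.as_array()
        _require_finite(arr)
        if np.any(arr < 0):
            raise ValueError(f"all state components must be >= 0, got {arr}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in self.ORDER], dtype=float)

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "SwarmbotState":
        arr = clip_small_negatives(np.asarray(arr, dtype=float))
        if arr.shape != (8,):
            raise ValueError(f"expected 8 components, got shape {arr.shape}")
        return cls(**dict(zip(cls.ORDER, arr.tolist())))

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.ORDER}


def swarmbot_rhs(
    state,
    p: BlamDimensionlessParams,
    tp: TransportParams,
    dosing_rate: float = 0.0,
    inputs: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Eight rates of the two-compartment BlaM model under dilution D.

    ``inputs`` is (I_s, I_a), the nutrient and antibiotic concentrations of
    the fresh medium.  Dilution at rate ``dosing_rate`` acts on the chamber
    only: every chamber species is washed out at -D*x2, and nutrient and
    antibiotic are replenished at +D*I_s and +D*I_a.  The capsule is shielded
    from the flow.
    """
    state = np.asarray(state, dtype=float)
    _require_finite(state)
    if dosing_rate < 0:
        raise ValueError(f"dosing_rate must be >= 0, got {dosing_rate}")
    n1, s1, a1, b1, n2, s2, a2, b2 = clip_small_negatives(state)
    i_s, i_a = inputs
    D = dosing_rate
    vr = tp.v_ratio

    g1 = s1 / (1.0 + s1) * (1.0 - n1)
    l1 = blam_lysis(a1, g1, p)
    g2 = s2 / (1.0 + s2) * (1.0 - n2)
    l2 = blam_lysis(a2, g2, p)

    dn1 = g1 * n1 - p.gamma1 * l1 * n1 + tp.f_n * (n2 - n1)
    ds1 = -p.gamma2 * g1 * n1 + p.beta1 * p.gamma1 * l1 * n1 + tp.f_s * (s2 - s1)
    da1 = -b1 * a1 / (1.0 + a1) + tp.f_a * (a2 - a1)
    db1 = -p.gamma3 * b1 + p.beta2 * p.gamma1 * l1 * n1 + tp.f_b * (b2 - b1)

    dn2 = g2 * n2 - p.gamma1 * l2 * n2 + tp.f_n / vr * (n1 - n2) - D * n2
    ds2 = (
        -p.gamma2 * g2 * n2
        + p.beta1 * p.gamma1 * l2 * n2
        + tp.f_s / vr * (s1 - s2)
        + D * i_s
        - D * s2
    )
    da2 = -b2 * a2 / (1.0 + a2) + tp.f_a / vr * (a1 - a2) + D * i_a - D * a2
    db2 = -p.gamma3 * b2 + p.beta2 * p.gamma1 * l2 * n2 + tp.f_b / vr * (b1 - b2) - D * b2

    return np.array([dn1, ds1, da1, db1, dn2, ds2, da2, db2])
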