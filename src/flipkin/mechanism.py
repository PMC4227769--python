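"""Kinetic scheme for multistep lesion recognition by a flipping DNA glycosylase.

The minimal mechanism is

    E + D  <=>  ENS  -->  IRC  <=>  SRC  -->  P + E
        (k_on, k_off_ns) (m*k_search,     (k_flip,   (k_chem)
                          k_escape)        k_unflip)

where D is free lesion-containing duplex, ENS the nonspecifically bound
enzyme-DNA complex, IRC the initial recognition complex at the lesion (base
still intrahelical), SRC the specific recognition complex with the damaged
nucleotide flipped into the active site, and P the abasic product.  ``m`` is
an occupancy multiplier: under the additive searching model several
nonspecifically bound proteins scan the same duplex and the lesion is found
``m`` times faster.

A pulse-chase quench ("chase") sequesters every enzyme molecule that is not
holding the flipped-out lesion: free enzyme, nonspecific and initial
recognition complexes are captured by the excess inhibitor DNA, so the only
surviving dynamics is the partitioning of SRC between N-glycosidic bond
cleavage (k_chem) and unflipping followed by dissociation (k_unflip).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "FlipKinError",
    "ValidationError",
    "IntegrationError",
    "UndefinedValueError",
    "RateConstantSet",
    "SpeciesState",
    "MechanismSpec",
    "Trajectory",
    "FateTally",
    "SPECIES",
    "SITE_CAPACITY",
    "simulate_timecourse",
    "simulate_stochastic",
    "equilibrium_flip_constant",
    "commitment_to_catalysis",
    "unflip_from_commitment",
    "observed_flip_rate",
    "occupancy_multiplier",
    "table1_rates",
    "TABLE1_VARIANTS",
]


class FlipKinError(Exception):
    """Base class for package errors."""


class ValidationError(FlipKinError, ValueError):
    """Invalid input (negative rate/concentration, malformed grid, ...)."""


class IntegrationError(FlipKinError, RuntimeError):
    """Stiff integration failed; message names the time of failure."""


class UndefinedValueError(FlipKinError, ValueError):
    """A derived quantity is undefined for the given inputs."""


# Species order used throughout: free enzyme, free lesion DNA, nonspecific
# complex, initial recognition complex, specific (flipped) complex, abasic
# product, chase-sequestered enzyme.
SPECIES = ("E", "D", "ENS", "IRC", "SRC", "P", "EQ")

#: maximum number of simultaneously searching proteins per 25mer duplex
SITE_CAPACITY = 10.0

# Share of k_find attributed to the forward (finding) step.  The initial
# recognition complex is strongly committed forward, which keeps the slow
# relaxation of the scheme equal to k_flip + k_unflip at the precision the
# phase analysis relies on.
_FIND_COMMITMENT = 0.99

_ODE_RTOL = 1e-10
_ODE_ATOL = 1e-15


def _require_finite_nonneg(name: str, value: float) -> float:
    v = float(value)
    if not math.isfinite(v) or v < 0:
        raise ValidationError(f"{name} must be finite and >= 0, got {value!r}")
    return v


@dataclass(frozen=True)
class RateConstantSet:
    """Microscopic rate constants of one enzyme variant.

    Parameters
    ----------
    k_on : float
        Bimolecular association rate with nonspecific DNA (M^-1 s^-1).
    k_off_ns : float
        Dissociation from nonspecific DNA (s^-1).
    k_search : float
        Per-bound-protein lesion-finding rate, ENS -> IRC (s^-1).
    k_escape : float
        Rate of leaving the initial recognition complex back to the
        nonspecific complex (s^-1).
    k_flip, k_unflip : float
        Forward/reverse nucleotide flipping rates, IRC <-> SRC (s^-1).
    k_chem : float
        N-glycosidic bond cleavage rate from SRC (s^-1).
    """

    k_on: float
    k_search: float
    k_escape: float
    k_flip: float
    k_unflip: float
    k_chem: float
    k_off_ns: float = 1.0

    def __post_init__(self) -> None:
        for name in ("k_on", "k_off_ns", "k_search", "k_escape",
                     "k_flip", "k_unflip", "k_chem"):
            _require_finite_nonneg(name, getattr(self, name))

    @property
    def k_find(self) -> float:
        """Macroscopic searching rate constant: sum of finding and leaving."""
        return self.k_search + self.k_escape

    @property
    def K_flip(self) -> float:
        return equilibrium_flip_constant(self.k_flip, self.k_unflip)

    @classmethod
    def from_observables(cls, k_on: float, k_find: float, k_flip: float,
                         k_unflip: float, k_chem: float,
                         find_commitment: float = _FIND_COMMITMENT,
                         k_off_ns: float = 1.0) -> "RateConstantSet":
        """Build a rate set from the experimentally observable constants.

        k_find is split into k_search = find_commitment * k_find and
        k_escape = (1 - find_commitment) * k_find.
        """
        if not 0 < find_commitment <= 1:
            raise ValidationError("find_commitment must be in (0, 1]")
        k_find = _require_finite_nonneg("k_find", k_find)
        return cls(k_on=k_on, k_search=find_commitment * k_find,
                   k_escape=(1.0 - find_commitment) * k_find,
                   k_flip=k_flip, k_unflip=k_unflip, k_chem=k_chem,
                   k_off_ns=k_off_ns)

    def replace(self, **kw) -> "RateConstantSet":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "RateConstantSet":
        return cls(**json.loads(s))


def table1_rates(variant: str, context: str = "TEC") -> RateConstantSet:
    """Published microscopic constants for an enzyme variant.

    For Y162A the binding and searching steps are too fast to measure; the
    values used here are lower-bound stand-ins fast enough that both phases
    complete within the instrument dead time (they are reported as limits,
    never as measurements, by the analysis layer).  In the AEA sequence
    context Y162A flips at 66 s^-1 instead of 170 s^-1.
    """
    key = (variant.upper(), context.upper())
    obs = {
        ("WT", "TEC"): dict(k_on=1.1e9, k_find=116.0, k_flip=3.6,
                            k_unflip=1.6e-3, k_chem=8.0e-4),
        ("WT", "AEA"): dict(k_on=1.1e9, k_find=116.0, k_flip=3.6,
                            k_unflip=1.6e-3, k_chem=8.0e-4),
        ("Y162F", "TEC"): dict(k_on=2.1e9, k_find=114.0, k_flip=7.9,
                               k_unflip=4.6e-3, k_chem=4.3e-4),
        ("Y162F", "AEA"): dict(k_on=2.1e9, k_find=114.0, k_flip=7.9,
                               k_unflip=4.6e-3, k_chem=4.3e-4),
        ("Y162A", "TEC"): dict(k_on=1.0e10, k_find=5000.0, k_flip=170.0,
                               k_unflip=10.0, k_chem=3.8e-4),
        ("Y162A", "AEA"): dict(k_on=1.0e10, k_find=5000.0, k_flip=66.0,
                               k_unflip=10.0, k_chem=3.8e-4),
    }
    if key not in obs:
        raise ValidationError(
            f"unknown variant/context {variant!r}/{context!r}; "
            "known variants: WT, Y162F, Y162A; contexts: TEC, AEA")
    return RateConstantSet.from_observables(**obs[key])


TABLE1_VARIANTS = ("WT", "Y162F", "Y162A")


@dataclass(frozen=True)
class SpeciesState:
    """Concentrations (M) of the seven mechanism species."""

    E: float = 0.0
    D: float = 0.0
    ENS: float = 0.0
    IRC: float = 0.0
    SRC: float = 0.0
    P: float = 0.0
    EQ: float = 0.0

    def __post_init__(self) -> None:
        for name in SPECIES:
            _require_finite_nonneg(name, getattr(self, name))

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, s) for s in SPECIES], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "SpeciesState":
        y = np.asarray(y, dtype=float)
        return cls(**{s: max(v, 0.0) for s, v in zip(SPECIES, y)})

    @classmethod
    def premix(cls, E_tot: float, D_tot: float) -> "SpeciesState":
        """State immediately after mixing free enzyme with free DNA."""
        return cls(E=E_tot, D=D_tot)

    @property
    def total_dna(self) -> float:
        return self.D + self.ENS + self.IRC + self.SRC + self.P

    @property
    def total_enzyme(self) -> float:
        return self.E + self.ENS + self.IRC + self.SRC + self.EQ


@dataclass(frozen=True)
class MechanismSpec:
    """A rate set plus the occupancy and chase behaviour of one experiment.

    occupancy_model:
        "single"   — one protein searches each duplex (multiplier 1).
        "additive" — the expected number of nonspecifically bound proteins
                     per duplex scan in parallel; the NS -> IRC flux is
                     multiplied by clip(E_tot / D_tot, 1, SITE_CAPACITY).
    chase:
        False — no quench.
        True  — excess inhibitor DNA sequesters every enzyme not engaged in
                the flipped complex (absorbing sink EQ); applied
                instantaneously at the start of the simulation.
    """

    rates: RateConstantSet
    occupancy_model: str = "additive"
    chase: bool = False

    def __post_init__(self) -> None:
        if self.occupancy_model not in ("single", "additive"):
            raise ValidationError(
                f"occupancy_model must be 'single' or 'additive', "
                f"got {self.occupancy_model!r}")

    def with_chase(self, chase: bool = True) -> "MechanismSpec":
        return replace(self, chase=chase)

    def to_json(self) -> str:
        return json.dumps({"rates": self.rates.to_dict(),
                           "occupancy_model": self.occupancy_model,
                           "chase": self.chase})

    @classmethod
    def from_json(cls, s: str) -> "MechanismSpec":
        d = json.loads(s)
        return cls(rates=RateConstantSet(**d["rates"]),
                   occupancy_model=d["occupancy_model"], chase=d["chase"])


def occupancy_multiplier(spec: MechanismSpec, E_tot: float,
                         D_tot: float) -> float:
    """Expected number of simultaneously searching proteins per duplex.

    Every nonspecific complex carries at least the one protein that defines
    it, hence the floor at 1; the ceiling is the duplex site capacity.
    """
    if spec.occupancy_model == "single":
        return 1.0
    if D_tot <= 0:
        return 1.0
    return float(np.clip(E_tot / D_tot, 1.0, SITE_CAPACITY))


def apply_chase(state: SpeciesState) -> SpeciesState:
    """Instantaneous capture of non-flipped enzyme by the chase inhibitor."""
    captured = state.E + state.ENS + state.IRC
    return SpeciesState(E=0.0, D=state.D + state.ENS + state.IRC,
                        ENS=0.0, IRC=0.0, SRC=state.SRC, P=state.P,
                        EQ=state.EQ + captured)


def _rhs(spec: MechanismSpec, m: float):
    k = spec.rates
    if spec.chase:
        def rhs(t, y):
            src = y[4]
            v_un = k.k_unflip * src
            v_ch = k.k_chem * src
            return [0.0, v_un, 0.0, 0.0, -(v_un + v_ch), v_ch, v_un + v_ch]
        return rhs

    def rhs(t, y):
        E, D, ENS, IRC, SRC = y[0], y[1], y[2], y[3], y[4]
        v_bind = k.k_on * E * D
        v_unbind = k.k_off_ns * ENS
        v_search = m * k.k_search * ENS
        v_escape = k.k_escape * IRC
        v_flip = k.k_flip * IRC
        v_unflip = k.k_unflip * SRC
        v_chem = k.k_chem * SRC
        return [
            -v_bind + v_unbind + v_chem,                       # E
            -v_bind + v_unbind,                                # D
            v_bind - v_unbind - v_search + v_escape,           # ENS
            v_search - v_escape - v_flip + v_unflip,           # IRC
            v_flip - v_unflip - v_chem,                        # SRC
            v_chem,                                            # P
            0.0,                                               # EQ
        ]
    return rhs


@dataclass
class Trajectory:
    """Deterministic time course: times (s) and species concentrations (M)."""

    times: np.ndarray
    concentrations: np.ndarray  # shape (len(times), len(SPECIES))
    spec: MechanismSpec = field(repr=False, default=None)

    def __getitem__(self, species: str) -> np.ndarray:
        return self.concentrations[:, SPECIES.index(species)]

    def state_at(self, i: int) -> SpeciesState:
        return SpeciesState.from_array(self.concentrations[i])

    def as_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.concentrations, columns=list(SPECIES))
        df.insert(0, "time_s", self.times)
        return df

    def to_csv(self, path) -> None:
        self.as_frame().to_csv(path, index=False)


def _validate_times(times) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise ValidationError("times must be a 1-D grid with >= 2 points")
    if not np.all(np.isfinite(t)) or t[0] < 0 or np.any(np.diff(t) <= 0):
        raise ValidationError("times must be finite, start >= 0 and be "
                              "strictly increasing")
    return t


def simulate_timecourse(spec: MechanismSpec, initial: SpeciesState,
                        times) -> Trajectory:
    """Integrate the mass-action scheme over a strictly increasing grid.

    The chase (if any) is applied instantaneously at t = times[0].  Uses a
    stiff-capable integrator (LSODA with BDF fallback); rates in a single
    experiment span many orders of magnitude (e.g. 10 s^-1 unflipping next
    to 1.6e-3 s^-1).
    """
    t = _validate_times(times)
    if spec.chase:
        initial = apply_chase(initial)
    y0 = initial.as_array()
    m = occupancy_multiplier(spec, initial.total_enzyme, initial.total_dna)
    rhs = _rhs(spec, m)

    scale = max(initial.total_dna, initial.total_enzyme, 1e-12)
    sol = solve_ivp(rhs, (t[0], t[-1]), y0, t_eval=t, method="LSODA",
                    rtol=_ODE_RTOL, atol=_ODE_ATOL * max(scale / 1e-7, 1.0))
    if not sol.success:
        sol = solve_ivp(rhs, (t[0], t[-1]), y0, t_eval=t, method="BDF",
                        rtol=_ODE_RTOL, atol=_ODE_ATOL * max(scale / 1e-7, 1.0))
    if not sol.success:
        t_fail = sol.t[-1] if sol.t.size else t[0]
        raise IntegrationError(
            f"stiff integration failed near t = {t_fail:.6g} s: {sol.message}")

    y = sol.y.T
    if np.any(y < -1e-12 * max(scale, 1.0)):
        raise IntegrationError(
            "integration produced significantly negative concentrations")
    y = np.clip(y, 0.0, None)
    return Trajectory(times=t, concentrations=y, spec=spec)


# ---------------------------------------------------------------------------
# Stochastic (per-molecule) simulation — cross-validation oracle for the
# pulse-chase partitioning analysis.
# ---------------------------------------------------------------------------

_S_D, _S_ENS, _S_IRC, _S_SRC, _S_P, _S_GONE = range(6)
_STATE_CODES = {"D": _S_D, "ENS": _S_ENS, "IRC": _S_IRC, "SRC": _S_SRC,
                "P": _S_P}


@dataclass(frozen=True)
class FateTally:
    """Per-molecule fates after a stochastic pulse-chase simulation."""

    product: int
    dissociated: int
    still_bound: int

    @property
    def n(self) -> int:
        return self.product + self.dissociated + self.still_bound

    @property
    def fraction_product(self) -> float:
        return self.product / self.n

    @property
    def fraction_dissociated(self) -> float:
        return self.dissociated / self.n


def simulate_stochastic(spec: MechanismSpec, n_molecules: int, seed: int,
                        horizon: float, start: str = "SRC",
                        enzyme_conc: float = 0.0,
                        occupancy: float = 1.0) -> FateTally:
    """Continuous-time Markov simulation of n single DNA molecules.

    Each molecule performs a jump chain over {D, ENS, IRC, SRC, P} with the
    mechanism's rates (binding is pseudo-first-order at the fixed free
    enzyme concentration ``enzyme_conc``).  With ``spec.chase`` active, any
    molecule whose enzyme is not in the flipped complex is captured by the
    inhibitor: the fate is decided by the SRC partition between cleavage and
    unflipping.  Fates partition into {product, dissociated, still bound}.
    """
    if n_molecules < 1:
        raise ValidationError("n_molecules must be >= 1")
    if not horizon > 0:
        raise ValidationError("horizon must be > 0")
    if start not in _STATE_CODES:
        raise ValidationError(f"start must be one of {sorted(_STATE_CODES)}")

    k = spec.rates
    rng = np.random.default_rng(seed)
    state = np.full(n_molecules, _STATE_CODES[start], dtype=np.int64)
    t = np.zeros(n_molecules)

    if spec.chase:
        # Non-flipped states are captured instantly.
        mask = (state == _S_D) | (state == _S_ENS) | (state == _S_IRC)
        state[mask] = _S_GONE

    # per-state (total exit rate, [branch rates...], [branch targets...])
    table = {
        _S_D: ([k.k_on * enzyme_conc], [_S_ENS]),
        _S_ENS: ([k.k_off_ns, occupancy * k.k_search], [_S_D, _S_IRC]),
        _S_IRC: ([k.k_escape, k.k_flip], [_S_ENS, _S_SRC]),
        _S_SRC: ([k.k_unflip, k.k_chem],
                 [_S_GONE if spec.chase else _S_IRC, _S_P]),
    }

    max_steps = 100_000
    for _ in range(max_steps):
        active = (state != _S_P) & (state != _S_GONE) & (t < horizon)
        if not active.any():
            break
        idx = np.flatnonzero(active)
        for code, (rates, targets) in table.items():
            sub = idx[state[idx] == code]
            if sub.size == 0:
                continue
            total = float(sum(rates))
            if total <= 0:
                t[sub] = horizon  # absorbing within the horizon
                continue
            dt = rng.exponential(1.0 / total, size=sub.size)
            u = rng.random(sub.size)
            new_t = t[sub] + dt
            # branch choice
            probs = np.cumsum(np.asarray(rates) / total)
            choice = np.searchsorted(probs, u, side="right")
            choice = np.minimum(choice, len(targets) - 1)
            jumped = new_t <= horizon
            t[sub] = np.where(jumped, new_t, horizon)
            new_state = np.asarray(targets)[choice]
            state[sub] = np.where(jumped, new_state, state[sub])
    else:  # pragma: no cover - guard against runaway chains
        raise IntegrationError("stochastic simulation exceeded step budget")

    product = int(np.count_nonzero(state == _S_P))
    gone = int(np.count_nonzero((state == _S_GONE) | (state == _S_D)))
    still = n_molecules - product - gone
    return FateTally(product=product, dissociated=gone, still_bound=still)


# ---------------------------------------------------------------------------
# Closed-form constants
# ---------------------------------------------------------------------------

def equilibrium_flip_constant(k_flip: float, k_unflip: float) -> float:
    """K_flip = k_flip / k_unflip (dimensionless)."""
    _require_finite_nonneg("k_flip", k_flip)
    _require_finite_nonneg("k_unflip", k_unflip)
    if k_unflip == 0:
        raise UndefinedValueError("K_flip undefined when k_unflip = 0")
    return k_flip / k_unflip


def commitment_to_catalysis(k_chem: float, k_unflip: float) -> float:
    """Fraction of the flipped complex that partitions forward to product.

    C = k_chem / (k_chem + k_unflip), the probability that N-glycosidic bond
    cleavage beats unflipping-and-dissociation in a chased complex.
    """
    _require_finite_nonneg("k_chem", k_chem)
    _require_finite_nonneg("k_unflip", k_unflip)
    if k_chem == 0 and k_unflip == 0:
        raise UndefinedValueError(
            "commitment undefined when both k_chem and k_unflip are 0")
    return k_chem / (k_chem + k_unflip)


def unflip_from_commitment(k_chem: float, commitment: float) -> float:
    """Invert the pulse-chase partition: k_unflip = k_chem (1 - C) / C."""
    _require_finite_nonneg("k_chem", k_chem)
    if k_chem == 0:
        raise ValidationError("k_chem must be > 0 to infer k_unflip")
    if not 0 < commitment <= 1:
        if commitment == 0:
            raise UndefinedValueError(
                "commitment 0 gives an infinite unflipping rate; the "
                "pulse-chase provides only a lower limit")
        raise ValidationError("commitment must be in (0, 1]")
    return k_chem * (1.0 - commitment) / commitment


def observed_flip_rate(k_flip: float, k_unflip: float) -> float:
    """Observed relaxation of the isolated flipping step: k_flip + k_unflip."""
    _require_finite_nonneg("k_flip", k_flip)
    _require_finite_nonneg("k_unflip", k_unflip)
    return k_flip + k_unflip
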