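"""Synthetic stopped-flow and gel observables for every experiment class.

Fluorescence traces are generated from the mechanism ODE through a
per-species signal model: the lesion base is intrinsically fluorescent and
its yield depends on the stacking environment, so each mechanism state
carries a coefficient relative to free DNA.  In the quenched sequence
context (TEC) the initial recognition complex is brighter than free DNA and
the flipped complex dimmer (rise-then-fall traces); in the bright context
(AEA) every bound state is dimmer (monotonic quench).

All generators take an explicit seed and are bit-reproducible; instrument
dead time removes the points recorded before flow stop, and noise is
additive Gaussian in signal units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .mechanism import (
    MechanismSpec,
    SpeciesState,
    Trajectory,
    ValidationError,
    apply_chase,
    simulate_timecourse,
)

__all__ = [
    "FluorescenceModel",
    "MixingExperiment",
    "Trace",
    "default_time_grid",
    "synthesize_association_trace",
    "synthesize_double_mixing_trace",
    "tight_binding_fraction",
    "synthesize_titration",
    "synthesize_single_turnover",
    "synthesize_competition_series",
    "write_trace",
    "read_trace",
]

#: dead time of the stopped-flow instrument (s)
DEFAULT_DEAD_TIME = 1.5e-3
#: Gaussian noise SD as a fraction of the free-DNA signal
DEFAULT_NOISE_SD = 0.005


@dataclass(frozen=True)
class FluorescenceModel:
    """Per-species fluorescence coefficients for one sequence context.

    Coefficients are normalized to free DNA (c_D = 1).  The optional drift
    term models a slow multiplicative photobleaching artifact
    exp(-k_bleach * t); off by default.
    """

    context: str = "TEC"
    coefficients: dict = field(default_factory=dict)
    bleach_rate: float = 0.0

    def __post_init__(self) -> None:
        c = {"D": 1.0, "ENS": 1.0, "IRC": 1.0, "SRC": 1.0, "P": 1.0}
        c.update(self.coefficients)
        if c["D"] != 1.0:
            # renormalize so the free-DNA signal defines the unit
            c = {k: v / c["D"] for k, v in c.items()}
        object.__setattr__(self, "coefficients", c)
        if self.bleach_rate < 0:
            raise ValidationError("bleach_rate must be >= 0")

    @classmethod
    def tec_default(cls, bleach_rate: float = 0.0) -> "FluorescenceModel":
        """Quenched context: the initial recognition complex is brighter
        than free DNA, the flipped complex dimmer (rise then fall)."""
        return cls("TEC", {"D": 1.0, "ENS": 1.0, "IRC": 1.6, "SRC": 0.55},
                   bleach_rate)

    @classmethod
    def aea_default(cls, variant: str = "WT",
                    bleach_rate: float = 0.0) -> "FluorescenceModel":
        """Bright context: binding quenches.  The flipped-complex quench is
        5-fold for WT and 2-3-fold for the intercalation mutants."""
        src = 0.2 if variant.upper() == "WT" else 0.4
        return cls("AEA", {"D": 1.0, "ENS": 1.0, "IRC": 0.9, "SRC": src},
                   bleach_rate)

    @classmethod
    def for_context(cls, context: str,
                    variant: str = "WT") -> "FluorescenceModel":
        if context.upper() == "TEC":
            return cls.tec_default()
        if context.upper() == "AEA":
            return cls.aea_default(variant)
        raise ValidationError(f"unknown sequence context {context!r}")

    def signal(self, traj: Trajectory, D_tot: float) -> np.ndarray:
        """Noise-free normalized fluorescence sum(c_s [s](t)) / D_tot."""
        sig = np.zeros_like(traj.times)
        for sp, c in self.coefficients.items():
            sig += c * traj[sp]
        sig /= D_tot
        if self.bleach_rate > 0:
            sig *= np.exp(-self.bleach_rate * traj.times)
        return sig


_MODES = ("single-mix", "double-mix", "titration", "single-turnover",
          "pulse-chase", "competition")


@dataclass(frozen=True)
class MixingExperiment:
    """Design of one stopped-flow or gel experiment."""

    mode: str
    E_tot: float
    D_tot: float
    times: np.ndarray = None
    age_time: float = 0.0
    competitor: float = 0.0
    dead_time: float = DEFAULT_DEAD_TIME
    noise_sd: float = DEFAULT_NOISE_SD
    seed: int = 0
    context: str = "TEC"
    experiment_id: str = ""

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValidationError(
                f"mode must be one of {_MODES}, got {self.mode!r}")
        for name in ("E_tot", "D_tot", "age_time", "competitor",
                     "dead_time", "noise_sd"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValidationError(f"{name} must be finite and >= 0, "
                                      f"got {v!r}")
        if self.times is not None:
            t = np.asarray(self.times, dtype=float)
            if t.ndim != 1 or np.any(np.diff(t) <= 0):
                raise ValidationError("times must be strictly increasing")
            object.__setattr__(self, "times", t)

    def replace(self, **kw) -> "MixingExperiment":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.times is not None:
            d["times"] = self.times.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MixingExperiment":
        d = dict(d)
        if d.get("times") is not None:
            d["times"] = np.asarray(d["times"], dtype=float)
        return cls(**d)


def default_time_grid(t_max: float = 3.0, n: int = 600,
                      t_min: float = 2e-4) -> np.ndarray:
    """Log-spaced acquisition grid, as stopped-flow software records."""
    return np.geomspace(t_min, t_max, n)


@dataclass
class Trace:
    """An observed (time, signal) record plus its experiment descriptor."""

    times: np.ndarray
    signal: np.ndarray
    experiment: MixingExperiment = None
    units: tuple = ("time_s", "signal")

    def __len__(self) -> int:
        return len(self.times)


def _finish_trace(times: np.ndarray, clean: np.ndarray,
                  exp: MixingExperiment) -> Trace:
    keep = times >= exp.dead_time
    if not keep.any():
        raise ValidationError(
            "no data points remain after dead-time truncation")
    times, clean = times[keep], clean[keep]
    if exp.noise_sd > 0:
        rng = np.random.default_rng(exp.seed)
        clean = clean + rng.normal(0.0, exp.noise_sd, size=clean.shape)
    return Trace(times=times, signal=clean, experiment=exp)


def synthesize_association_trace(spec: MechanismSpec, fl: FluorescenceModel,
                                 exp: MixingExperiment) -> Trace:
    """Single-mix association: enzyme is mixed with lesion DNA at t = 0."""
    if exp.mode != "single-mix":
        raise ValidationError("association traces require mode 'single-mix'")
    if exp.E_tot <= 0 or exp.D_tot <= 0:
        raise ValidationError("E_tot and D_tot must be > 0 for association")
    times = exp.times if exp.times is not None else default_time_grid()
    grid = times if times[0] == 0.0 else np.concatenate([[0.0], times])
    traj = simulate_timecourse(spec.with_chase(False),
                               SpeciesState.premix(exp.E_tot, exp.D_tot),
                               grid)
    sig = fl.signal(traj, exp.D_tot)
    if grid is not times:
        grid, sig = grid[1:], sig[1:]
    return _finish_trace(grid, sig, exp)


def synthesize_double_mixing_trace(spec: MechanismSpec,
                                   fl: FluorescenceModel,
                                   exp: MixingExperiment) -> Trace:
    """Double-mix chase: form the complex, age, then add excess inhibitor.

    Stage 1 runs the un-chased mechanism for ``age_time``; stage 2 continues
    from the aged state with the chase active and reports times measured
    from the second mix.  The fluorescence recovers toward the free-DNA
    level as the lesion unflips and is released.
    """
    if exp.mode != "double-mix":
        raise ValidationError("double-mixing traces require mode 'double-mix'")
    if exp.age_time <= 0:
        raise ValidationError("age_time must be > 0 for double mixing")
    stage1 = simulate_timecourse(spec.with_chase(False),
                                 SpeciesState.premix(exp.E_tot, exp.D_tot),
                                 np.array([0.0, exp.age_time]))
    aged = stage1.state_at(-1)
    times = exp.times if exp.times is not None else default_time_grid()
    grid = times if times[0] == 0.0 else np.concatenate([[0.0], times])
    traj = simulate_timecourse(spec.with_chase(True), aged, grid)
    sig = fl.signal(traj, exp.D_tot)
    if grid is not times:
        grid, sig = grid[1:], sig[1:]
    return _finish_trace(grid, sig, exp)


# ---------------------------------------------------------------------------
# Equilibrium titration
# ---------------------------------------------------------------------------

def tight_binding_fraction(E_tot, Kd: float, n: float,
                           D_tot: float) -> np.ndarray:
    """Fraction of DNA bound from the two-component binding quadratic.

    Solves [ED] for E_tot total enzyme, n*D_tot binding-site concentration
    and dissociation constant Kd:
        [ED] = ((E+S+Kd) - sqrt((E+S+Kd)^2 - 4 E S)) / 2,  S = n*D_tot,
    returned as [ED]/S.
    """
    if Kd < 0:
        raise ValidationError("Kd must be >= 0")
    if D_tot <= 0 or n <= 0:
        raise ValidationError("D_tot and n must be > 0")
    E = np.asarray(E_tot, dtype=float)
    S = n * D_tot
    b = E + S + Kd
    disc = np.maximum(b * b - 4.0 * E * S, 0.0)
    return (b - np.sqrt(disc)) / (2.0 * S)


def synthesize_titration(Kd: float, n: float, D_tot: float, enzyme_series,
                         quench_factor: float, noise_sd: float = 0.0,
                         seed: int = 0):
    """Equilibrium titration quench curve.

    The normalized signal interpolates from 1 (free DNA) to 1/quench_factor
    (fully bound) with the bound fraction from the tight-binding quadratic.
    Returns (E_tot array, normalized signal array).
    """
    if quench_factor < 1:
        raise ValidationError("quench_factor must be >= 1")
    E = np.asarray(enzyme_series, dtype=float)
    if np.any(E < 0):
        raise ValidationError("enzyme concentrations must be >= 0")
    fb = tight_binding_fraction(E, Kd, n, D_tot)
    sig = 1.0 - (1.0 - 1.0 / quench_factor) * fb
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        sig = sig + rng.normal(0.0, noise_sd, size=sig.shape)
    return E, sig


# ---------------------------------------------------------------------------
# Gel assays
# ---------------------------------------------------------------------------

def synthesize_single_turnover(k_obs: float, times, noise_sd: float = 0.0,
                               seed: int = 0):
    """Single-turnover excision time course: fraction = 1 - exp(-k t).

    ``k_obs`` in s^-1 and ``times`` in seconds (the reporting layer converts
    to per-minute units at the boundary).  Noisy values are clipped to
    [0, 1.05], matching gel quantification limits.
    """
    if not k_obs > 0:
        raise ValidationError("k_obs must be > 0")
    t = np.asarray(times, dtype=float)
    frac = 1.0 - np.exp(-k_obs * t)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        frac = np.clip(frac + rng.normal(0.0, noise_sd, size=frac.shape),
                       0.0, 1.05)
    return t, frac


def synthesize_competition_series(k_ref: float, ic50: float,
                                  competitor_series, noise_sd: float = 0.0,
                                  seed: int = 0):
    """Normalized excision rate versus competitor DNA concentration.

    rate/k_ref = 1 / (1 + [N]/IC50); IC50 = inf encodes no inhibition.
    """
    if not (ic50 > 0 or np.isinf(ic50)):
        raise ValidationError("ic50 must be > 0 (or inf for no inhibition)")
    N = np.asarray(competitor_series, dtype=float)
    if np.any(N < 0):
        raise ValidationError("competitor concentrations must be >= 0")
    if np.isinf(ic50):
        norm = np.ones_like(N)
    else:
        with np.errstate(divide="ignore"):
            norm = np.where(np.isinf(N), 0.0, 1.0 / (1.0 + N / ic50))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        norm = norm + rng.normal(0.0, noise_sd, size=norm.shape)
    return N, norm


# ---------------------------------------------------------------------------
# Trace I/O: CSV with a JSON sidecar holding the experiment descriptor
# ---------------------------------------------------------------------------

def write_trace(trace: Trace, path) -> None:
    path = Path(path)
    pd.DataFrame({trace.units[0]: trace.times,
                  trace.units[1]: trace.signal}).to_csv(path, index=False)
    if trace.experiment is not None:
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(trace.experiment.to_dict(), indent=1))


def read_trace(path) -> Trace:
    path = Path(path)
    df = pd.read_csv(path)
    tcol, scol = df.columns[0], df.columns[1]
    exp = None
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        exp = MixingExperiment.from_dict(json.loads(sidecar.read_text()))
    return Trace(times=df[tcol].to_numpy(), signal=df[scol].to_numpy(),
                 experiment=exp, units=(tcol, scol))
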