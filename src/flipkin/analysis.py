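"""From fitted observables to microscopic constants and the summary table.

The pipeline's final stage: subtract unflipping from the observed flipping
relaxation (k_flip = k_2,obs - k_unflip), form the flipping equilibrium
constant (K_flip = k_flip / k_unflip), turn pulse-chase partitioning into
commitments and unflipping rates, and compile everything into a per-variant
parameter table with provenance (measured / derived / limit) and the
rounding convention of the published comparisons (two significant figures,
half away from zero).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mechanism import (
    FlipKinError,
    UndefinedValueError,
    ValidationError,
    equilibrium_flip_constant,
    unflip_from_commitment,
)
from .phasefit import fit_single_turnover

__all__ = [
    "ConflictError",
    "Measurement",
    "ParameterTable",
    "derive_k_flip",
    "pulse_chase_commitment",
    "fold_change",
    "round_sig",
    "nucleotide_excess",
    "compile_parameter_table",
]


class ConflictError(FlipKinError, ValueError):
    """Duplicate measurements of one cell disagree beyond 3 SD."""


def derive_k_flip(k_2obs: float, k_unflip: float, sd_2obs: float = None,
                  sd_unflip: float = None):
    """Microscopic flipping rate: k_flip = k_2,obs - k_unflip.

    Uncertainties, when provided, propagate in quadrature; returns
    (k_flip, sd) in that case, otherwise the bare value.
    """
    if k_unflip < 0 or k_2obs < 0:
        raise ValidationError("rates must be >= 0")
    if k_2obs < k_unflip:
        raise ValidationError(
            f"inconsistent inputs: k_2,obs ({k_2obs:g}) < k_unflip "
            f"({k_unflip:g})")
    k_flip = k_2obs - k_unflip
    if sd_2obs is None and sd_unflip is None:
        return k_flip
    sd = math.hypot(sd_2obs or 0.0, sd_unflip or 0.0)
    return k_flip, sd


def pulse_chase_commitment(times, product_with_chase, product_without_chase,
                           baseline=None) -> float:
    """Commitment to catalysis from gel-quantified pulse-chase series.

    C = (plateau(chase) - plateau(baseline)) / plateau(no chase), clipped to
    [0, 1].  The baseline series is the control in which chase and
    substrate are added simultaneously (default plateau 0).  Raises if
    either series has not reached exponential saturation.
    """
    def plateau(y):
        fit = fit_single_turnover(times, y)
        if "plateau-not-reached" in fit["flags"]:
            raise ValidationError(
                "plateau not reached: series shows no exponential saturation")
        if "rate-unidentifiable" in fit["flags"]:
            return float(np.mean(y))
        return fit["endpoint"]

    p_chase = plateau(np.asarray(product_with_chase, dtype=float))
    p_nochase = plateau(np.asarray(product_without_chase, dtype=float))
    p_base = (plateau(np.asarray(baseline, dtype=float))
              if baseline is not None else 0.0)
    if p_nochase <= 0:
        raise ValidationError("no-chase control produced no product")
    return float(np.clip((p_chase - p_base) / p_nochase, 0.0, 1.0))


def round_sig(x: float, sig_figs: int) -> float:
    """Round to ``sig_figs`` significant figures, half away from zero."""
    if sig_figs < 1:
        raise ValidationError("sig_figs must be >= 1")
    if x == 0 or not math.isfinite(x):
        return x
    mag = math.floor(math.log10(abs(x)))
    unit = 10.0 ** (mag - sig_figs + 1)
    scaled = abs(x) / unit
    # nudge against binary representation error before the half-up floor
    rounded = math.floor(scaled + 0.5 + 1e-9) * unit
    return math.copysign(rounded, x)


def fold_change(numerator: float, denominator: float, sig_figs: int = 1):
    """Ratio of two constants, rounded as the printed fold comparisons are.

    Returns (rounded, raw).  Half-away-from-zero rounding at the requested
    number of significant figures.
    """
    if denominator <= 0:
        raise ValidationError("denominator must be > 0")
    raw = numerator / denominator
    return round_sig(raw, sig_figs), raw


def nucleotide_excess(competitor_conc: float, substrate_conc: float,
                      nt_per_competitor: float) -> float:
    """Fold excess of undamaged nucleotides over damaged substrate sites.

    One lesion per substrate duplex is assumed:
    (competitor concentration x undamaged nt per duplex) / substrate.
    """
    if substrate_conc <= 0:
        raise ValidationError("substrate_conc must be > 0")
    if competitor_conc < 0 or nt_per_competitor < 0:
        raise ValidationError("inputs must be >= 0")
    return competitor_conc * nt_per_competitor / substrate_conc


# ---------------------------------------------------------------------------
# Parameter table
# ---------------------------------------------------------------------------

#: rate at which the WT table-vs-pulse-chase unflipping estimates are close
#: enough not to flag (relative spread)
_SPREAD_TOL = 0.15

_KNOWN_PARAMS = ("k_on", "k_find", "k_2obs", "k_flip", "k_unflip", "K_flip",
                 "k_chem", "commitment", "IC50", "k_unflip_from_commitment")


@dataclass(frozen=True)
class Measurement:
    """One measured (or bounded) quantity feeding the parameter table."""

    variant: str
    name: str
    value: float
    context: str = "TEC"
    sd: float = None
    provenance: str = "measured"
    bound: str = None   # None | ">=" | "<="

    def __post_init__(self) -> None:
        if self.name not in _KNOWN_PARAMS:
            raise ValidationError(f"unknown parameter name {self.name!r}; "
                                  f"known: {_KNOWN_PARAMS}")
        if self.provenance not in ("measured", "derived", "limit"):
            raise ValidationError("provenance must be measured/derived/limit")
        if self.bound not in (None, ">=", "<="):
            raise ValidationError("bound must be None, '>=' or '<='")


@dataclass
class ParameterTable:
    """Compiled per-variant constants with provenance, plus derived cells."""

    cells: list = field(default_factory=list)  # of Measurement
    notes: list = field(default_factory=list)

    def get(self, variant: str, name: str, context: str = None):
        hits = [c for c in self.cells
                if c.variant == variant and c.name == name and
                (context is None or c.context == context)]
        return hits[0] if hits else None

    def value(self, variant: str, name: str, context: str = None):
        cell = self.get(variant, name, context)
        return None if cell is None else cell.value

    def as_frame(self, rounded: bool = False) -> pd.DataFrame:
        rows = []
        for c in self.cells:
            val = round_sig(c.value, 2) if rounded else c.value
            rows.append({"variant": c.variant, "context": c.context,
                         "parameter": c.name, "value": val, "sd": c.sd,
                         "provenance": c.provenance, "bound": c.bound or ""})
        return pd.DataFrame(rows)

    def to_csv(self, path, rounded: bool = True) -> None:
        self.as_frame(rounded=rounded).to_csv(path, index=False)

    def to_json(self, path=None) -> str:
        payload = {"cells": self.as_frame(rounded=False)
                   .to_dict(orient="records"),
                   "notes": self.notes}
        s = json.dumps(payload, indent=1, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    def to_markdown(self) -> str:
        """Human-readable report: parameters as rows, variants as columns."""
        df = self.as_frame(rounded=True)
        variants = sorted(df["variant"].unique())
        params = [p for p in _KNOWN_PARAMS if p in set(df["parameter"])]
        lines = ["| parameter | " + " | ".join(variants) + " |",
                 "|---" * (len(variants) + 1) + "|"]
        for p in params:
            row = [p]
            for v in variants:
                sub = df[(df["variant"] == v) & (df["parameter"] == p)]
                if sub.empty:
                    row.append("—")
                else:
                    r = sub.iloc[0]
                    row.append(f"{r['bound']}{r['value']:g}".strip())
            lines.append("| " + " | ".join(row) + " |")
        if self.notes:
            lines.append("")
            lines.extend(f"- {n}" for n in self.notes)
        return "\n".join(lines)


def _merge_duplicates(measurements):
    """Inverse-variance-average duplicate cells; conflicting cells error."""
    grouped = {}
    for m in measurements:
        grouped.setdefault((m.variant, m.context, m.name), []).append(m)
    merged, conflicts = [], []
    for key, group in grouped.items():
        if len(group) == 1:
            merged.append(group[0])
            continue
        vals = np.array([g.value for g in group])
        sds = np.array([g.sd if g.sd else np.nan for g in group])
        pooled_sd = (np.sqrt(np.nansum(sds ** 2)) if np.any(np.isfinite(sds))
                     else 0.05 * np.mean(np.abs(vals)))
        if np.ptp(vals) > 3 * max(pooled_sd, 1e-300):
            conflicts.append((key, vals.tolist()))
            continue
        if np.all(np.isfinite(sds)) and np.all(sds > 0):
            w = 1.0 / sds ** 2
            value = float(np.sum(w * vals) / np.sum(w))
            sd = float(1.0 / np.sqrt(np.sum(w)))
        else:
            value, sd = float(vals.mean()), group[0].sd
        merged.append(Measurement(variant=group[0].variant, name=key[2],
                                  value=value, context=group[0].context,
                                  sd=sd, provenance=group[0].provenance,
                                  bound=group[0].bound))
    if conflicts:
        raise ConflictError(
            "conflicting duplicate measurements (beyond 3 SD): "
            + "; ".join(f"{k} -> {v}" for k, v in conflicts))
    return merged


def compile_parameter_table(measurements) -> ParameterTable:
    """Populate measured cells and compute derived constants per variant.

    Derived cells: k_flip = k_2,obs - k_unflip; K_flip = k_flip / k_unflip;
    the pulse-chase-implied unflipping rate from commitment and k_chem.
    Limits (bound set) are carried through but never used in derivations.
    When both a directly fitted k_unflip and a pulse-chase-implied one are
    available and disagree by more than 15%, the spread is noted, and both
    values are reported.
    """
    table = ParameterTable(cells=_merge_duplicates(list(measurements)))
    by_vc = {}
    for c in table.cells:
        by_vc.setdefault((c.variant, c.context), {})[c.name] = c

    for (variant, context), cells in sorted(by_vc.items()):
        def usable(name):
            c = cells.get(name)
            return c if c is not None and c.bound is None else None

        k2 = usable("k_2obs")
        ku = usable("k_unflip")
        kc = usable("k_chem")
        comm = usable("commitment")

        if comm is not None and kc is not None and "k_unflip_from_commitment" \
                not in cells:
            try:
                ku_pc = unflip_from_commitment(kc.value, comm.value)
            except UndefinedValueError:
                ku_pc = None
                table.notes.append(
                    f"{variant}/{context}: zero commitment gives only a "
                    "lower limit on k_unflip")
            if ku_pc is not None:
                cell = Measurement(variant=variant, context=context,
                                   name="k_unflip_from_commitment",
                                   value=ku_pc, provenance="derived")
                table.cells.append(cell)
                cells["k_unflip_from_commitment"] = cell
                if ku is not None and abs(ku_pc / ku.value - 1) > _SPREAD_TOL:
                    table.notes.append(
                        f"{variant}/{context}: direct k_unflip "
                        f"({ku.value:.3g}) and pulse-chase-implied value "
                        f"({ku_pc:.3g}) differ by more than "
                        f"{_SPREAD_TOL:.0%}; both reported")

        if ku is None:
            ku = usable("k_unflip_from_commitment")

        if "k_flip" not in cells and k2 is not None and ku is not None:
            kf = derive_k_flip(k2.value, ku.value)
            cell = Measurement(variant=variant, context=context,
                               name="k_flip", value=kf, provenance="derived")
            table.cells.append(cell)
            cells["k_flip"] = cell

        kf = usable("k_flip")
        if "K_flip" not in cells and kf is not None and ku is not None \
                and ku.value > 0:
            cell = Measurement(variant=variant, context=context,
                               name="K_flip",
                               value=equilibrium_flip_constant(kf.value,
                                                               ku.value),
                               provenance="derived")
            table.cells.append(cell)
            cells["K_flip"] = cell

    return table
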