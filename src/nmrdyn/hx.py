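"""Millisecond-and-slower dynamics: hydrogen exchange in the EX2 limit.

Backbone amide protons exchange with solvent through transient opening:

    closed  <=[k_op / k_cl]=>  open  --k_int-->  exchanged

so the observed rate is

    k_obs = k_op * k_int / (k_cl + k_int),

which in the EX2 limit (k_cl >> k_int) reduces to k_obs = k_op k_int / k_cl.
The protection factor P = k_int / k_obs then reports the local
opening equilibrium, and logP = log10(P) is the standard per-residue
protection score.

Slowly exchanging amides are quantified from single-exponential decays of
HSQC peak intensities after dissolution in D2O; amides that exchange before
the first spectrum are measured by CLEANEX-type magnetisation-transfer
experiments analysed with the initial-slope approximation on short mixing
times.  Intrinsic (random-coil) rates k_int come from the poly-DL-alanine
reference formalism with nearest-neighbour side-chain corrections and
Arrhenius temperature scaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .constants import R_GAS_KCAL
from .relaxation import fit_monoexponential
from .types import (
    DecayCurve,
    InsufficientDataError,
    ResidueID,
    ValidationError,
)
from ._hxtables import (
    ACID_REF_LOG10,
    BASE_REF_LOG10,
    WATER_REF_LOG10,
    PKD,
    T_REF,
    EA_ACID,
    EA_BASE,
    EA_WATER,
    SIDE_CHAIN_LOG10,
    NTERM_LOG10,
    CTERM_LOG10,
)

__all__ = [
    "HXRecord",
    "EX2KineticModel",
    "simulate_kobs",
    "fit_hx_decay",
    "cleanex_initial_slope",
    "intrinsic_rates",
    "protection_factors",
]


@dataclass
class EX2KineticModel:
    """Opening/closing/intrinsic rates (s^-1) of the two-state exchange scheme."""

    k_op: float
    k_cl: float
    k_int: float

    def __post_init__(self) -> None:
        if not (self.k_op > 0 and self.k_cl > 0 and self.k_int > 0):
            raise ValidationError("all rates must be positive")


@dataclass
class HXRecord:
    """Per-residue observed/intrinsic exchange rates and protection factor."""

    residue: ResidueID
    k_obs: float  # s^-1
    k_int: float  # s^-1
    logP: float
    k_obs_err: float = 0.0
    logP_err: float = 0.0
    method: str = "decay-fit"  # or "cleanex"
    flags: str = ""

    def __post_init__(self) -> None:
        if not (self.k_obs > 0 and self.k_int > 0):
            raise ValidationError("k_obs and k_int must be positive")
        expected = np.log10(self.k_int / self.k_obs)
        if abs(self.logP - expected) > 1e-12 * max(1.0, abs(expected)):
            raise ValidationError(
                f"logP {self.logP} inconsistent with log10(k_int/k_obs) = {expected}"
            )


def simulate_kobs(model: EX2KineticModel) -> float:
    """Observed exchange rate k_obs = k_op k_int / (k_cl + k_int)."""
    return model.k_op * model.k_int / (model.k_cl + model.k_int)


def ex2_kobs(model: EX2KineticModel) -> float:
    """EX2-limit approximation k_obs = k_op k_int / k_cl (k_cl >> k_int)."""
    return model.k_op * model.k_int / model.k_cl


def fit_hx_decay(curve: DecayCurve) -> tuple[float, float, str]:
    """Single-exponential k_obs from an HX intensity decay.

    Returns (k_obs, error, flags).  Flags: ``poorly-constrained`` when the
    sampled time range covers less than half of 1/k_obs, ``increasing`` for
    rising intensities (best-effort fit), ``near-zero-rate`` for an
    essentially flat curve.
    """
    flags = []
    if curve.intensities[-1] > curve.intensities[0]:
        warnings.warn(
            f"residue {curve.residue.index}: intensities increase with time; "
            "best-effort fit flagged",
            stacklevel=2,
        )
        flags.append("increasing")
    rel_span = np.ptp(curve.intensities) / max(np.abs(curve.intensities).max(), 1e-300)
    if rel_span < 1e-3:
        warnings.warn(
            f"residue {curve.residue.index}: essentially flat decay; "
            "rate is near zero",
            stacklevel=2,
        )
        flags.append("near-zero-rate")
    res = fit_monoexponential(curve, require_positive=False)
    k = res.rate
    if k > 0 and curve.times[-1] * k < 0.5:
        warnings.warn(
            f"residue {curve.residue.index}: time grid covers only "
            f"{curve.times[-1] * k:.2f} of 1/k_obs; rate poorly constrained",
            stacklevel=2,
        )
        flags.append("poorly-constrained")
    return k, res.rate_err, ",".join(flags)


def cleanex_initial_slope(
    ratios: Sequence[tuple[float, float]],
    errors: Optional[Sequence[float]] = None,
    regime_limit: float = 0.050,
) -> tuple[float, float]:
    """Exchange rate from the initial slope of CLEANEX buildup ratios.

    ``ratios`` holds (mixing time in s, I/I0) pairs with mixing times in the
    short-time regime (canonical grid 0, 10, 15, 20, 25 ms).  A weighted
    linear fit through the origin gives slope = k (s^-1).  The initial-slope
    approximation underestimates k when k * tau_m is not small (buildup
    curvature); mixing times beyond ``regime_limit`` trigger a warning.
    """
    arr = np.asarray(ratios, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValidationError("ratios must be (tau_m, I/I0) pairs")
    tau = arr[:, 0]
    y = arr[:, 1]
    nonzero = tau > 0
    if nonzero.sum() < 2:
        raise InsufficientDataError(
            "initial-slope fit needs >= 2 nonzero mixing times"
        )
    if np.any(tau > regime_limit):
        warnings.warn(
            f"mixing times beyond {regime_limit * 1e3:.0f} ms violate the "
            "short-time regime; initial-slope estimate will be biased low",
            stacklevel=2,
        )
    w = np.ones(nonzero.sum())
    if errors is not None:
        e = np.asarray(errors, dtype=float)[nonzero]
        if np.all(e > 0):
            w = 1.0 / e**2
    t = tau[nonzero]
    v = y[nonzero]
    # weighted least squares through the origin: k = sum(w t y) / sum(w t^2)
    denom = np.sum(w * t**2)
    k = float(np.sum(w * t * v) / denom)
    resid = v - k * t
    dof = max(len(t) - 1, 1)
    k_err = float(np.sqrt(np.sum(w * resid**2) / dof / denom))
    return k, k_err


# ---------------------------------------------------------------------------
# Intrinsic rates
# ---------------------------------------------------------------------------

def _arrhenius(log_k_ref: float, ea_kcal: float, temperature_K: float) -> float:
    k_ref = 10.0**log_k_ref
    return k_ref * np.exp(-ea_kcal / R_GAS_KCAL * (1.0 / temperature_K - 1.0 / T_REF))


def intrinsic_rates(
    sequence: str,
    pD: float,
    temperature_K: float = 293.0,
    direction: str = "H-D",
) -> dict[int, float]:
    """Random-coil amide exchange rates k_int (s^-1) per residue.

    Poly-DL-alanine reference rates with acid-, base- and water-catalysed
    terms, nearest-neighbour side-chain corrections (the amide's own residue
    and its predecessor), N-/C-terminal corrections, and Arrhenius
    temperature scaling of each catalytic term.  ``pD`` is taken as the
    direct reading (no glass-electrode correction).  The first residue has no
    backbone amide proton and is not reported.

    Returns {residue index (1-based): k_int}.
    """
    sequence = sequence.upper()
    if len(sequence) < 2:
        raise ValidationError("need a sequence of length >= 2")
    for aa in sequence:
        if aa not in SIDE_CHAIN_LOG10:
            raise ValidationError(f"unknown residue code {aa!r}")
    if direction not in ("H-D", "H-H"):
        raise ValidationError("direction must be 'H-D' or 'H-H'")

    k_acid_ref = _arrhenius(ACID_REF_LOG10, EA_ACID, temperature_K)
    k_base_ref = _arrhenius(BASE_REF_LOG10, EA_BASE, temperature_K)
    k_water_ref = _arrhenius(WATER_REF_LOG10, EA_WATER, temperature_K)
    conc_D = 10.0 ** (-pD)
    conc_OD = 10.0 ** (pD - PKD)

    out: dict[int, float] = {}
    n = len(sequence)
    for i in range(1, n):  # 0-based position of the amide-bearing residue
        aa_r = sequence[i]  # residue whose amide exchanges
        aa_l = sequence[i - 1]  # preceding residue
        if aa_r == "P":
            continue  # proline has no amide proton
        acid = SIDE_CHAIN_LOG10[aa_r][0] + SIDE_CHAIN_LOG10[aa_l][1]
        base = SIDE_CHAIN_LOG10[aa_r][2] + SIDE_CHAIN_LOG10[aa_l][3]
        if i == 1:
            acid += NTERM_LOG10[0]
            base += NTERM_LOG10[1]
        if i == n - 1:
            acid += CTERM_LOG10[0]
            base += CTERM_LOG10[1]
        k_min = (
            k_acid_ref * 10.0**acid * conc_D
            + k_base_ref * 10.0**base * conc_OD
            + k_water_ref * 10.0**base
        )
        out[i + 1] = k_min / 60.0  # reference rates are per minute
    return out


def protection_factors(
    k_obs_records: Sequence[tuple[ResidueID, float, float, str]],
    k_int: dict[int, float],
) -> list[HXRecord]:
    """logP = log10(k_int / k_obs) for every residue with both rates.

    ``k_obs_records`` holds (residue, k_obs, k_obs_err, method).  A k_obs
    exceeding k_int gives logP < 0, which is unphysical under EX2; the value
    is kept but flagged.  logP errors propagate the k_obs fit error
    (d logP = k_err / (k ln 10)).
    """
    out: list[HXRecord] = []
    for rid, k_obs, k_err, method in k_obs_records:
        if rid.index not in k_int:
            continue
        ki = k_int[rid.index]
        if not k_obs > 0:
            warnings.warn(
                f"residue {rid.index}: nonpositive k_obs skipped", stacklevel=2
            )
            continue
        logp = float(np.log10(ki / k_obs))
        flags = ""
        if logp < 0:
            warnings.warn(
                f"residue {rid.index}: k_obs > k_int (logP = {logp:.2f}) is "
                "nonphysical under EX2",
                stacklevel=2,
            )
            flags = "nonphysical-under-EX2"
        logp_err = float(k_err / (k_obs * np.log(10.0))) if k_err > 0 else 0.0
        out.append(
            HXRecord(
                residue=rid,
                k_obs=float(k_obs),
                k_int=float(ki),
                logP=logp,
                k_obs_err=float(k_err),
                logP_err=logp_err,
                method=method,
                flags=flags,
            )
        )
    return out


def summarize_protection(records: Sequence[HXRecord]) -> tuple[float, float]:
    """(mean, SD) of logP over the supplied (structured-region) records."""
    if not records:
        raise InsufficientDataError("no protection factors to summarize")
    vals = np.array([r.logP for r in records])
    return float(vals.mean()), float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
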