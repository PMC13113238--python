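"""One-compartment cadmium biokinetics.

Whole-body cadmium burden [Cd] (μg Cd g⁻¹ dry wt) in *Daphnia* is modelled
with first-order uptake and elimination,

    d[Cd]/dt = k_u − k_e · [Cd],

with initial burden 0 (culture animals are below the detection limit).
During exposure the closed form is

    [Cd](t) = (k_u / k_e) · (1 − e^(−k_e t)),

with the limit k_u·t as k_e → 0.  During depuration (k_u = 0, starting from
the end-of-exposure burden Cd_A) the burden decays as Cd_A · e^(−k_e t).

The estimators invert this model from a single A-daphnid (end of exposure)
and E-daphnid (end of elimination) burden pair:

    k_e = ln(Cd_A / Cd_E) / Δt_elim
    k_u = k_e · Cd_A / (1 − e^(−k_e · Δt_exp))

Uptake rates are expressed per unit dry body weight (k_u*) for analysis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

# Below this |k_e| the uptake closed form switches to its k_e -> 0 limit.
KE_LIMIT_TOL = 1e-10


@dataclass(frozen=True)
class BiokineticParams:
    """First-order uptake/elimination constants.

    k_u is per individual (μg Cd individual⁻¹ day⁻¹); k_u_star is the
    dry-weight-normalized form (μg Cd g⁻¹ dry wt day⁻¹); k_e is day⁻¹.
    """

    k_u: float
    k_e: float
    k_u_star: float | None = None


def uptake_burden(k_u: float, k_e: float, t) -> np.ndarray | float:
    """Burden after time t of exposure, starting from zero burden."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("exposure time must be non-negative")
    if abs(k_e) < KE_LIMIT_TOL:
        out = k_u * t
    else:
        # -expm1 avoids cancellation in 1 - e^(-k_e t) for small k_e t
        out = (k_u / k_e) * (-np.expm1(-k_e * t))
    return float(out) if out.ndim == 0 else out


def elimination_burden(cd_a, k_e: float, t) -> np.ndarray | float:
    """Burden after time t of depuration, starting from burden cd_a."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("elimination time must be non-negative")
    out = np.asarray(cd_a, dtype=float) * np.exp(-k_e * t)
    return float(out) if out.ndim == 0 else out


def forward_concentration(
    params: BiokineticParams, t, phase: str = "uptake", cd_a: float | None = None
):
    """Evaluate the one-compartment model in either phase.

    phase='uptake' uses params.k_u (or k_u_star, giving a dry-weight
    normalized burden); phase='elimination' decays from cd_a.
    """
    if phase == "uptake":
        k_u = params.k_u_star if params.k_u_star is not None else params.k_u
        return uptake_burden(k_u, params.k_e, t)
    if phase == "elimination":
        if cd_a is None:
            raise ValueError("elimination phase requires cd_a")
        return elimination_burden(cd_a, params.k_e, t)
    raise ValueError(f"unknown phase {phase!r}")


def estimate_ke(cd_a: float, cd_e: float, t_elim: float) -> float:
    """Elimination rate constant from an A/E burden pair.

    Negative estimates (Cd_E > Cd_A, possible under measurement noise) are
    returned as-is with a warning rather than clipped.
    """
    if cd_a <= 0 or cd_e <= 0:
        raise ValueError("burdens must be positive")
    if t_elim <= 0:
        raise ValueError("elimination duration must be positive")
    # log1p form keeps precision when the burdens are nearly equal
    k_e = math.log1p((cd_a - cd_e) / cd_e) / t_elim
    if k_e < 0:
        warnings.warn(
            f"negative k_e estimate ({k_e:.4g} day^-1): E-burden exceeds A-burden",
            stacklevel=2,
        )
    return k_e


def estimate_ku(
    k_e: float, cd_a: float, t_exposure: float, dry_weight: float | None = None
) -> float:
    """Uptake rate constant from the end-of-exposure burden.

    With |k_e| below KE_LIMIT_TOL the k_e -> 0 limit Cd_A / t_exposure is
    used.  If dry_weight is given, cd_a is taken per individual and the
    dry-weight-normalized k_u* is returned.
    """
    if cd_a <= 0:
        raise ValueError("A-burden must be positive")
    if t_exposure <= 0:
        raise ValueError("exposure duration must be positive")
    if abs(k_e) < KE_LIMIT_TOL:
        k_u = cd_a / t_exposure
    else:
        k_u = k_e * cd_a / (-math.expm1(-k_e * t_exposure))
    if dry_weight is not None:
        if dry_weight <= 0:
            raise ValueError("dry weight must be positive")
        k_u = k_u / dry_weight
    return k_u


def estimate_params(records: pd.DataFrame) -> pd.DataFrame:
    """Per-beaker (k_e, k_u*) estimates from a burden record table.

    Expects columns isolate, clade, beaker, cd_a, cd_e, t_exposure, t_elim
    (dry_weight optional; burdens already per g dry wt if absent).
    Duplicate beaker estimates of k_e are additionally averaged per isolate
    and reported in column ke_isolate_mean.
    """
    required = {"isolate", "clade", "beaker", "cd_a", "cd_e", "t_exposure", "t_elim"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    rows = []
    for rec in records.itertuples(index=False):
        k_e = estimate_ke(rec.cd_a, rec.cd_e, rec.t_elim)
        k_u = estimate_ku(k_e, rec.cd_a, rec.t_exposure)
        rows.append(
            {
                "isolate": rec.isolate,
                "clade": rec.clade,
                "beaker": rec.beaker,
                "k_e": k_e,
                "k_u_star": k_u,
                "negative_ke": k_e < 0,
            }
        )
    out = pd.DataFrame(rows)
    out["ke_isolate_mean"] = out.groupby("isolate")["k_e"].transform("mean")
    return out


def summarize_clades(params: pd.DataFrame) -> pd.DataFrame:
    """Mean ± SD (and n) of k_u* and k_e per clade.

    Single-record clades report SD 0 with sd_defined=False rather than NaN.
    """
    if params.empty:
        raise ValueError("no records to summarize")
    rows = []
    for clade, grp in params.groupby("clade", sort=True):
        n = len(grp)
        for var in ("k_u_star", "k_e"):
            if var not in grp.columns:
                continue
            vals = grp[var].to_numpy(dtype=float)
            sd = float(np.std(vals, ddof=1)) if n > 1 else 0.0
            rows.append(
                {
                    "clade": clade,
                    "variable": var,
                    "mean": float(vals.mean()),
                    "sd": sd,
                    "n": n,
                    "sd_defined": n > 1,
                }
            )
    return pd.DataFrame(rows)
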