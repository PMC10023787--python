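"""Standard-curve qPCR quantification and control-normalized enrichment.

In the affinity-maturation (linker optimization) readout, each SL-B linker
code is quantified by qPCR with code-specific primers. Ct is linear in
log10 of starting template amount; a standard curve fitted on a dilution
series of known quantities converts Ct values to amounts, and per-code
enrichment is the amount in the target selection divided by the amount in
a declared control selection (typically the no-target / blank-support
selection).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError


@dataclass(frozen=True)
class StandardCurve:
    """Fitted line Ct = slope * log10(quantity) + intercept.

    ``slope`` must be negative (more template -> earlier threshold cycle).
    Amplification efficiency is ``10**(-1/slope) - 1``: a perfect doubling
    per cycle gives slope -1/log10(2) = -3.3219 and efficiency 1.0 (100%).
    """

    slope: float
    intercept: float
    r_squared: float = 1.0

    def __post_init__(self):
        if not np.isfinite(self.slope) or self.slope >= 0:
            raise ConfigError(f"standard-curve slope must be negative, got {self.slope}")
        if not -1e-9 <= self.r_squared <= 1 + 1e-9:
            raise ConfigError(f"r_squared must be in [0, 1], got {self.r_squared}")

    @property
    def efficiency(self) -> float:
        return float(10.0 ** (-1.0 / self.slope) - 1.0)


def fit_standard_curve(known_quantities, cts) -> StandardCurve:
    """Ordinary least squares of Ct on log10(quantity)."""
    q = np.asarray(known_quantities, dtype=float)
    ct = np.asarray(cts, dtype=float)
    if q.shape != ct.shape or q.ndim != 1:
        raise ConfigError("quantities and Ct values must be equal-length 1-d vectors")
    if np.any(q <= 0):
        raise ConfigError("standard quantities must be > 0")
    if len(np.unique(q)) < 2:
        raise ConfigError("standard curve needs >= 2 distinct quantities")
    res = stats.linregress(np.log10(q), ct)
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2) if np.isfinite(res.rvalue) else 1.0,
    )


def ct_to_amount(ct, curve: StandardCurve):
    """Invert the standard curve: amount = 10**((ct - intercept) / slope).

    Accepts scalars or arrays; every finite Ct maps to a positive amount.
    """
    ct_arr = np.asarray(ct, dtype=float)
    amount = 10.0 ** ((ct_arr - curve.intercept) / curve.slope)
    return float(amount) if np.isscalar(ct) or ct_arr.ndim == 0 else amount


def amounts_from_ct_table(
    ct_table: pd.DataFrame,
    curves: StandardCurve | Mapping[str, StandardCurve],
    calibrated_range: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Convert a (code_id, ct) table to amounts.

    ``curves`` is either one shared standard curve or a per-code mapping
    (code-specific primers can differ in efficiency); missing per-code
    entries fall back to the mapping's ``"__shared__"`` key if present.
    Amounts outside ``calibrated_range`` are flagged ``extrapolated``.
    """
    if "code_id" not in ct_table.columns or "ct" not in ct_table.columns:
        raise ConfigError("ct table must have columns code_id and ct")
    rows = []
    for row in ct_table.itertuples(index=False):
        if isinstance(curves, StandardCurve):
            curve = curves
        else:
            curve = curves.get(row.code_id) or curves.get("__shared__")
            if curve is None:
                raise ConfigError(f"no standard curve for code {row.code_id!r}")
        below = bool(getattr(row, "below_detection", False)) or not np.isfinite(row.ct)
        amount = np.nan if below else ct_to_amount(float(row.ct), curve)
        extrapolated = False
        if calibrated_range is not None and not below:
            lo, hi = calibrated_range
            extrapolated = not (lo <= amount <= hi)
        rows.append(
            {
                "code_id": row.code_id,
                "amount": amount,
                "below_detection": below,
                "extrapolated": extrapolated,
            }
        )
    return pd.DataFrame(rows, columns=["code_id", "amount", "below_detection", "extrapolated"])


def control_normalized_enrichment(
    target_amounts: Mapping[str, float],
    control_amounts: Mapping[str, float],
    floor: float,
) -> pd.DataFrame:
    """Per-code enrichment ratio target / max(control, floor).

    ``floor`` guards division by below-detection controls (recommended:
    0.1 x the smallest calibrated standard quantity); floored codes are
    flagged. Codes present in only one sample get a ``missing`` flag
    instead of a ratio.
    """
    if floor <= 0:
        raise ConfigError(f"floor must be > 0, got {floor}")
    codes = sorted(set(target_amounts) | set(control_amounts))
    rows = []
    for code in codes:
        t = target_amounts.get(code)
        c = control_amounts.get(code)
        missing = t is None or c is None or not np.isfinite(t) or not np.isfinite(c)
        if missing:
            rows.append(
                {
                    "code_id": code,
                    "target_amount": np.nan if t is None else t,
                    "control_amount": np.nan if c is None else c,
                    "ratio": np.nan,
                    "floored": False,
                    "missing": True,
                }
            )
            continue
        denom = max(c, floor)
        rows.append(
            {
                "code_id": code,
                "target_amount": float(t),
                "control_amount": float(c),
                "ratio": float(t) / denom,
                "floored": c < floor,
                "missing": False,
            }
        )
    return pd.DataFrame(
        rows, columns=["code_id", "target_amount", "control_amount", "ratio", "floored", "missing"]
    )
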