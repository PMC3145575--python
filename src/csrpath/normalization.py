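"""Hill-filter normalisation of raw assay values to [0, 1].

Raw bead-assay fluorescence is mapped to the unit interval per readout by
(i) gating changes smaller than the assay noise floor to zero, (ii) taking
the relative change over the basal (time-zero, unstimulated) level, and
(iii) passing it through a saturating Hill curve H(c) = c^n / (K^n + c^n).
Values at or above the declared assay saturation limit map to 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["NormalizationParams", "hill_normalize"]


@dataclass
class NormalizationParams:
    """Parameters of the Hill filter.

    noise_floor and saturation are in raw fluorescence units (the assay
    noise floor default follows repeated unstimulated controls at ~166
    units); hill_half_point K is on the relative-change scale, so K = 1
    puts the half-effect at a 100% increase over basal.
    """

    noise_floor: float = 166.0
    saturation: float = float("inf")
    hill_exponent: float = 2.0
    hill_half_point: float = 1.0
    two_sided: bool = False

    def __post_init__(self) -> None:
        if self.noise_floor < 0:
            raise ValueError("noise_floor must be >= 0")
        if self.saturation <= self.noise_floor:
            raise ValueError("saturation must exceed noise_floor")
        if self.hill_exponent <= 0 or self.hill_half_point <= 0:
            raise ValueError("hill parameters must be positive")


def hill_normalize(
    raw, basal, params: NormalizationParams = NormalizationParams()
):
    """Normalise a condition x readout matrix to [0, 1].

    ``raw`` is a DataFrame or 2-D array of non-negative raw values;
    ``basal`` gives the per-readout basal level (Series indexed by column,
    or 1-D array along columns).  Changes within the noise floor map to 0;
    by default only increases over basal count (the Boolean model has no
    below-basal state), unless ``params.two_sided``.
    """
    is_df = isinstance(raw, pd.DataFrame)
    values = np.asarray(raw, dtype=float)
    if is_df and isinstance(basal, pd.Series):
        b = basal.reindex(raw.columns).to_numpy(dtype=float)
    else:
        b = np.asarray(basal, dtype=float)
    b = np.broadcast_to(b, values.shape[-1:]).astype(float)
    if np.any(values[np.isfinite(values)] < 0):
        raise ValueError("raw values must be >= 0")
    if np.any(b < 0):
        raise ValueError("basal values must be >= 0")
    if np.isfinite(params.saturation) and np.any(params.saturation <= b):
        raise ValueError("saturation must exceed every basal level")

    delta = values - b[None, :]
    if params.two_sided:
        delta = np.abs(delta)
    # noise gate, then relative change over basal
    gated = np.maximum(0.0, delta - params.noise_floor)
    denom = np.where(b > 0, b, 1.0)  # basal 0: fall back to absolute change
    c = gated / denom
    n, k = params.hill_exponent, params.hill_half_point
    with np.errstate(over="ignore"):
        out = c**n / (k**n + c**n)
    out = np.where(np.abs(values - b[None, :]) <= params.noise_floor, 0.0, out)
    if np.isfinite(params.saturation):
        out = np.where(values >= params.saturation, 1.0, out)
    out = np.where(np.isnan(values), np.nan, np.clip(out, 0.0, 1.0))
    if is_df:
        return pd.DataFrame(out, index=raw.index, columns=raw.columns)
    return out
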