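"""Multiple linear regression of responses on measured signals.

Each response readout is regressed (no intercept) on all measured signal
readouts; the coefficient matrix W provides the stoichiometric yields of
the candidate non-canonical edges.  Low-magnitude coefficients are pruned
globally, retaining a fixed fraction of the largest |w|.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from .network import NonCanonicalEdge

__all__ = ["WeightMatrix", "fit_mlr", "prune_weights", "edge_id"]


@dataclass
class WeightMatrix:
    """Response x signal coefficient matrix W; entry (i, j) is the weight
    w_ij of the candidate edge signal_j -> response_i."""

    entries: np.ndarray
    response_names: list[str]
    signal_names: list[str]

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=float)
        if self.entries.shape != (len(self.response_names), len(self.signal_names)):
            raise ValueError("weight matrix shape does not match names")

    @property
    def n_entries(self) -> int:
        return self.entries.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.entries, index=self.response_names, columns=self.signal_names
        )


def _collinear_columns(x: np.ndarray, names: list[str]) -> list[str]:
    """Columns beyond the numerical rank, via pivoted QR."""
    r = np.linalg.matrix_rank(x)
    _, _, piv = scipy.linalg.qr(x, pivoting=True, mode="economic")
    return sorted(names[j] for j in piv[r:])


def fit_mlr(
    signals,
    responses,
    ridge: float | None = None,
) -> WeightMatrix:
    """Least-squares coefficients of every response on all signals.

    ``signals`` (k x n_sig) and ``responses`` (k x n_res) are DataFrames or
    arrays over the same k conditions.  No intercept is fitted: weights act
    as edge yields and basal response is handled by normalisation.  With
    fewer conditions than signals (or an exactly collinear design) a small
    ridge penalty is required; pass ``ridge`` explicitly or a ``ValueError``
    names the collinear columns.
    """
    sig_names = (
        list(signals.columns)
        if isinstance(signals, pd.DataFrame)
        else [f"s{j + 1}" for j in range(np.asarray(signals).shape[1])]
    )
    res_names = (
        list(responses.columns)
        if isinstance(responses, pd.DataFrame)
        else [f"y{j + 1}" for j in range(np.asarray(responses).shape[1])]
    )
    x = np.asarray(signals, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.shape[0] != y.shape[0]:
        raise ValueError("signals and responses must cover the same conditions")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values present; impute or drop conditions first")

    deficient = np.linalg.matrix_rank(x) < x.shape[1]
    if deficient and ridge is None:
        raise ValueError(
            "rank-deficient design (collinear or too few conditions); "
            f"dependent columns: {_collinear_columns(x, sig_names)}; "
            "pass ridge=<penalty> to regularise"
        )
    if ridge is not None:
        if deficient:
            warnings.warn(
                "rank-deficient design: falling back to ridge regression",
                stacklevel=2,
            )
        g = x.T @ x + float(ridge) * np.eye(x.shape[1])
        w = np.linalg.solve(g, x.T @ y).T
    else:
        w = np.linalg.lstsq(x, y, rcond=None)[0].T
    return WeightMatrix(entries=w, response_names=res_names, signal_names=sig_names)


def edge_id(source: str, target: str) -> str:
    return f"{source}->{target}"


def prune_weights(w: WeightMatrix, retain_fraction: float = 0.6) -> list[NonCanonicalEdge]:
    """Keep the ceil(retain_fraction * total) largest-|w| entries.

    Retention is global over the whole matrix.  Ties in |w| are broken by
    (response_name, signal_name) lexicographic order, so the result is
    deterministic.  Kept entries become NonCanonicalEdge records
    (source=signal, target=response).
    """
    if not (0 < retain_fraction <= 1):
        raise ValueError("retain_fraction must be in (0, 1]")
    items = [
        (abs(w.entries[i, j]), w.response_names[i], w.signal_names[j], w.entries[i, j])
        for i in range(len(w.response_names))
        for j in range(len(w.signal_names))
    ]
    items.sort(key=lambda t: (-t[0], t[1], t[2]))
    keep = math.ceil(retain_fraction * len(items))
    return [
        NonCanonicalEdge(id=edge_id(sig, res), source=sig, target=res, weight=val)
        for _, res, sig, val in items[:keep]
    ]
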