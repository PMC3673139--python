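"""Wavelet-energy features for activity windows.

Each axis of a window is decomposed to level ``i`` and summarised by

* the energy distribution ratios (EDRs): the fraction of the total
  coefficient energy  E_T = A_i A_i' + sum_j D_j D_j'  carried by the
  approximation vector and by each detail vector, and
* the normalized coefficient variances: the population variance of each of
  the i+1 coefficient vectors, rescaled to sum to one within the axis.

Both blocks are dimensionless and invariant to amplitude scaling of the
window, which makes them comparable across devices and subjects.  A
tri-axial window therefore yields 6(1+i) features at level i — e.g. 42
features at level 6.

The feature ordering is normative: for each axis in (x, y, z) the block is
[EDR_A, EDR_D1..EDR_Di, nvar_A, nvar_D1..nvar_Di].  Saved feature tables
use column names encoding axis and coefficient (``x_EDR_D3``, ``z_nvar_A``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .signals import ActivityWindow
from .wavelet import DWTCoefficients, WaveletSpec, dwt_decompose, get_wavelet

AXES = ("x", "y", "z")


@dataclass(frozen=True)
class FeatureVector:
    """One window's 6(1+i) features plus extraction metadata."""

    values: np.ndarray
    names: tuple[str, ...]
    wavelet: str
    level: int
    window_length: float
    source_rate: float
    label: str | None = None
    window_id: str = ""

    def __post_init__(self) -> None:
        if len(self.values) != 6 * (1 + self.level):
            raise ValueError(
                f"expected 6(1+{self.level}) = {6 * (1 + self.level)} "
                f"features, got {len(self.values)}"
            )

    def __len__(self) -> int:
        return len(self.values)


def total_energy(coeffs: DWTCoefficients) -> float:
    """Total coefficient energy E_T = A_i A_i' + sum_j D_j D_j'."""
    return float(sum(v @ v for v in coeffs.all_vectors()))


def energy_ratios(coeffs: DWTCoefficients) -> tuple[float, np.ndarray]:
    """Energy distribution ratios (EDR_A, [EDR_D1..EDR_Di]).

    The ratios sum to one by construction.  An all-zero window has no
    energy to distribute; by convention it is treated as pure
    approximation (EDR_A = 1, all EDR_Dj = 0) and a warning is issued.
    """
    e_t = total_energy(coeffs)
    if e_t == 0.0:
        warnings.warn(
            "zero-energy window: EDRs fall back to (1, 0, ..., 0)",
            RuntimeWarning,
            stacklevel=2,
        )
        return 1.0, np.zeros(coeffs.level)
    edr_a = float(coeffs.approximation @ coeffs.approximation) / e_t
    edr_d = np.array([float(d @ d) for d in coeffs.details]) / e_t
    return edr_a, edr_d


def coefficient_variances(coeffs: DWTCoefficients) -> np.ndarray:
    """Normalized population variances of [A_i, D_1, ..., D_i].

    The i+1 variances are rescaled to sum to one; if every vector is
    constant (all variances zero) the uniform distribution 1/(i+1) is
    returned so the block stays a valid composition.
    """
    raw = np.array([float(np.var(v)) for v in coeffs.all_vectors()])
    s = raw.sum()
    if s == 0.0:
        return np.full(len(raw), 1.0 / len(raw))
    return raw / s


def feature_names(level: int) -> tuple[str, ...]:
    """Normative feature-column names for a given level."""
    names: list[str] = []
    for axis in AXES:
        names.append(f"{axis}_EDR_A")
        names += [f"{axis}_EDR_D{j}" for j in range(1, level + 1)]
        names.append(f"{axis}_nvar_A")
        names += [f"{axis}_nvar_D{j}" for j in range(1, level + 1)]
    return tuple(names)


def extract_features(window: ActivityWindow, wavelet: WaveletSpec | str,
                     level: int) -> FeatureVector:
    """Decompose each axis independently and assemble the feature vector."""
    if isinstance(wavelet, str):
        wavelet = get_wavelet(wavelet)
    blocks: list[np.ndarray] = []
    with warnings.catch_warnings():
        # a stationary axis triggers the zero-energy fallback; that is
        # expected for label A1 and not worth one warning per axis
        warnings.simplefilter("ignore", RuntimeWarning)
        for axis in window.axes:
            coeffs = dwt_decompose(axis, wavelet, level)
            edr_a, edr_d = energy_ratios(coeffs)
            nvar = coefficient_variances(coeffs)
            blocks.append(np.concatenate(([edr_a], edr_d, nvar)))
    return FeatureVector(
        values=np.concatenate(blocks),
        names=feature_names(level),
        wavelet=wavelet.name,
        level=level,
        window_length=window.length,
        source_rate=window.source_rate,
        label=window.label,
        window_id=window.window_id,
    )


def feature_table(windows: Iterable[ActivityWindow],
                  wavelet: WaveletSpec | str, level: int) -> pd.DataFrame:
    """Extract features for many windows into one tidy DataFrame.

    Columns: window_id, label, wavelet, level, length, then the 6(1+i)
    named feature columns.
    """
    if isinstance(wavelet, str):
        wavelet = get_wavelet(wavelet)
    rows = []
    for win in windows:
        fv = extract_features(win, wavelet, level)
        row = {
            "window_id": fv.window_id,
            "label": fv.label,
            "wavelet": fv.wavelet,
            "level": fv.level,
            "length": fv.window_length,
        }
        row.update(zip(fv.names, fv.values))
        rows.append(row)
    return pd.DataFrame(rows)


FEATURE_META_COLUMNS = ("window_id", "label", "wavelet", "level", "length")


def split_feature_table(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Split a feature table into (X features, y labels) for model training."""
    feats = [c for c in table.columns if c not in FEATURE_META_COLUMNS]
    return table[feats].copy(), table["label"].copy()
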