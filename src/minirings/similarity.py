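"""The rS structure-similarity statistic and its transforms.

Two secondary structures are compared through the Pearson correlation of
their four feature percentages, paired by variable identity (stem with
stem, hairpin-loop with hairpin-loop, and so on — never permuted).  The
more positive rS, the more similar the structures.

Three transform conventions are provided for the downstream rank
correlations:

``identity``
    rH correlates the raw rS with the accretion ranks.  This is the
    pipeline default: it is the convention that reproduces the published
    per-organism rH extrema from the packaged tables (see the methods
    note), although the source prints a log formula.
``fisher``
    the conventional variance-stabilizing z = arctanh(r)
    = (1/2) ln((1+r)/(1-r)), strictly increasing in r.
``paper_literal``
    z = -ln((1+r)/(1-r)) = -2 arctanh(r) exactly as printed, strictly
    decreasing in r.  Because it is a negative scaling of ``fisher``,
    every downstream rank correlation computed under the two log modes
    differs exactly by sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure_features import FeatureVector

__all__ = ["SimilarityScore", "Z_MODES", "pairwise_rs", "rs_matrix", "z_transform"]

Z_MODES = ("identity", "fisher", "paper_literal")

_CLAMP = 1.0 - 1e-12


@dataclass(frozen=True)
class SimilarityScore:
    r_s: float
    z: float
    valid: bool
    mode: str

    def __bool__(self) -> bool:
        return self.valid


def _as_values(v: FeatureVector | tuple | list | np.ndarray) -> np.ndarray:
    if isinstance(v, FeatureVector):
        return np.asarray(v.values, dtype=float)
    arr = np.asarray(v, dtype=float)
    if arr.shape != (4,):
        raise ValueError("a feature vector has exactly 4 values")
    return arr


def pairwise_rs(
    f1: FeatureVector | tuple | list | np.ndarray,
    f2: FeatureVector | tuple | list | np.ndarray,
    mode: str = "identity",
) -> SimilarityScore:
    """4-point Pearson correlation between two feature vectors.

    Symmetric in its arguments.  A degenerate vector (zero variance across
    its four values, or any non-finite value) yields ``valid=False`` with
    NaN score, not an exception; such pairs are excluded downstream,
    reducing the rank-correlation sample size.
    """
    a, b = _as_values(f1), _as_values(f2)
    if (
        not np.all(np.isfinite(a))
        or not np.all(np.isfinite(b))
        or a.std() == 0.0
        or b.std() == 0.0
    ):
        return SimilarityScore(float("nan"), float("nan"), False, mode)
    am, bm = a - a.mean(), b - b.mean()
    r = float(am @ bm / np.sqrt((am @ am) * (bm @ bm)))
    r = max(-1.0, min(1.0, r))
    return SimilarityScore(r, z_transform(r, mode), True, mode)


def rs_matrix(ring_features: np.ndarray, subelement_features: np.ndarray) -> np.ndarray:
    """All pairwise rS values: rows of the first matrix against rows of the second.

    Inputs are ``(n, 4)`` arrays; rows with NaN or zero variance produce
    NaN rows/columns.  Returns an ``(n_rings, n_subelements)`` matrix.
    """
    A = np.asarray(ring_features, dtype=float)
    B = np.asarray(subelement_features, dtype=float)

    def standardize(M: np.ndarray) -> np.ndarray:
        Mc = M - np.nanmean(M, axis=1, keepdims=True)
        sd = np.sqrt(np.sum(Mc**2, axis=1, keepdims=True))
        with np.errstate(invalid="ignore", divide="ignore"):
            out = Mc / sd
        out[~np.isfinite(out)] = np.nan
        bad = ~np.all(np.isfinite(M), axis=1)
        out[bad] = np.nan
        return out

    R = standardize(A) @ standardize(B).T
    return np.clip(R, -1.0, 1.0)


def z_transform(r: float | np.ndarray, mode: str = "identity") -> float | np.ndarray:
    """Transform a correlation in [-1, 1] per the selected convention.

    r is clamped to +/-(1 - 1e-12) first so the log modes stay finite;
    z(0) = 0 in every mode.
    """
    if mode not in Z_MODES:
        raise ValueError(f"unknown z mode {mode!r}; choose from {Z_MODES}")
    arr = np.clip(np.asarray(r, dtype=float), -_CLAMP, _CLAMP)
    if mode == "identity":
        out = arr
    elif mode == "fisher":
        out = np.arctanh(arr)
    else:  # paper_literal
        out = -2.0 * np.arctanh(arr)
    return float(out) if np.isscalar(r) or np.asarray(r).ndim == 0 else out
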