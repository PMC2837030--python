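"""Compositional-complexity filtering of alignment columns.

A SEG-style two-threshold scheme operating on the *normalized weighted column
entropy* of a multiple alignment.  Column complexity is the Shannon entropy of
the weighted residue distribution of the column (gaps excluded, renormalized)
divided by log 20, so values lie in [0, 1]: 0 for a perfectly conserved
column, 1 for a column where all twenty residues are equally likely.

High-complexity stretches (near-uniform residue distributions, typically
misaligned or structurally unrelated regions) are masked by default before
profile construction; low-complexity stretches can optionally be masked as
well.  Trigger/extension thresholds follow SEG's two-level design: a window
whose mean complexity crosses the trigger threshold seeds a segment, which is
then extended while the windowed mean stays beyond the extension threshold.
Masked columns are excluded from profile positions but retain their
coordinates in the alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .alphabet import GAP_CODE, N_AA, ambiguity_split, robinson_background
from .msa import MultipleAlignment

__all__ = ["ComplexityParams", "column_complexity", "mask_complexity"]

_LOG20 = np.log(N_AA)


@dataclass(frozen=True)
class ComplexityParams:
    window: int = 12
    trigger_high: float = 0.9
    extension_high: float = 0.85
    trigger_low: float = 0.15
    extension_low: float = 0.2
    filter_high: bool = True
    filter_low: bool = False

    def __post_init__(self):
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if not (0.0 <= self.trigger_low <= self.extension_low
                <= self.extension_high <= self.trigger_high <= 1.0):
            raise ValueError(
                "thresholds must satisfy 0 <= trigger_low <= extension_low "
                "<= extension_high <= trigger_high <= 1")


def weighted_column_distributions(codes: np.ndarray,
                                  weights: np.ndarray) -> np.ndarray:
    """Per-column weighted residue distributions (length x 20).

    Gaps are excluded and columns renormalized; ambiguity codes are spread
    over their constituent residues.  All-gap columns yield a zero row.
    """
    n, m = codes.shape
    bg = robinson_background()
    dist = np.zeros((m, N_AA))
    for code in np.unique(codes):
        if code == GAP_CODE:
            continue
        mask = codes == code
        col_w = weights @ mask  # weight of this code per column
        dist += np.outer(col_w, ambiguity_split(int(code), bg))
    totals = dist.sum(axis=1, keepdims=True)
    nonzero = totals[:, 0] > 0
    dist[nonzero] /= totals[nonzero]
    return dist


def column_complexity(msa: MultipleAlignment,
                      weights: np.ndarray) -> np.ndarray:
    """Normalized weighted Shannon entropy per column, in [0, 1].

    ``weights`` are per-sequence weights summing to 1.  All-gap columns get
    complexity 0 (they are flagged and dropped at profile construction).
    """
    weights = np.asarray(weights, dtype=float)
    if not np.isclose(weights.sum(), 1.0, atol=1e-6):
        raise ValueError("weights must sum to 1")
    dist = weighted_column_distributions(msa.codes(), weights)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(dist > 0, dist * np.log(dist), 0.0)
    return -plogp.sum(axis=1) / _LOG20


def _windowed_mean(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average, truncated at the edges.

    A window larger than the sequence degenerates to the whole-sequence mean.
    """
    m = values.size
    if window >= m:
        return np.full(m, values.mean())
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(values)])
    lo = np.clip(np.arange(m) - half, 0, m)
    hi = np.clip(np.arange(m) + (window - half), 0, m)
    return (csum[hi] - csum[lo]) / (hi - lo)


def _seg_segments(wm: np.ndarray, trigger: float, extension: float,
                  above: bool) -> np.ndarray:
    """Boolean mask of columns in trigger/extension segments."""
    if above:
        seeds = wm > trigger
        extend = wm > extension
    else:
        seeds = wm < trigger
        extend = wm < extension
    out = np.zeros(wm.size, dtype=bool)
    for i in np.flatnonzero(seeds):
        if out[i]:
            continue
        lo = i
        while lo > 0 and extend[lo - 1]:
            lo -= 1
        hi = i
        while hi < wm.size - 1 and extend[hi + 1]:
            hi += 1
        out[lo:hi + 1] = True
    return out


def mask_complexity(msa: MultipleAlignment,
                    params: ComplexityParams = ComplexityParams(),
                    weights: np.ndarray | None = None) -> MultipleAlignment:
    """Return a copy of the alignment with low/high-complexity columns masked.

    The mask is recomputed from the raw columns, so the operation is
    idempotent.  With both filters off the mask is all-true.
    """
    if weights is None:
        from .profile import henikoff_weights
        weights = henikoff_weights(msa.codes())
    mask = np.ones(msa.length, dtype=bool)
    if params.filter_high or params.filter_low:
        comp = column_complexity(msa, weights)
        wm = _windowed_mean(comp, params.window)
        if params.filter_high:
            mask &= ~_seg_segments(wm, params.trigger_high,
                                   params.extension_high, above=True)
        if params.filter_low:
            mask &= ~_seg_segments(wm, params.trigger_low,
                                   params.extension_low, above=False)
    return replace(msa, column_mask=mask)
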