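"""Per-feature coverage extraction and exact length normalization.

Every feature vector is rescaled to a common length L by averaging the raw
depth over windows of size r = m / L (the normalization ratio).  Windows with
non-integer boundaries weight the boundary positions by their fractional
overlap, so the procedure is exact for any ratio and preserves both the
overall shape and the mean of the raw vector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from metaclust.alignment_io import CoverageTrack
from metaclust.annotation_io import GenomicFeature

logger = logging.getLogger(__name__)


class MatrixError(Exception):
    """Fatal matrix-stage failure (every feature skipped)."""


@dataclass
class FeatureMatrix:
    """n x L matrix of length-normalized coverage vectors with row ids."""

    ids: list[str]
    rows: np.ndarray
    L: int

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=float)
        if self.rows.ndim != 2 or self.rows.shape != (len(self.ids), self.L):
            raise ValueError(
                f"rows shape {self.rows.shape} inconsistent with "
                f"{len(self.ids)} ids and L={self.L}"
            )
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("feature ids must be unique")
        if not np.all(np.isfinite(self.rows)):
            raise ValueError("matrix contains non-finite values")

    @property
    def n(self) -> int:
        return len(self.ids)


def extract_raw(
    track: CoverageTrack,
    feature: GenomicFeature,
    *,
    reverse_minus: bool = True,
) -> np.ndarray:
    """Slice a feature's per-base depth from its chromosome array.

    The 1-based inclusive feature interval is converted to a 0-based
    half-open slice here, the single conversion point in the package.
    Minus-strand features are reversed (5' end first) unless disabled.
    """
    if feature.chrom not in track.depth:
        raise KeyError(f"chromosome {feature.chrom!r} absent from coverage track")
    arr = track.depth[feature.chrom]
    if feature.end > len(arr):
        raise IndexError(
            f"feature {feature.id!r} end {feature.end} exceeds "
            f"{feature.chrom} length {len(arr)}"
        )
    raw = np.asarray(arr[feature.start - 1 : feature.end], dtype=float)
    if reverse_minus and feature.strand == "-":
        raw = raw[::-1]
    return raw


def normalize_length(raw: np.ndarray, L: int) -> np.ndarray:
    """Rescale a length-m vector to L bins by fractional-overlap averaging.

    Output bin j is the mean of the step function `raw` over the real
    interval [j*r, (j+1)*r) with r = m/L.  Works for upsampling (r < 1),
    identity (r = 1) and downsampling (r > 1); mean(raw) is preserved
    exactly up to floating point.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 1 or raw.size == 0:
        raise ValueError("raw vector must be 1-D and non-empty")
    if L < 1:
        raise ValueError("L must be a positive integer")
    m = raw.size
    if L == m:
        return raw.copy()
    # Cumulative integral of the step function at arbitrary real x:
    # C(x) = cum[floor(x)] + frac(x) * raw[floor(x)]
    cum = np.concatenate(([0.0], np.cumsum(raw)))
    edges = np.linspace(0.0, float(m), L + 1)
    idx = np.minimum(edges.astype(int), m - 1)
    integral = cum[idx] + (edges - idx) * raw[idx]
    integral[-1] = cum[m]  # guard the right endpoint against rounding
    return np.diff(integral) / (m / L)


def build_matrix(
    track: CoverageTrack,
    features: list[GenomicFeature],
    L: int,
    control: CoverageTrack | None = None,
    *,
    reverse_minus: bool = True,
    scale_rows: bool = False,
    pseudocount: float = 1.0,
) -> FeatureMatrix:
    """Build the n x L matrix to be clustered, one row per retained feature.

    With a control track, each raw position becomes
    log2((treatment + pseudocount) / (control + pseudocount)) before
    normalization.  Features on missing chromosomes or outside chromosome
    bounds are skipped with a warning; all-skipped is fatal.
    Zero-coverage features are retained as zero rows.
    """
    if not features:
        raise MatrixError("no features supplied")
    ids: list[str] = []
    rows: list[np.ndarray] = []
    n_skipped = 0
    for feature in features:
        try:
            raw = extract_raw(track, feature, reverse_minus=reverse_minus)
            if control is not None:
                raw_ctrl = extract_raw(control, feature, reverse_minus=reverse_minus)
                raw = np.log2((raw + pseudocount) / (raw_ctrl + pseudocount))
        except (KeyError, IndexError) as exc:
            logger.warning("feature %r skipped: %s", feature.id, exc)
            n_skipped += 1
            continue
        ids.append(feature.id)
        rows.append(normalize_length(raw, L))
    if not ids:
        raise MatrixError(f"all {len(features)} features were skipped")
    if n_skipped:
        logger.info("skipped %d of %d features", n_skipped, len(features))
    matrix = np.vstack(rows)
    if scale_rows:
        means = matrix.mean(axis=1, keepdims=True)
        nonzero = means[:, 0] != 0
        matrix[nonzero] /= means[nonzero]
    return FeatureMatrix(ids=ids, rows=matrix, L=L)
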