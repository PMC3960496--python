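"""Wavelet-correlation functional connectivity.

The entry point is an ROI-by-frame signal matrix. The pipeline is:

1. regress nuisance signals (motion parameters, tissue signals, intercept)
   out of every node's time course;
2. decompose each residual series with the maximum-overlap discrete
   wavelet transform (MODWT) and keep the detail coefficients at scales
   2-4, which for TR = 2 s tile the 0.0156-0.125 Hz band carrying the
   block-design haemodynamic response;
3. average the three aligned detail series pointwise per node;
4. correlate averaged series between every node pair and take absolute
   values, giving a symmetric connectivity matrix with entries in [0, 1].

The MODWT is undecimated and defined for any series length; scale k
isolates the frequency octave [2^(-k-1)/TR, 2^(-k)/TR]. The pyramid is
implemented here with circular boundary handling on top of PyWavelets
filter banks (default ``sym4``, the Daubechies least-asymmetric length-8
filter customary in fMRI wavelet-correlation work).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

__all__ = [
    "RoiTimeSeriesMatrix",
    "ConnectivityMatrix",
    "regress_confounds",
    "scale_passband",
    "modwt_details",
    "wavelet_band_coefficients",
    "averaged_band_series",
    "build_connectivity",
]

DEFAULT_SCALES = (2, 3, 4)
DEFAULT_WAVELET = "sym4"


@dataclass
class RoiTimeSeriesMatrix:
    """Per-subject ROI signal matrix, nodes x frames."""

    node_ids: list[str]
    data: np.ndarray
    tr: float
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.node_ids = list(self.node_ids)
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (nodes x frames)")
        if self.data.shape[0] != len(self.node_ids):
            raise ValueError(
                f"{len(self.node_ids)} node ids but {self.data.shape[0]} rows"
            )
        if len(set(self.node_ids)) != len(self.node_ids):
            raise ValueError("node ids must be unique")
        if not np.isfinite(self.data).all():
            raise ValueError("time series contains non-finite values")
        if not self.tr > 0:
            raise ValueError("TR must be positive")

    @property
    def n_nodes(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]


@dataclass
class ConnectivityMatrix:
    """Symmetric matrix of absolute Pearson correlations, diagonal NaN."""

    node_ids: list[str]
    values: np.ndarray
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.node_ids = list(self.node_ids)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.node_ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape must match node count")
        off = ~np.eye(n, dtype=bool)
        finite = np.isfinite(self.values[off])
        if finite.any():
            vals = self.values[off][finite]
            if (vals < -1e-12).any() or (vals > 1 + 1e-12).any():
                raise ValueError("off-diagonal entries must lie in [0, 1]")
        if not np.allclose(
            np.nan_to_num(self.values), np.nan_to_num(self.values.T), atol=1e-12
        ):
            raise ValueError("matrix must be symmetric")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def pair_count(self) -> int:
        """Number of distinct node pairs, N(N-1)/2."""
        n = self.n_nodes
        return n * (n - 1) // 2

    def upper_values(self) -> np.ndarray:
        """Off-diagonal entries in upper-triangle order."""
        iu = np.triu_indices(self.n_nodes, k=1)
        return self.values[iu]

    def undefined_pairs(self) -> list[tuple[str, str]]:
        """Node pairs whose correlation is undefined (NaN)."""
        iu, ju = np.triu_indices(self.n_nodes, k=1)
        bad = np.isnan(self.values[iu, ju])
        return [
            (self.node_ids[i], self.node_ids[j])
            for i, j in zip(iu[bad], ju[bad])
        ]


def regress_confounds(
    ts: RoiTimeSeriesMatrix,
    confounds: np.ndarray | None = None,
    add_intercept: bool = True,
) -> RoiTimeSeriesMatrix:
    """Regress per-frame nuisance regressors out of every node series.

    Returns the least-squares residuals; they are orthogonal to each
    confound column. A rank-deficient design (collinear confounds) raises
    with the offending columns named.
    """
    frames = ts.n_frames
    if confounds is None:
        design = np.ones((frames, 1))
        labels = ["intercept"]
    else:
        confounds = np.atleast_2d(np.asarray(confounds, dtype=float))
        if confounds.shape[0] != frames:
            raise ValueError(
                f"confounds have {confounds.shape[0]} rows, expected {frames} frames"
            )
        labels = [f"confound_{i}" for i in range(confounds.shape[1])]
        if add_intercept:
            design = np.column_stack([np.ones(frames), confounds])
            labels = ["intercept"] + labels
        else:
            design = confounds
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify columns that do not increase rank when added greedily
        bad, r = [], 0
        for j in range(design.shape[1]):
            rj = np.linalg.matrix_rank(design[:, : j + 1])
            if rj == r:
                bad.append(labels[j])
            r = rj
        raise ValueError(f"confound design is rank deficient; collinear: {bad}")
    beta, *_ = np.linalg.lstsq(design, ts.data.T, rcond=None)
    resid = ts.data.T - design @ beta
    return RoiTimeSeriesMatrix(ts.node_ids, resid.T, ts.tr, ts.subject_id)


def scale_passband(k: int, tr: float) -> tuple[float, float]:
    """Frequency band (Hz) isolated by MODWT scale ``k`` at sampling interval TR.

    Scale k covers the dyadic octave [2^(-k-1)/TR, 2^(-k)/TR]; e.g. scale 3
    at TR = 2 s covers 0.03125-0.0625 Hz.
    """
    if k < 1:
        raise ValueError("scale index must be >= 1")
    if not tr > 0:
        raise ValueError("TR must be positive")
    return (2.0 ** (-k - 1) / tr, 2.0 ** (-k) / tr)


def min_frames_for_scale(k: int) -> int:
    """Minimum series length required for a meaningful scale-k detail series."""
    return 2 ** (k + 1)


def _modwt_filters(wavelet: str) -> tuple[np.ndarray, np.ndarray]:
    w = pywt.Wavelet(wavelet)
    # MODWT filters are the DWT bank rescaled by 1/sqrt(2)
    g = np.asarray(w.dec_lo, dtype=float) / np.sqrt(2.0)
    h = np.asarray(w.dec_hi, dtype=float) / np.sqrt(2.0)
    return g, h


def _phase_advance(level: int, filter_length: int) -> int:
    # circular advance aligning LA-family detail coefficients with time
    lj = (2**level - 1) * (filter_length - 1) + 1
    return lj // 2 - 1


def modwt_details(
    data: np.ndarray,
    max_level: int,
    wavelet: str = DEFAULT_WAVELET,
    align: bool = True,
) -> dict[int, np.ndarray]:
    """MODWT detail coefficient series for levels 1..max_level.

    ``data`` may be 1-D (one series) or 2-D (series in rows); coefficients
    keep the input length (undecimated transform, periodic boundary).
    With ``align=True`` each level is circularly advanced so coefficients
    line up with the events that produced them, which makes pointwise
    averaging across levels meaningful.
    """
    x = np.atleast_2d(np.asarray(data, dtype=float))
    n = x.shape[1]
    if n < min_frames_for_scale(max_level):
        raise ValueError(
            f"series of length {n} too short for scale {max_level}; "
            f"need at least {min_frames_for_scale(max_level)} frames"
        )
    g, h = _modwt_filters(wavelet)
    taps = len(g)
    v = x
    details: dict[int, np.ndarray] = {}
    idx_base = np.arange(n)
    for level in range(1, max_level + 1):
        step = 2 ** (level - 1)
        w_level = np.zeros_like(v)
        v_next = np.zeros_like(v)
        for tap in range(taps):
            shifted = v[:, (idx_base - step * tap) % n]
            w_level += h[tap] * shifted
            v_next += g[tap] * shifted
        if align:
            w_level = np.roll(w_level, -_phase_advance(level, taps), axis=1)
        details[level] = w_level
        v = v_next
    if np.asarray(data).ndim == 1:
        return {k: w[0] for k, w in details.items()}
    return details


def wavelet_band_coefficients(
    series: np.ndarray,
    scales: tuple[int, ...] = DEFAULT_SCALES,
    wavelet: str = DEFAULT_WAVELET,
    align: bool = True,
) -> dict[int, np.ndarray]:
    """Detail coefficient series at the requested scales (same length as input)."""
    scales = tuple(sorted(set(int(s) for s in scales)))
    if min(scales) < 1:
        raise ValueError("scales must be >= 1")
    details = modwt_details(series, max(scales), wavelet=wavelet, align=align)
    return {k: details[k] for k in scales}


def averaged_band_series(
    data: np.ndarray,
    scales: tuple[int, ...] = DEFAULT_SCALES,
    wavelet: str = DEFAULT_WAVELET,
) -> np.ndarray:
    """Pointwise mean of the detail series across the requested scales."""
    bands = wavelet_band_coefficients(data, scales, wavelet=wavelet)
    return np.mean([bands[k] for k in sorted(bands)], axis=0)


def build_connectivity(
    ts: RoiTimeSeriesMatrix,
    scales: tuple[int, ...] = DEFAULT_SCALES,
    wavelet: str = DEFAULT_WAVELET,
) -> ConnectivityMatrix:
    """Absolute-correlation connectivity matrix from averaged wavelet details.

    Each node's scale-averaged detail series is correlated with every
    other node's; entries are |Pearson r|. A node whose averaged series
    has zero variance yields NaN (undefined) in its row/column, reported
    via :meth:`ConnectivityMatrix.undefined_pairs`.
    """
    avg = averaged_band_series(ts.data, scales, wavelet=wavelet)
    sd = avg.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(avg)
    corr[sd == 0, :] = np.nan
    corr[:, sd == 0] = np.nan
    vals = np.abs(corr)
    vals = np.clip(vals, 0.0, 1.0)
    np.fill_diagonal(vals, np.nan)
    vals = (vals + vals.T) / 2.0  # enforce exact symmetry against rounding
    return ConnectivityMatrix(ts.node_ids, vals, ts.subject_id)
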