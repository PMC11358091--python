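"""Functional connectivity: band-averaged coherence and histogram mutual information.

Magnitude-squared coherence is computed from Welch-averaged auto- and
cross-spectra, ``COH(f) = |S_xy(f)|^2 / (S_xx(f) S_yy(f))``, and reduced
to one scalar per pair as the arithmetic mean of COH(f) over the
analysis band. Mutual information is the histogram plug-in estimate
``I(X,Y) = H(X) + H(Y) - H(X,Y)`` in bits over equal-width amplitude
bins, clipped at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .layout import ElectrodeLayout, REGIONS, assign_regions
from .recording import Recording


@dataclass(frozen=True)
class SpectralParams:
    segment_length: int = 256  # samples (1 s at 256 Hz)
    overlap_fraction: float = 0.5
    window: str = "hann"
    band: tuple[float, float] = (55.0, 95.0)

    def __post_init__(self):
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ValueError("overlap_fraction must lie in [0, 1)")

    @property
    def noverlap(self) -> int:
        return int(self.segment_length * self.overlap_fraction)


@dataclass
class ConnectivityMatrix:
    values: np.ndarray  # channels x channels
    metric: str  # "coherence" | "mi"
    channel_labels: list[str]
    symmetric: bool = True
    band: tuple[float, float] | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.channel_labels),) * 2:
            raise ValueError("matrix shape must match channel count")

    def off_diagonal_mean(self) -> float:
        n = self.values.shape[0]
        mask = ~np.eye(n, dtype=bool)
        return float(self.values[mask].mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.channel_labels,
                            columns=self.channel_labels)


@dataclass
class RegionSummary:
    """Mean connectivity within each region and between each region pair."""

    within: dict  # region -> mean (NaN when a region has < 2 channels)
    between: dict  # "F-P" style key -> mean
    metric: str = ""


def coherence_pair(x, y, params: SpectralParams = SpectralParams(),
                   fs: float = 256.0) -> float:
    """Band-mean magnitude-squared coherence between two equal-length series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if len(x) < 2 * params.segment_length:
        raise ValueError(
            "series shorter than two Welch segments; coherence would degenerate"
        )
    f, coh = signal.coherence(
        x, y, fs=fs, window=params.window,
        nperseg=params.segment_length, noverlap=params.noverlap,
    )
    return float(np.mean(coh[_band_mask(f, params.band)]))


def _band_mask(f: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    mask = (f >= band[0]) & (f <= band[1])
    if not mask.any():
        raise ValueError(f"no spectral bins inside band {band}")
    return mask


def _hist_entropy_bits(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def mutual_information_pair(x, y, n_bins: int = 16) -> float:
    """Histogram mutual information in bits, clipped at zero.

    Equal-width bins over each margin's observed range; a constant
    margin has zero entropy, hence MI = 0.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.min() == x.max() or y.min() == y.max():
        return 0.0
    joint, _, _ = np.histogram2d(x, y, bins=n_bins)
    hx = _hist_entropy_bits(joint.sum(axis=1))
    hy = _hist_entropy_bits(joint.sum(axis=0))
    hxy = _hist_entropy_bits(joint.ravel())
    return max(0.0, hx + hy - hxy)


def _coherence_matrix(samples: np.ndarray, fs: float,
                      params: SpectralParams) -> np.ndarray:
    """All-pairs band-mean coherence from one cross-spectral computation."""
    f, sxy = signal.csd(
        samples[:, None, :], samples[None, :, :], fs=fs,
        window=params.window, nperseg=params.segment_length,
        noverlap=params.noverlap,
    )
    sxx = np.real(np.einsum("iif->if", sxy))
    coh = np.abs(sxy) ** 2 / (sxx[:, None, :] * sxx[None, :, :])
    values = coh[:, :, _band_mask(f, params.band)].mean(axis=2)
    np.fill_diagonal(values, 1.0)
    return values


def adjacency_matrix(
    rec: Recording,
    metric: str,
    spectral: SpectralParams = SpectralParams(),
    n_bins: int = 16,
) -> ConnectivityMatrix:
    """Channel x channel symmetric connectivity matrix for one epoch.

    The coherence diagonal is 1; the MI diagonal holds each channel's
    self-information (excluded from all region summaries).
    """
    if metric == "coherence":
        values = _coherence_matrix(rec.samples, rec.fs, spectral)
        band = spectral.band
    elif metric == "mi":
        n = rec.n_channels
        values = np.zeros((n, n))
        for i in range(n):
            for j in range(i, n):
                values[i, j] = values[j, i] = mutual_information_pair(
                    rec.samples[i], rec.samples[j], n_bins
                )
        band = None
    else:
        raise ValueError(f"unknown metric {metric!r}; expected 'coherence' or 'mi'")
    return ConnectivityMatrix(
        values=values, metric=metric,
        channel_labels=list(rec.channel_labels), band=band,
    )


def region_summary(matrix: ConnectivityMatrix, layout: ElectrodeLayout) -> RegionSummary:
    """Within-region and between-region means over unique channel pairs.

    With the default 4/4/2 layout: within F and P average 6 pairs each,
    within O averages 1; between-region means cover 16 (F-P), 8 (F-O)
    and 8 (P-O) pairs. The diagonal is never included. A region with
    fewer than 2 channels gets a NaN "within" entry.
    """
    regions = assign_regions(layout, matrix.channel_labels)
    idx = {r: [i for i, lab in enumerate(matrix.channel_labels) if regions[lab] == r]
           for r in REGIONS}
    v = matrix.values
    within = {}
    for r in REGIONS:
        chans = idx[r]
        if len(chans) < 2:
            within[r] = float("nan")
            continue
        vals = [v[a, b] for k, a in enumerate(chans) for b in chans[k + 1:]]
        within[r] = float(np.mean(vals))
    between = {}
    for a_r, b_r in (("F", "P"), ("F", "O"), ("P", "O")):
        vals = [v[a, b] for a in idx[a_r] for b in idx[b_r]]
        between[f"{a_r}-{b_r}"] = float(np.mean(vals)) if vals else float("nan")
    return RegionSummary(within=within, between=between, metric=matrix.metric)
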