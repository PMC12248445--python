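"""Spectrum preprocessing: TIC normalization, peak alignment, intensity filter.

The chain runs in the order normalize -> align -> filter.  Alignment groups
the pooled, sorted peaks of all pixels into features by greedy ppm-window
clustering: a new feature opens whenever the next peak lies more than
``tolerance_ppm`` above the running intensity-weighted centroid of the open
feature.  Each pixel contributes at most one peak per feature (the most
intense; ties broken toward lower m/z).

The low-intensity filter follows the 0.5%-of-strongest-peak rule applied to
the dataset mean spectrum: per-pixel filtering would delete genuine
low-abundance species from individual pixels and break class-percentage
comparability across pixels.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import sparse

from .msi_io import Datacube, FeatureMatrix, PixelSpectrum

logger = logging.getLogger("lipidmsi")

__all__ = ["tic_normalize", "align_peaks", "filter_low_intensity", "run_preprocessing"]


def tic_normalize(cube: Datacube) -> Datacube:
    """Divide each spectrum by its total ion current, then rescale by the mean
    TIC so the global intensity scale is preserved.

    Pixels with zero TIC are dropped with a logged warning; afterwards every
    retained pixel has the same intensity sum.
    """
    tics = np.array([s.tic for s in cube.spectra])
    keep = tics > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("tic_normalize: dropped %d zero-TIC pixel(s)", n_dropped)
    kept = [s for s, k in zip(cube.spectra, keep) if k]
    if not kept:
        raise ValueError("all pixels have zero TIC")
    mean_tic = float(tics[keep].mean())
    spectra = [
        PixelSpectrum(s.mz.copy(), s.intensity * (mean_tic / s.tic), s.coord)
        for s in kept
    ]
    out = Datacube(spectra, cube.grid_shape, cube.pixel_size, cube.mode_polarity)
    return out


def align_peaks(cube: Datacube, tolerance_ppm: float = 5.0) -> FeatureMatrix:
    """Cluster peaks across pixels into aligned features.

    Greedy 1-D clustering on the pooled sorted m/z values: the running feature
    centroid is the intensity-weighted mean of the member peaks, and a peak
    further than ``tolerance_ppm`` from it opens a new feature.
    """
    if tolerance_ppm <= 0:
        raise ValueError("tolerance_ppm must be positive")
    if cube.n_pixels == 0:
        raise ValueError("empty datacube")
    pix_of = []
    mz_all = []
    int_all = []
    for i, s in enumerate(cube.spectra):
        pix_of.append(np.full(s.mz.size, i))
        mz_all.append(s.mz)
        int_all.append(s.intensity)
    pix = np.concatenate(pix_of)
    mz = np.concatenate(mz_all)
    inten = np.concatenate(int_all)
    order = np.argsort(mz, kind="stable")
    pix, mz, inten = pix[order], mz[order], inten[order]

    # greedy pass over plain Python floats (numpy scalar arithmetic is slow)
    feature_id = np.empty(mz.size, dtype=np.int64)
    mz_l = mz.tolist()
    int_l = inten.tolist()
    centroid = wsum = msum = 0.0
    current = -1
    tol = tolerance_ppm * 1e-6
    for j in range(len(mz_l)):
        m = mz_l[j]
        w = int_l[j]
        if current < 0 or (m - centroid) > tol * centroid:
            current += 1
            wsum, msum = w, w * m
            centroid = m
        else:
            wsum += w
            msum += w * m
            if wsum > 0:
                centroid = msum / wsum
        feature_id[j] = current
    n_features = current + 1

    # one peak per (pixel, feature): most intense wins, ties -> lower m/z.
    # Stable-sort by (feature, pixel, -intensity, mz) and keep first of each run.
    sort_idx = np.lexsort((mz, -inten, pix, feature_id))
    f_s, p_s = feature_id[sort_idx], pix[sort_idx]
    first = np.ones(sort_idx.size, dtype=bool)
    first[1:] = (np.diff(f_s) != 0) | (np.diff(p_s) != 0)
    winners = sort_idx[first]

    # sparse until the low-intensity filter prunes the (many) noise features
    values = sparse.csr_matrix(
        (inten[winners], (pix[winners], feature_id[winners])),
        shape=(cube.n_pixels, n_features),
    )

    # recompute final centroids over winning members only
    final_mz = np.zeros(n_features)
    weights = np.zeros(n_features)
    np.add.at(final_mz, feature_id[winners], inten[winners] * mz[winners])
    np.add.at(weights, feature_id[winners], inten[winners])
    zero = weights == 0
    for f in np.flatnonzero(zero):  # all-zero-intensity feature: unweighted mean
        final_mz[f] = mz[feature_id == f].mean()
        weights[f] = 1.0
    final_mz = final_mz / weights

    order_f = np.argsort(final_mz, kind="stable")
    matrix = FeatureMatrix(
        mz_axis=final_mz[order_f],
        values=values[:, order_f],
        pixel_index=[s.coord for s in cube.spectra],
        grid_shape=cube.grid_shape,
        normalized=False,
        metadata={"tolerance_ppm": tolerance_ppm},
    )
    logger.info("align_peaks: %d peaks -> %d features", mz.size, n_features)
    return matrix


def filter_low_intensity(matrix: FeatureMatrix, threshold_fraction: float = 0.005
                         ) -> FeatureMatrix:
    """Drop features whose dataset-mean intensity falls below
    ``threshold_fraction`` of the strongest mean-spectrum peak."""
    if matrix.n_features == 0 or matrix.n_pixels == 0:
        raise ValueError("empty feature matrix")
    mean_spec = np.asarray(matrix.values.mean(axis=0)).ravel()
    threshold = threshold_fraction * mean_spec.max()
    keep = mean_spec >= threshold
    dropped = int((~keep).sum())
    logger.info("filter_low_intensity: retained %d, dropped %d features",
                int(keep.sum()), dropped)
    values = matrix.values[:, keep]
    if sparse.issparse(values) and values.shape[0] * values.shape[1] < 5_000_000:
        values = np.asarray(values.todense(), dtype=np.float64)
    out = FeatureMatrix(
        mz_axis=matrix.mz_axis[keep],
        values=values,
        pixel_index=list(matrix.pixel_index),
        grid_shape=matrix.grid_shape,
        normalized=matrix.normalized,
        metadata={**matrix.metadata,
                  "filter_threshold_fraction": threshold_fraction,
                  "filter_scope": "dataset_mean_spectrum",
                  "n_dropped": dropped},
    )
    return out


def run_preprocessing(cube: Datacube, tolerance_ppm: float = 5.0,
                      threshold_fraction: float = 0.005) -> FeatureMatrix:
    """normalize -> align -> filter, the full preprocessing chain."""
    normalized = tic_normalize(cube)
    matrix = align_peaks(normalized, tolerance_ppm)
    matrix.normalized = True
    return filter_low_intensity(matrix, threshold_fraction)
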