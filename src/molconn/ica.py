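"""Spatial group ICA of 4D series and component-level quantification.

Subjects' in-mask voxel time series (restricted to an analysis window) are
voxelwise standardized and concatenated along time; a fixed-point
(FastICA, symmetric/parallel, logcosh contrast) decomposition with
PCA whitening then yields spatial components that are statistically
independent across voxels. Maps are z-scored over in-mask voxels and
sign-aligned to positive skewness, and can be thresholded at |z| >= 1.96
(two-sided p <= 0.05) for display, summarized per atlas region, and
correlated against regional drug-effect t-scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .atlas import Atlas
from .kinetics import DynamicImage

__all__ = ["ComponentMaps", "group_spatial_ica", "regional_component_scores",
           "component_effect_correlation", "match_components"]

DEFAULT_THRESHOLD_Z = 1.96


@dataclass
class ComponentMaps:
    """z-scored spatial independent components over an in-mask voxel set."""

    maps: np.ndarray            # n_components x n_mask_voxels, z-scored
    mask: np.ndarray            # 3D boolean
    threshold_z: float = DEFAULT_THRESHOLD_Z
    modality: str = "PET"
    seed: int | None = None
    n_iter: int | None = None

    @property
    def n_components(self) -> int:
        return self.maps.shape[0]

    def map_volume(self, k: int, thresholded: bool = False) -> np.ndarray:
        """Component k as a 3D volume (zeros outside the mask)."""
        vol = np.zeros(self.mask.shape)
        m = self.maps[k]
        if thresholded:
            m = np.where(np.abs(m) >= self.threshold_z, m, 0.0)
        vol[self.mask] = m
        return vol

    def thresholded(self, k: int) -> np.ndarray:
        """In-mask weights of component k with sub-threshold voxels zeroed."""
        m = self.maps[k]
        return np.where(np.abs(m) >= self.threshold_z, m, 0.0)

    def stack_volume(self) -> np.ndarray:
        """All components as a 4D array (component axis last)."""
        return np.stack([self.map_volume(k) for k in range(self.n_components)], axis=-1)


def _windowed_voxel_matrix(img: DynamicImage, mask: np.ndarray,
                           window_min: tuple[float, float]) -> np.ndarray:
    mid = img.frame_mid_min
    keep = (mid >= window_min[0]) & (mid < window_min[1])
    if keep.sum() < 2:
        raise ValueError(f"fewer than 2 frames in analysis window {window_min}")
    x = img.data[mask][:, keep]  # voxels x frames
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def group_spatial_ica(images: list[DynamicImage], mask: np.ndarray,
                      n_components: int, seed: int | None = None,
                      analysis_window_min: tuple[float, float] = (30.0, 80.0),
                      threshold_z: float = DEFAULT_THRESHOLD_Z,
                      tol: float = 1e-6, max_iter: int = 1000) -> ComponentMaps:
    """Group spatial ICA over temporally concatenated, standardized subjects.

    Dimensionality is reduced to ``n_components`` principal components
    before the fixed-point iteration; the result is deterministic for a
    given (inputs, seed, n_components).
    """
    if len(images) < 1:
        raise ValueError("need at least one image")
    mask = np.asarray(mask, dtype=bool)
    blocks = []
    for img in images:
        if img.data.shape[:3] != mask.shape:
            raise ValueError("image grid does not match mask")
        blocks.append(_windowed_voxel_matrix(img, mask, analysis_window_min))
    X = np.concatenate(blocks, axis=1)  # voxels x total time
    if n_components >= X.shape[1]:
        raise ValueError("n_components must be below total concatenated time points")

    ica = FastICA(n_components=n_components, algorithm="parallel", fun="logcosh",
                  whiten="unit-variance", tol=tol, max_iter=max_iter,
                  random_state=np.random.RandomState(seed))
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            sources = ica.fit_transform(X)  # voxels x components (spatial maps)
        except ConvergenceWarning:
            raise RuntimeError(
                f"spatial ICA did not converge within {max_iter} iterations "
                f"at tolerance {tol}") from None

    maps = sources.T  # components x voxels
    mu = maps.mean(axis=1, keepdims=True)
    sd = maps.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    maps = (maps - mu) / sd
    skew = stats.skew(maps, axis=1)
    maps[skew < 0] *= -1.0
    return ComponentMaps(maps=maps, mask=mask, threshold_z=threshold_z,
                         modality=images[0].modality, seed=seed,
                         n_iter=int(ica.n_iter_))


def regional_component_scores(maps: ComponentMaps, atlas: Atlas) -> pd.DataFrame:
    """Mean and SD of unthresholded component z-scores per atlas region.

    Rows follow the region table's matrix-position order; one block of 48
    rows per component.
    """
    if maps.mask.shape != atlas.shape:
        raise ValueError("atlas grid does not match component mask")
    labels = atlas.label_volume[maps.mask]
    rows = []
    for k in range(maps.n_components):
        m = maps.maps[k]
        for rec in atlas.region_table:
            sel = labels == rec.matrix_position
            if not sel.any():
                raise ValueError(f"region {rec.region_id} has no voxels in mask")
            rows.append({
                "component": k + 1,
                "position": rec.matrix_position,
                "region_id": rec.region_id,
                "mean_z": float(m[sel].mean()),
                "sd_z": float(m[sel].std()),
            })
    return pd.DataFrame(rows)


def component_effect_correlation(ic_scores: np.ndarray,
                                 effect_tscores: np.ndarray) -> tuple[float, float]:
    """Pearson correlation between regional IC z-scores and effect t-scores."""
    ic_scores = np.asarray(ic_scores, dtype=float)
    effect_tscores = np.asarray(effect_tscores, dtype=float)
    if ic_scores.shape != effect_tscores.shape:
        raise ValueError("region vectors differ in length")
    if ic_scores.size < 5:
        raise ValueError("need at least 5 regions")
    r, p = stats.pearsonr(ic_scores, effect_tscores)
    return float(r), float(p)


def match_components(maps: ComponentMaps, truth_maps: np.ndarray) -> list[tuple[int, float]]:
    """Greedy assignment of components to truth maps by absolute spatial r.

    ``truth_maps`` is n_truth x n_mask_voxels. Returns, per truth map, the
    matched component index and the absolute spatial correlation.
    """
    n_truth = truth_maps.shape[0]
    corr = np.zeros((n_truth, maps.n_components))
    for i in range(n_truth):
        for j in range(maps.n_components):
            corr[i, j] = abs(stats.pearsonr(truth_maps[i], maps.maps[j])[0])
    out: list[tuple[int, float]] = [(-1, 0.0)] * n_truth
    used: set[int] = set()
    flat = sorted(((corr[i, j], i, j) for i in range(n_truth)
                   for j in range(maps.n_components)), reverse=True)
    assigned = set()
    for c, i, j in flat:
        if i in assigned or j in used:
            continue
        out[i] = (j, float(c))
        assigned.add(i)
        used.add(j)
    return out
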