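"""Drug-challenge analysis: uptake t-maps, regional scores, MC-vs-BP change.

An acute displacement challenge (an MDMA-like serotonin releaser) lowers
tracer binding in proportion to transporter occupancy. Its footprint is
quantified on whole-brain-normalized static uptake images as voxelwise
two-sample t-maps between scan periods (baseline vs early, early vs late),
summarized per atlas region, and contrasted against connectivity changes:
each region's paired-t statistic of global molecular-connectivity strength
(mean Fisher z to all other regions) after vs before the challenge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import Atlas
from .connectivity import Connectome
from .kinetics import StaticImage

__all__ = ["EffectMap", "effect_tmap", "regional_effect_scores",
           "regional_mc_change_tscores", "bp_change_vs_mc_change",
           "detect_displacement_onset"]


@dataclass
class EffectMap:
    """Voxelwise t-statistics for a between-period uptake contrast."""

    t_volume: np.ndarray
    contrast: str                     # e.g. "baseline_vs_early"
    fwe_mask: np.ndarray              # voxels significant after Bonferroni
    alpha: float
    mask: np.ndarray                  # in-brain voxels tested
    windows: tuple[tuple[float, float], tuple[float, float]] | None = None


def effect_tmap(group_a: list[StaticImage], group_b: list[StaticImage],
                alpha: float = 0.05, mask: np.ndarray | None = None,
                contrast: str = "baseline_vs_early",
                paired: bool = False) -> EffectMap:
    """Voxelwise t-map of group_a minus group_b on normalized uptake images.

    The default is the unpaired two-sample test; ``paired=True`` switches to
    a paired test over matched subjects. Family-wise error control is
    Bonferroni over in-mask voxels.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be nonempty")
    shape = group_a[0].data.shape
    for img in (*group_a, *group_b):
        if img.data.shape != shape:
            raise ValueError("grid mismatch between static images")
        if img.normalization == "none":
            raise ValueError("effect maps require normalized static images")
    a = np.stack([img.data for img in group_a])
    b = np.stack([img.data for img in group_b])
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    if paired:
        if len(group_a) != len(group_b):
            raise ValueError("paired test requires equal group sizes")
        res = stats.ttest_rel(a, b, axis=0)
    else:
        res = stats.ttest_ind(a, b, axis=0)
    t = np.nan_to_num(np.asarray(res.statistic), nan=0.0)
    p = np.nan_to_num(np.asarray(res.pvalue), nan=1.0)
    n_vox = int(mask.sum())
    fwe = np.zeros(shape, dtype=bool)
    fwe[mask] = (p[mask] * n_vox) < alpha
    t = np.where(mask, t, 0.0)
    windows = (tuple(group_a[0].window_min), tuple(group_b[0].window_min))
    return EffectMap(t_volume=t, contrast=contrast, fwe_mask=fwe,
                     alpha=alpha, mask=mask, windows=windows)


def regional_effect_scores(emap: EffectMap, atlas: Atlas) -> pd.DataFrame:
    """Mean and SD of voxel t-scores per region, in matrix-position order."""
    if emap.t_volume.shape != atlas.shape:
        raise ValueError("atlas grid does not match t-volume")
    rows = []
    for rec in atlas.region_table:
        sel = atlas.label_volume == rec.matrix_position
        if not sel.any():
            raise ValueError(f"region {rec.region_id} has no labelled voxels")
        vals = emap.t_volume[sel]
        rows.append({
            "position": rec.matrix_position,
            "region_id": rec.region_id,
            "mean_t": float(vals.mean()),
            "sd_t": float(vals.std()),
        })
    return pd.DataFrame(rows)


def regional_mc_change_tscores(baseline: list[Connectome],
                               post: list[Connectome]) -> pd.DataFrame:
    """Per-region paired-t of global MC strength, post vs baseline.

    A region's global MC strength in one connectome is its mean Fisher z to
    all other regions. Negative t means reduced connectivity after the
    challenge.
    """
    if len(baseline) != len(post) or len(baseline) < 2:
        raise ValueError("need matched baseline/post connectomes for >=2 subjects")
    region_ids = baseline[0].region_ids
    R = len(region_ids)

    def _strengths(conns):
        s = np.stack([c.z for c in conns])  # subjects x R x R
        return (s.sum(axis=2)) / (R - 1)

    sb = _strengths(baseline)
    sp = _strengths(post)
    res = stats.ttest_rel(sp, sb, axis=0)
    return pd.DataFrame({
        "region_id": region_ids,
        "mc_t": np.nan_to_num(np.asarray(res.statistic), nan=0.0),
        "mc_p": np.nan_to_num(np.asarray(res.pvalue), nan=1.0),
        "strength_baseline": sb.mean(axis=0),
        "strength_post": sp.mean(axis=0),
    })


def bp_change_vs_mc_change(bp_t: np.ndarray, mc_t: np.ndarray,
                           region_ids: list[str] | None = None):
    """Compare regional binding-change and connectivity-change t-scores.

    Returns the Pearson r across regions and a tidy table for plotting.
    Both vectors follow the sign convention that reductions are negative.
    """
    bp_t = np.asarray(bp_t, dtype=float)
    mc_t = np.asarray(mc_t, dtype=float)
    if bp_t.shape != mc_t.shape:
        raise ValueError("region vectors differ in length")
    r, p = stats.pearsonr(bp_t, mc_t)
    table = pd.DataFrame({
        "region_id": region_ids if region_ids is not None
        else [f"r{i + 1}" for i in range(bp_t.size)],
        "bp_t": bp_t,
        "mc_t": mc_t,
    })
    return float(r), table


def detect_displacement_onset(t_min: np.ndarray, curve: np.ndarray,
                              baseline_window_min: tuple[float, float],
                              search_from_min: float | None = None,
                              n_sd: float = 4.0,
                              min_consecutive: int = 3,
                              plateau_window_min: tuple[float, float] | None = None,
                              drop_fraction: float = 0.25) -> float:
    """First sustained drop of a binding time course below its baseline band.

    The baseline mean and SD are taken over ``baseline_window_min``; the
    onset is the time of the first frame after ``search_from_min`` (default:
    baseline end) from which ``min_consecutive`` consecutive frames all lie
    below a threshold. Returns NaN if no sustained drop is found.

    Two threshold conventions:

    * default: mean - n_sd * SD of the baseline — simple, but the detection
      lag shrinks with displacement amplitude;
    * with ``plateau_window_min``: the threshold sits ``drop_fraction`` of
      the way from the baseline mean to the post-displacement plateau mean.
      For a saturating drop the lag to cross a fixed fraction of the full
      amplitude is independent of the amplitude, so onsets of curves with
      different displacement depths are directly comparable.
    """
    t_min = np.asarray(t_min, dtype=float)
    curve = np.asarray(curve, dtype=float)
    lo, hi = baseline_window_min
    base = curve[(t_min >= lo) & (t_min < hi)]
    if base.size < 3:
        raise ValueError("baseline window contains fewer than 3 frames")
    if plateau_window_min is not None:
        plo, phi = plateau_window_min
        plateau = curve[(t_min >= plo) & (t_min < phi)]
        if plateau.size < 3:
            raise ValueError("plateau window contains fewer than 3 frames")
        thresh = base.mean() - drop_fraction * (base.mean() - plateau.mean())
    else:
        thresh = base.mean() - n_sd * base.std(ddof=1)
    start = hi if search_from_min is None else search_from_min
    idx = np.nonzero(t_min >= start)[0]
    below = curve[idx] < thresh
    run = 0
    for k, flag in enumerate(below):
        run = run + 1 if flag else 0
        if run >= min_consecutive:
            return float(t_min[idx[k - min_consecutive + 1]])
    return float("nan")
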