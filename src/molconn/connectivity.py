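"""Fisher-z connectomes, group edge statistics, similarity, sliding windows.

A subject connectome is the matrix of pairwise Pearson correlations between
regional time series (BP_ND series for molecular connectivity, BOLD for
hemodynamic functional connectivity), Fisher z-transformed
(z = arctanh r) for variance-stabilized group statistics. Group inference
is a per-edge one-sample t-test against zero with Bonferroni family-wise
error control over the unique edges. Temporal stability and challenge
effects are probed with sliding windows and within-network mean edge
strength.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .atlas import NetworkDefinition, RegionTable
from .kinetics import RegionalTimeSeries

__all__ = [
    "Connectome",
    "GroupConnectome",
    "NetworkStrengthResult",
    "subject_connectome",
    "group_connectome",
    "edge_similarity",
    "sliding_window_connectomes",
    "network_strength",
    "network_strength_timecourse",
]

_R_CLIP = 1.0 - 1e-7


@dataclass
class Connectome:
    """Symmetric Fisher-z correlation matrix with zero diagonal."""

    z: np.ndarray
    region_ids: list[str]
    subject_id: str = ""
    window_min: tuple[float, float] | None = None
    modality: str = "PET"

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        R = len(self.region_ids)
        if self.z.shape != (R, R):
            raise ValueError("z matrix shape does not match region list")
        if not np.allclose(self.z, self.z.T, atol=0):
            raise ValueError("z matrix must be exactly symmetric")
        if np.any(np.diag(self.z) != 0):
            raise ValueError("diagonal must be zero")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("z matrix contains non-finite entries")

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def edges(self) -> np.ndarray:
        """Unique off-diagonal edges, row-major upper triangle."""
        iu = np.triu_indices(self.n_regions, k=1)
        return self.z[iu]


@dataclass
class GroupConnectome:
    """Edgewise group statistics over a cohort of connectomes."""

    mean_z: np.ndarray
    edge_t: np.ndarray
    edge_p: np.ndarray
    fwe_mask: np.ndarray
    n_subjects: int
    region_ids: list[str]
    alpha: float = 0.05

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def edges(self) -> np.ndarray:
        iu = np.triu_indices(self.n_regions, k=1)
        return self.mean_z[iu]

    def thresholded_mean_z(self) -> np.ndarray:
        """Display-convention matrix: edges failing FWE set exactly to zero."""
        out = np.where(self.fwe_mask, self.mean_z, 0.0)
        np.fill_diagonal(out, 0.0)
        return out


def _fisher_z(r: np.ndarray) -> np.ndarray:
    return np.arctanh(np.clip(r, -_R_CLIP, _R_CLIP))


def subject_connectome(ts, window_min: tuple[float, float] | None = None,
                       subject_id: str = "") -> Connectome:
    """Pairwise Pearson correlations between regional series, Fisher z.

    ``ts`` is a RegionalTimeSeries (optionally restricted to ``window_min``,
    half-open on frame midpoints) or a bare region x sample matrix.
    Correlations are clipped to +/-(1 - 1e-7) before arctanh so every z is
    finite. Zero-variance regions yield zero edges with a warning.
    """
    if isinstance(ts, RegionalTimeSeries):
        if window_min is not None:
            ts = ts.window(window_min)
        values = ts.values
        region_ids = list(ts.region_ids)
        modality = ts.modality
    else:
        values = np.asarray(ts, dtype=float)
        region_ids = [f"r{i + 1}" for i in range(values.shape[0])]
        modality = "PET"
    if values.shape[1] < 3:
        raise ValueError(f"need at least 3 samples per region, got {values.shape[1]}")

    sd = values.std(axis=1)
    # relative tolerance: a constant row's std is float noise, not exactly 0
    degenerate = sd <= 1e-12 * (np.abs(values).mean(axis=1) + 1.0)
    if np.any(degenerate):
        warnings.warn(
            f"zero-variance region(s) {[region_ids[i] for i in np.nonzero(degenerate)[0]]}; "
            "their edges are set to 0", stacklevel=2)
        values = values.copy()
        values[degenerate] = 0.0
        values[degenerate, 0] = 1.0  # benign fake variance; edges zeroed below

    r = np.corrcoef(values)
    z = _fisher_z(r)
    if np.any(degenerate):
        z[degenerate, :] = 0.0
        z[:, degenerate] = 0.0
    z = (z + z.T) / 2  # enforce exact symmetry against float asymmetries
    np.fill_diagonal(z, 0.0)
    return Connectome(z=z, region_ids=region_ids, subject_id=subject_id,
                      window_min=window_min, modality=modality)


def group_connectome(connectomes: list[Connectome], alpha: float = 0.05) -> GroupConnectome:
    """Mean connectome with per-edge one-sample t-tests and Bonferroni FWE.

    Each unique edge's Fisher-z values across subjects are tested against
    zero (two-sided); p-values are Bonferroni-corrected over the
    R(R-1)/2 unique edges.
    """
    if len(connectomes) < 2:
        raise ValueError("need at least 2 subjects")
    region_ids = connectomes[0].region_ids
    for c in connectomes[1:]:
        if c.region_ids != region_ids:
            raise ValueError("connectomes have mismatching region sets")
    stack = np.stack([c.z for c in connectomes])
    mean_z = stack.mean(axis=0)
    R = len(region_ids)
    iu = np.triu_indices(R, k=1)
    edge_vals = stack[:, iu[0], iu[1]]  # subjects x edges
    t, p = stats.ttest_1samp(edge_vals, 0.0, axis=0)
    n_edges = len(iu[0])
    p_corr = np.minimum(p * n_edges, 1.0)

    def _sym(vec, fill=0.0):
        m = np.full((R, R), fill)
        m[iu] = vec
        m[(iu[1], iu[0])] = vec
        np.fill_diagonal(m, 0.0 if fill == 0.0 else fill)
        return m

    edge_t = _sym(t)
    edge_p = _sym(p, fill=1.0)
    np.fill_diagonal(edge_p, 1.0)
    fwe = _sym((p_corr < alpha).astype(float)) > 0
    return GroupConnectome(mean_z=mean_z, edge_t=edge_t, edge_p=edge_p,
                           fwe_mask=fwe, n_subjects=len(connectomes),
                           region_ids=list(region_ids), alpha=alpha)


def edge_similarity(a, b) -> float:
    """Pearson correlation of two connectomes' unique off-diagonal edges."""
    if a.n_regions != b.n_regions:
        raise ValueError("connectomes differ in size")
    r, _ = stats.pearsonr(a.edges(), b.edges())
    return float(r)


def sliding_window_connectomes(ts: RegionalTimeSeries,
                               window_len_min: float = 20.0,
                               start_min: float = 20.0,
                               end_min: float = 80.0,
                               step_min: float = 5.0,
                               subject_id: str = "") -> list[Connectome]:
    """Connectomes on windows [s, s+len) for s = start, start+step, ...

    The last window start is the largest s <= end_min - window_len_min.
    """
    if ts.frame_mid_min[-1] < start_min + window_len_min:
        raise ValueError("window longer than the available series")
    out = []
    s = start_min
    while s <= end_min - window_len_min + 1e-9:
        out.append(subject_connectome(ts, window_min=(s, s + window_len_min),
                                      subject_id=subject_id))
        s += step_min
    return out


@dataclass
class NetworkStrengthResult:
    """Within-network connectivity strength of one window across a cohort."""

    network: str
    window_min: tuple[float, float] | None
    per_subject: np.ndarray        # mean within-network unique-edge z, per subject
    node_strength: dict[str, float]  # member -> mean within-network edge z (group mean)

    @property
    def network_strength(self) -> float:
        return float(self.per_subject.mean())


def network_strength(conn: Connectome, net: NetworkDefinition,
                     table: RegionTable) -> tuple[float, dict[str, float]]:
    """Mean within-network unique-edge z, and per-node mean edge z."""
    member_ids = net.member_ids(table)
    idx = [conn.region_ids.index(m) for m in member_ids]
    sub = conn.z[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), k=1)
    strength = float(sub[iu].mean())
    node = {}
    for k, m in enumerate(member_ids):
        others = [j for j in range(len(idx)) if j != k]
        node[m] = float(sub[k, others].mean())
    return strength, node


def network_strength_timecourse(windows_per_subject: list[list[Connectome]],
                                net: NetworkDefinition,
                                table: RegionTable,
                                baseline_index: int = 0,
                                alpha: float = 0.05):
    """Time-resolved within-network strength with paired tests vs baseline.

    Parameters
    ----------
    windows_per_subject : list over subjects of equal-length window lists.
    baseline_index : which window is the pre-challenge baseline.

    Returns
    -------
    results : list of NetworkStrengthResult, one per window
    p_fdr : array of Benjamini-Hochberg-adjusted paired-t p-values per
        window (baseline itself gets p = 1)
    final_test : (t, p) paired t-test of the final window against baseline
    """
    n_windows = len(windows_per_subject[0])
    for w in windows_per_subject:
        if len(w) != n_windows:
            raise ValueError("subjects have differing numbers of windows")
    strengths = np.empty((len(windows_per_subject), n_windows))
    results = []
    for j in range(n_windows):
        node_acc: dict[str, list[float]] = {}
        for i, windows in enumerate(windows_per_subject):
            s, node = network_strength(windows[j], net, table)
            strengths[i, j] = s
            for m, v in node.items():
                node_acc.setdefault(m, []).append(v)
        results.append(NetworkStrengthResult(
            network=net.name,
            window_min=windows_per_subject[0][j].window_min,
            per_subject=strengths[:, j].copy(),
            node_strength={m: float(np.mean(v)) for m, v in node_acc.items()},
        ))
    base = strengths[:, baseline_index]
    p_raw = np.ones(n_windows)
    for j in range(n_windows):
        if j == baseline_index:
            continue
        diff = strengths[:, j] - base
        if np.allclose(diff, 0):
            p_raw[j] = 1.0
        else:
            p_raw[j] = stats.ttest_rel(strengths[:, j], base).pvalue
    others = [j for j in range(n_windows) if j != baseline_index]
    p_fdr = np.ones(n_windows)
    if others:
        p_fdr[others] = multipletests(p_raw[others], alpha=alpha, method="fdr_bh")[1]
    diff = strengths[:, -1] - base
    if np.allclose(diff, 0):
        final_test = (0.0, 1.0)
    else:
        res = stats.ttest_rel(strengths[:, -1], base)
        final_test = (float(res.statistic), float(res.pvalue))
    return results, p_fdr, final_test
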