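"""Synthetic simultaneous PET/BOLD cohorts with known ground truth.

The generator emulates a bolus-plus-constant-infusion reference-tissue PET
protocol (k_bol expressed as minutes of infusion contained in the bolus)
acquired simultaneously with resting-state BOLD: an 80-min scan in 1-min
PET frames (80 frames) and a 2-s repetition time (2400 BOLD volumes).

Ground truth is planted at the level the downstream analyses measure:

* two molecular networks (a subcortical high-binding network and a
  salience-like projection network) whose regional BP_ND series share a
  network-wide latent fluctuation, producing a block-structured molecular
  connectome;
* an optional displacement challenge at 40 min driving receptor occupancy
  up along a saturating onset curve — immediately in the subcortical
  network and ~10 min later in the salience network — which multiplies
  BP_ND by (1 - occupancy);
* BOLD series built from order-1 autoregressive innovations mixed through
  the same network structure.

Regional PET activity follows activity = ref(t) * (1 + BP_r(t)) + noise,
so framewise DVR-1 quantification recovers the planted BP_r(t) exactly in
the noise-free limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .atlas import (Atlas, NetworkDefinition, RegionTable, REFERENCE_ID,
                    REFERENCE_LABEL, SALIENCE_NETWORK, SUBCORTICAL_NETWORK,
                    build_toy_atlas, load_region_table)
from .kinetics import DynamicImage, FrameSchedule, RegionalTimeSeries

__all__ = ["SimulationConfig", "SimulationTruth", "SimulatedCohort",
           "simulate_reference_tac", "occupancy_curve", "simulate_cohort",
           "simulate_component_images", "paint_regional_series"]

#: time constant giving 95% of occupancy amplitude 10 min after onset
_OCC_TAU_MIN = 10.0 / np.log(20.0)


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic PET/BOLD cohort.

    Defaults mirror the emulated acquisition protocol: an 80-min scan with
    1-min PET frames and TR = 2 s BOLD, bolus-plus-infusion with
    k_bol = 38.7 min, and a challenge (when enabled) at 40 min with a
    ~10-min delayed salience response.
    """

    n_subjects: int = 30
    scan_min: float = 80.0
    pet_frame_min: float = 1.0
    bold_tr_s: float = 2.0
    k_bol_min: float = 38.7
    challenge_min: float | None = None
    occupancy_amplitude: dict = field(
        default_factory=lambda: {"subcortical": 0.40, "salience": 0.25})
    background_occupancy: float = 0.15
    salience_delay_min: float = 10.0
    coupling_reduction: dict = field(default_factory=dict)
    baseline_bp: dict | None = None
    network_defs: list = field(
        default_factory=lambda: [SUBCORTICAL_NETWORK, SALIENCE_NETWORK])
    fluctuation_sd: float = 0.06          # shared network factor, relative BP
    private_fluctuation_sd: float = 0.04  # per-region factor, relative BP
    fluctuation_corr_time_min: float = 3.0
    noise_sd: float = 0.02                # PET activity noise per 1-min frame
    voxel_noise_sd: float = 0.05          # extra voxel noise when painting
    bold_network_loading: float = 0.5
    bold_ar: float = 0.4
    # reference-tissue kinetics: plasma elimination matched to the default
    # k_bol so the standard protocol pre-fills the plasma steady state
    plasma_elim_per_min: float = 1.0 / 38.7
    ref_k2_per_min: float = 0.15
    infusion_rate: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.challenge_min is not None and not (0 < self.challenge_min < self.scan_min):
            raise ValueError("challenge time must lie within the scan")
        for name, amp in self.occupancy_amplitude.items():
            if not 0 <= amp < 1:
                raise ValueError(f"occupancy amplitude for {name!r} must be in [0, 1)")

    @classmethod
    def mdma_like(cls, n_subjects: int = 11, **kw) -> "SimulationConfig":
        """The challenge-cohort conditions: displacement at 40 min."""
        kw.setdefault("challenge_min", 40.0)
        return cls(n_subjects=n_subjects, **kw)

    @property
    def n_pet_frames(self) -> int:
        return int(round(self.scan_min / self.pet_frame_min))

    @property
    def n_bold_volumes(self) -> int:
        return int(round(self.scan_min * 60.0 / self.bold_tr_s))

    def frame_schedule(self) -> FrameSchedule:
        return FrameSchedule.uniform(self.n_pet_frames, self.pet_frame_min)

    def default_baseline_bp(self, table: RegionTable) -> dict:
        """A graded SERT-density profile: highest binding in the subcortical
        network (raphe-adjacent structures), intermediate in the salience
        projection targets, lower and smoothly varying elsewhere. Densities
        vary region to region within each class, as transporter expression
        does, rather than sitting at flat class values."""
        if self.baseline_bp is not None:
            return dict(self.baseline_bp)
        by_name = {n.name: n for n in self.network_defs}
        sub_ids = by_name["subcortical"].member_ids(table) if "subcortical" in by_name else []
        sal_ids = by_name["salience"].member_ids(table) if "salience" in by_name else []
        other_ids = [rid for rid in table.region_ids
                     if rid not in sub_ids and rid not in sal_ids]
        bp: dict[str, float] = {}
        for ids, hi, lo in ((sub_ids, 2.6, 1.8), (sal_ids, 1.45, 0.95),
                            (other_ids, 0.85, 0.35)):
            for rid, val in zip(ids, np.linspace(hi, lo, max(len(ids), 1))):
                bp[rid] = float(val)
        return bp


@dataclass
class SimulationTruth:
    """Everything planted by the generator, for closed-loop validation."""

    region_ids: list[str]
    network_of_region: dict          # region_id -> network name or None
    baseline_bp: dict                # region_id -> BP_ND
    occupancy: np.ndarray            # regions x PET frames, fraction occupied
    occupancy_amplitude: dict        # region_id -> planted plateau amplitude
    bp_series: list                  # per subject: regions x frames planted BP_r(t)
    latent_factors: list             # per subject: network -> shared factor series
    block_structure: np.ndarray      # regions x regions, True within a network
    per_subject_seeds: list
    frame_mid_min: np.ndarray
    seed: int


@dataclass
class SimulatedCohort:
    """Simulator output: per-subject PET and BOLD data plus ground truth."""

    pet: list                        # RegionalTimeSeries or DynamicImage
    bold: list                       # RegionalTimeSeries or DynamicImage
    truth: SimulationTruth
    schedule: FrameSchedule
    config: SimulationConfig
    atlas: Atlas | None = None


def simulate_reference_tac(config: SimulationConfig,
                           t_min: np.ndarray | None = None) -> np.ndarray:
    """Reference-tissue activity under bolus plus constant infusion.

    Plasma is one-compartment with elimination ``plasma_elim_per_min`` fed
    by a constant infusion plus an initial bolus equal to ``k_bol_min``
    minutes of infusion; the reference tissue follows one-tissue kinetics
    with efflux ``ref_k2_per_min`` and unit equilibrium distribution volume.
    With the default k_bol matched to the plasma elimination the plasma is
    constant from t = 0 and the tissue rises monotonically to a stable
    plateau. The whole curve is linear in the infusion rate.
    """
    if config.k_bol_min < 0:
        raise ValueError("k_bol must be non-negative")
    if config.k_bol_min == 0 and config.plasma_elim_per_min <= 0:
        raise ValueError("plasma elimination must be positive")
    if t_min is None:
        t_min = config.frame_schedule().mid_min
    t = np.asarray(t_min, dtype=float)
    kel = config.plasma_elim_per_min
    k2 = config.ref_k2_per_min
    R = config.infusion_rate
    A = R / kel                       # plasma steady state
    B = R * (config.k_bol_min - 1.0 / kel)  # bolus mismatch term
    curve = A * (1.0 - np.exp(-k2 * t))
    if B != 0.0:
        if abs(k2 - kel) < 1e-12:
            curve += k2 * B * t * np.exp(-k2 * t)
        else:
            curve += k2 * B * (np.exp(-kel * t) - np.exp(-k2 * t)) / (k2 - kel)
    return curve


def occupancy_curve(t_min: np.ndarray, onset_min: float, amplitude: float) -> np.ndarray:
    """Saturating occupancy onset: 0 before onset, 95% of amplitude by +10 min."""
    t = np.asarray(t_min, dtype=float)
    occ = np.zeros_like(t)
    after = t >= onset_min
    occ[after] = amplitude * (1.0 - np.exp(-(t[after] - onset_min) / _OCC_TAU_MIN))
    return occ


def _ar1_series(rng: np.random.Generator, n: int, sd: float, phi: float,
                size: int = 1) -> np.ndarray:
    """Stationary AR(1) rows with marginal SD ``sd`` and lag-1 correlation phi."""
    innov_sd = sd * np.sqrt(1.0 - phi ** 2)
    x = np.empty((size, n))
    x[:, 0] = rng.normal(0.0, sd, size)
    eps = rng.normal(0.0, innov_sd, (size, n - 1))
    for t in range(1, n):
        x[:, t] = phi * x[:, t - 1] + eps[:, t - 1]
    return x


def simulate_cohort(config: SimulationConfig,
                    table: RegionTable | None = None,
                    paint_pet: bool = False,
                    paint_bold: bool = False,
                    atlas: Atlas | None = None) -> SimulatedCohort:
    """Generate a cohort of simultaneous dynamic PET and BOLD datasets.

    By default regional time series are returned (the substrate of every
    regional analysis); with ``paint_pet``/``paint_bold`` the regional
    values are painted into the toy atlas volume (plus voxel noise) to
    produce 4D images for voxel-level analyses. Identical seeds give
    byte-identical outputs.
    """
    if table is None:
        table = load_region_table()
    if (paint_pet or paint_bold) and atlas is None:
        atlas = build_toy_atlas(region_table=table)

    region_ids = table.region_ids
    R = len(region_ids)
    schedule = config.frame_schedule()
    t_pet = schedule.mid_min
    n_pet = schedule.n_frames
    n_bold = config.n_bold_volumes
    t_bold = (config.bold_tr_s / 60.0) * (np.arange(n_bold) + 0.5)

    # network membership
    network_of: dict[str, str | None] = {rid: None for rid in region_ids}
    members: dict[str, list[int]] = {}
    for net in config.network_defs:
        ids = net.member_ids(table)
        members[net.name] = [region_ids.index(i) for i in ids]
        for rid in ids:
            if network_of[rid] is not None:
                raise ValueError(f"region {rid} assigned to two networks")
            network_of[rid] = net.name
    block = np.zeros((R, R), dtype=bool)
    for idx in members.values():
        block[np.ix_(idx, idx)] = True
    np.fill_diagonal(block, False)

    baseline_bp = config.default_baseline_bp(table)
    bp0 = np.array([baseline_bp[rid] for rid in region_ids])

    # occupancy truth (identical across subjects): network plateaus for
    # members, a small density-scaled background occupancy elsewhere —
    # a displacing drug binds transporters brain-wide, strongest where
    # availability is highest
    occ = np.zeros((R, n_pet))
    occ_amp = {rid: 0.0 for rid in region_ids}
    if config.challenge_min is not None:
        bp_max = bp0.max()
        for i, rid in enumerate(region_ids):
            if network_of[rid] is None:
                amp = config.background_occupancy * bp0[i] / bp_max
                occ[i] = occupancy_curve(t_pet, config.challenge_min, amp)
                occ_amp[rid] = float(amp)
        for net in config.network_defs:
            amp = config.occupancy_amplitude.get(net.name, 0.0)
            onset = config.challenge_min
            if net.name == "salience":
                onset = onset + config.salience_delay_min
            curve = occupancy_curve(t_pet, onset, amp)
            for i in members[net.name]:
                occ[i] = curve
                occ_amp[region_ids[i]] = amp

    # post-challenge shared-coupling attenuation per network (for planting
    # connectivity reductions beyond what occupancy itself produces)
    coupling = np.ones((R, n_pet))
    if config.challenge_min is not None:
        for name, red in config.coupling_reduction.items():
            onset = config.challenge_min
            if name == "salience":
                onset += config.salience_delay_min
            factor = 1.0 - red * (occupancy_curve(t_pet, onset, 1.0))
            for i in members[name]:
                coupling[i] = factor

    ref = simulate_reference_tac(config, t_pet)
    phi_pet = float(np.exp(-config.pet_frame_min / config.fluctuation_corr_time_min))
    phi_bold = config.bold_ar
    frame_dur = schedule.duration_min

    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_subjects)
    per_subject_seeds = [int(c.generate_state(1)[0]) for c in children]

    pet_out, bold_out = [], []
    bp_series_truth, factors_truth = [], []
    net_names = list(members)
    for s in range(config.n_subjects):
        rng = np.random.default_rng(children[s])
        shared = {name: _ar1_series(rng, n_pet, config.fluctuation_sd, phi_pet)[0]
                  for name in net_names}
        private = _ar1_series(rng, n_pet, config.private_fluctuation_sd, phi_pet, size=R)
        fluct = private.copy()
        for name, idx in members.items():
            fluct[idx] += shared[name][None, :] * coupling[idx]
        bp_t = bp0[:, None] * (1.0 - occ) * (1.0 + fluct)
        bp_series_truth.append(bp_t)
        factors_truth.append(shared)

        activity = ref[None, :] * (1.0 + bp_t)
        ref_activity = ref.copy()
        if config.noise_sd > 0:
            scale = config.noise_sd / np.sqrt(frame_dur)[None, :]
            activity = activity + rng.normal(0.0, 1.0, activity.shape) * scale * np.abs(activity)
            ref_activity = ref_activity + rng.normal(0.0, 1.0, n_pet) * scale[0] * np.abs(ref_activity)
        pet_ts = RegionalTimeSeries(
            values=np.vstack([activity, ref_activity[None, :]]),
            region_ids=region_ids + [REFERENCE_ID],
            frame_mid_min=t_pet, modality="PET")

        # BOLD: AR(1) innovations mixed through the network loading matrix
        shared_b = {name: _ar1_series(rng, n_bold, 1.0, phi_bold)[0]
                    for name in net_names}
        bold = _ar1_series(rng, n_bold, 1.0, phi_bold, size=R)
        for name, idx in members.items():
            bold[idx] += config.bold_network_loading * shared_b[name][None, :]
        bold_ts = RegionalTimeSeries(values=bold, region_ids=list(region_ids),
                                     frame_mid_min=t_bold, modality="BOLD")

        if paint_pet:
            pet_out.append(paint_regional_series(
                pet_ts, atlas, rng, voxel_noise_sd=config.voxel_noise_sd,
                schedule=schedule))
        else:
            pet_out.append(pet_ts)
        if paint_bold:
            bold_out.append(paint_regional_series(
                bold_ts, atlas, rng, voxel_noise_sd=config.voxel_noise_sd,
                repetition_time_s=config.bold_tr_s, additive_noise=True))
        else:
            bold_out.append(bold_ts)

    truth = SimulationTruth(
        region_ids=list(region_ids),
        network_of_region=network_of,
        baseline_bp=baseline_bp,
        occupancy=occ,
        occupancy_amplitude=occ_amp,
        bp_series=bp_series_truth,
        latent_factors=factors_truth,
        block_structure=block,
        per_subject_seeds=per_subject_seeds,
        frame_mid_min=t_pet,
        seed=config.seed,
    )
    return SimulatedCohort(pet=pet_out, bold=bold_out, truth=truth,
                           schedule=schedule, config=config, atlas=atlas)


def paint_regional_series(ts: RegionalTimeSeries, atlas: Atlas,
                          rng: np.random.Generator | None = None,
                          voxel_noise_sd: float = 0.0,
                          schedule: FrameSchedule | None = None,
                          repetition_time_s: float | None = None,
                          additive_noise: bool = False) -> DynamicImage:
    """Paint regional values into the atlas label volume as a 4D image.

    Every voxel of a region carries the regional value, plus independent
    Gaussian voxel noise (relative to the value, or additive for zero-mean
    BOLD series). The reference row, when present, fills the reference
    label.
    """
    n_frames = ts.n_frames
    data = np.zeros(atlas.shape + (n_frames,), dtype=float)
    pos_of = {rec.region_id: rec.matrix_position for rec in atlas.region_table}
    pos_of[REFERENCE_ID] = REFERENCE_LABEL
    for i, rid in enumerate(ts.region_ids):
        label = pos_of[rid]
        sel = atlas.label_volume == label
        vals = np.broadcast_to(ts.values[i], (int(sel.sum()), n_frames)).copy()
        if voxel_noise_sd > 0 and rng is not None:
            noise = rng.normal(0.0, voxel_noise_sd, vals.shape)
            vals = vals + noise if additive_noise else vals * (1.0 + noise)
        data[sel] = vals
    if ts.modality == "PET":
        return DynamicImage(data=data, voxel_size_mm=atlas.voxel_size_mm,
                            modality="PET", timing=schedule)
    return DynamicImage(data=data, voxel_size_mm=atlas.voxel_size_mm,
                        modality="BOLD", repetition_time_s=repetition_time_s)


def simulate_component_images(n_subjects: int = 2, n_frames: int = 80,
                              frame_min: float = 1.0, noise_sd: float = 0.3,
                              seed: int = 0, atlas: Atlas | None = None):
    """4D PET-like images containing two disjoint planted spatial patterns.

    Each pattern occupies the voxels of one planted network's regions and is
    driven by its own smooth latent time course, independent across
    patterns; everything rides on i.i.d. voxel noise. Within a pattern the
    member regions carry alternating-sign weights centred to a zero sum, so
    the two spatial sources are uncorrelated over voxels as the ICA model
    assumes (disjoint all-positive blobs would be negatively correlated by
    construction). Returns (images, truth_maps, mask): truth maps are the
    in-mask planted weights.
    """
    if atlas is None:
        atlas = build_toy_atlas()
    table = atlas.region_table
    mask = atlas.mask(include_reference=False)
    patterns = []
    for net in (SUBCORTICAL_NETWORK, SALIENCE_NETWORK):
        vol = np.zeros(atlas.shape)
        positions = net.member_positions(table)
        for k, pos in enumerate(positions):
            vol[atlas.label_volume == pos] = 1.0 if k % 2 == 0 else -1.0
        flat = vol[mask]
        support = flat != 0
        flat[support] -= flat[support].mean()
        patterns.append(flat)
    truth_maps = np.stack(patterns)

    ss = np.random.SeedSequence(seed)
    rngs = [np.random.default_rng(c) for c in ss.spawn(n_subjects)]
    schedule = FrameSchedule.uniform(n_frames, frame_min)
    images = []
    for rng in rngs:
        courses = _ar1_series(rng, n_frames, 1.0, 0.5, size=2)
        vox = rng.normal(0.0, noise_sd, (mask.sum(), n_frames))
        vox += truth_maps.T @ courses
        data = np.zeros(atlas.shape + (n_frames,))
        data[mask] = vox
        images.append(DynamicImage(data=data, voxel_size_mm=atlas.voxel_size_mm,
                                   modality="PET", timing=schedule))
    return images, truth_maps, mask
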