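"""End-to-end pipeline: simulate → extract → bp → connectome → graph →
ica → challenge → report, with file products and provenance per stage.

Each stage reads only the products of earlier stages from the run
directory and never mutates them; rerunning a later stage leaves earlier
outputs untouched. All randomness flows from the single top-level seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .atlas import (SALIENCE_NETWORK, SUBCORTICAL_NETWORK, build_toy_atlas,
                    extract_regional_timeseries, load_region_table)
from .challenge import (bp_change_vs_mc_change, effect_tmap,
                        regional_effect_scores, regional_mc_change_tscores)
from .connectivity import (edge_similarity, group_connectome,
                           network_strength_timecourse, sliding_window_connectomes,
                           subject_connectome)
from .graph import group_small_world_test, small_world_coefficient
from .ica import group_spatial_ica, regional_component_scores
from .kinetics import discard_and_detrend, framewise_bpnd, static_uptake
from .simulate import SimulationConfig, simulate_cohort

logger = logging.getLogger(__name__)

STAGES = ["simulate", "extract", "bp", "connectome", "graph", "ica",
          "challenge", "report"]

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    """Declarative configuration of one pipeline run."""

    seed: int = 0
    n_subjects: int = 11
    challenge_min: float | None = None
    paint_pet: bool = False
    reference_region: str = "Cer"
    discard_min: float = 20.0
    knot_interval_min: float = 20.0
    window_len_min: float = 20.0
    window_step_min: float = 5.0
    window_start_min: float = 20.0
    window_end_min: float = 80.0
    baseline_window_min: tuple = (30.0, 40.0)
    early_window_min: tuple = (50.0, 60.0)
    late_window_min: tuple = (70.0, 80.0)
    ica_window_min: tuple = (30.0, 80.0)
    n_components: int = 2
    alpha: float = 0.05
    density: float = 0.25
    n_rand: int = 100
    # paths for pre-existing data (optional; simulation used when absent)
    pet_images: list = field(default_factory=list)
    pet_timing: list = field(default_factory=list)
    bold_images: list = field(default_factory=list)
    bold_tr_s: float = 2.0
    atlas_labels: str | None = None
    region_table: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("baseline_window_min", "early_window_min", "late_window_min",
                    "ica_window_min"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def simulation_config(self) -> SimulationConfig:
        return SimulationConfig(n_subjects=self.n_subjects, seed=self.seed,
                                challenge_min=self.challenge_min,
                                bold_tr_s=self.bold_tr_s)


def _provenance(cfg: PipelineConfig, stage: str, params: dict) -> dict:
    return {"stage": stage, "config_hash": cfg.config_hash(), "seed": cfg.seed,
            "version": __version__, "params": params}


def _write_provenance(cfg, stage, rundir: Path, **params) -> None:
    path = rundir / stage / "provenance.json"
    path.write_text(json.dumps(_provenance(cfg, stage, params), indent=1,
                               default=str))


def _require(rundir: Path, relpath: str, needed_stage: str) -> Path:
    p = rundir / relpath
    if not p.exists():
        raise FileNotFoundError(
            f"missing upstream product {relpath}; run stage '{needed_stage}' first")
    return p


def _subject_paths(rundir: Path, stage: str, pattern: str) -> list[Path]:
    return sorted((rundir / stage).glob(pattern))


def stage_simulate(cfg: PipelineConfig, rundir: Path) -> None:
    out = rundir / "simulate"
    out.mkdir(parents=True, exist_ok=True)
    sim_cfg = cfg.simulation_config()
    cohort = simulate_cohort(sim_cfg, paint_pet=cfg.paint_pet)
    mio.save_frame_schedule(cohort.schedule, out / "pet_timing.json")
    for s in range(cfg.n_subjects):
        tag = f"sub-{s + 1:02d}"
        if cfg.paint_pet:
            mio.save_dynamic_image(cohort.pet[s], out / f"{tag}_pet.nii.gz")
        else:
            mio.save_timeseries(cohort.pet[s], out / f"{tag}_pet_tac.tsv")
        mio.save_timeseries(cohort.bold[s], out / f"{tag}_bold_tac.tsv")
    if cfg.paint_pet:
        mio.save_label_volume(cohort.atlas, out / "atlas_labels.nii.gz")
    truth = cohort.truth
    (out / "truth.json").write_text(json.dumps({
        "region_ids": truth.region_ids,
        "network_of_region": truth.network_of_region,
        "baseline_bp": truth.baseline_bp,
        "occupancy_amplitude": truth.occupancy_amplitude,
        "per_subject_seeds": truth.per_subject_seeds,
        "seed": truth.seed,
    }, indent=1))
    _write_provenance(cfg, "simulate", rundir, n_subjects=cfg.n_subjects,
                      challenge_min=cfg.challenge_min, paint_pet=cfg.paint_pet,
                      simulation=dataclasses.asdict(sim_cfg))


def stage_extract(cfg: PipelineConfig, rundir: Path) -> None:
    out = rundir / "extract"
    out.mkdir(parents=True, exist_ok=True)
    if cfg.pet_images:  # user-supplied images
        atlas = mio.load_atlas(cfg.atlas_labels, cfg.region_table)
        for s, (img_path, timing) in enumerate(zip(cfg.pet_images, cfg.pet_timing)):
            img = mio.load_dynamic_image(img_path, timing)
            ts = extract_regional_timeseries(img, atlas)
            mio.save_timeseries(ts, out / f"sub-{s + 1:02d}_pet_tac.tsv")
        for s, img_path in enumerate(cfg.bold_images):
            img = mio.load_dynamic_image(img_path, modality="BOLD",
                                         repetition_time_s=cfg.bold_tr_s)
            ts = extract_regional_timeseries(img, atlas)
            mio.save_timeseries(ts, out / f"sub-{s + 1:02d}_bold_tac.tsv")
    elif cfg.paint_pet:
        labels = _require(rundir, "simulate/atlas_labels.nii.gz", "simulate")
        atlas = mio.load_atlas(labels, cfg.region_table)
        timing = _require(rundir, "simulate/pet_timing.json", "simulate")
        for path in _subject_paths(rundir, "simulate", "sub-*_pet.nii.gz"):
            img = mio.load_dynamic_image(path, timing)
            ts = extract_regional_timeseries(img, atlas)
            mio.save_timeseries(ts, out / (path.name.split("_pet")[0] + "_pet_tac.tsv"))
        for path in _subject_paths(rundir, "simulate", "sub-*_bold_tac.tsv"):
            mio.save_timeseries(mio.load_timeseries(path), out / path.name)
    else:
        tacs = _subject_paths(rundir, "simulate", "sub-*_tac.tsv")
        if not tacs:
            raise FileNotFoundError(
                "missing upstream regional series; run stage 'simulate' first "
                "or provide pet_images in the config")
        for path in tacs:
            mio.save_timeseries(mio.load_timeseries(path), out / path.name)
    _write_provenance(cfg, "extract", rundir, source="images" if cfg.pet_images
                      else "simulate")


def stage_bp(cfg: PipelineConfig, rundir: Path) -> None:
    out = rundir / "bp"
    out.mkdir(parents=True, exist_ok=True)
    tacs = _subject_paths(rundir, "extract", "sub-*_pet_tac.tsv")
    if not tacs:
        raise FileNotFoundError("missing upstream PET series; run stage 'extract' first")
    for path in tacs:
        ts = mio.load_timeseries(path)
        bp = framewise_bpnd(ts, reference=cfg.reference_region)
        bp = discard_and_detrend(bp, discard_min=cfg.discard_min,
                                 knot_interval_min=cfg.knot_interval_min)
        mio.save_bpseries(bp, out / path.name.replace("_pet_tac", "_bp"))
    _write_provenance(cfg, "bp", rundir, reference=cfg.reference_region,
                      discard_min=cfg.discard_min,
                      knot_interval_min=cfg.knot_interval_min)


def stage_connectome(cfg: PipelineConfig, rundir: Path) -> None:
    out = rundir / "connectome"
    out.mkdir(parents=True, exist_ok=True)
    bps = _subject_paths(rundir, "bp", "sub-*_bp.tsv")
    if not bps:
        raise FileNotFoundError("missing upstream BP series; run stage 'bp' first")
    mc, fc = [], []
    for path in bps:
        bp = mio.load_bpseries(path)
        conn = subject_connectome(bp.as_timeseries(), subject_id=path.stem)
        mc.append(conn)
        mio.save_connectome(conn, out / path.name.replace("_bp", "_mc"))
        for w in sliding_window_connectomes(
                bp.as_timeseries(), window_len_min=cfg.window_len_min,
                start_min=cfg.window_start_min, end_min=cfg.window_end_min,
                step_min=cfg.window_step_min, subject_id=path.stem):
            lo = int(w.window_min[0])
            mio.save_connectome(w, out / path.name.replace(
                "_bp", f"_mc_win{lo:02d}"))
    for path in _subject_paths(rundir, "extract", "sub-*_bold_tac.tsv"):
        ts = mio.load_timeseries(path)
        conn = subject_connectome(ts, subject_id=path.stem)
        fc.append(conn)
        mio.save_connectome(conn, out / path.name.replace("_bold_tac", "_fc"))
    if len(mc) >= 2:
        mio.save_group_edges(group_connectome(mc, alpha=cfg.alpha),
                             out / "group_mc_edges.tsv")
    if len(fc) >= 2:
        mio.save_group_edges(group_connectome(fc, alpha=cfg.alpha),
                             out / "group_fc_edges.tsv")
    _write_provenance(cfg, "connectome", rundir, alpha=cfg.alpha,
                      window_len_min=cfg.window_len_min,
                      window_step_min=cfg.window_step_min)


def stage_graph(cfg: PipelineConfig, rundir: Path) -> None:
    out = rundir / "graph"
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    metrics_by_mod = {"MC": [], "FC": []}
    rng = np.random.default_rng(cfg.seed + 1)
    for pattern, modality in (("sub-*_mc.tsv", "MC"), ("sub-*_fc.tsv", "FC")):
        for path in _subject_paths(rundir, "connectome", pattern):
            conn = mio.load_connectome(path, subject_id=path.stem)
            m = small_world_coefficient(conn, density=cfg.density,
                                        n_rand=cfg.n_rand,
                                        seed=int(rng.integers(2 ** 31)))
            metrics_by_mod[modality].append(m)
            rows.append({"subject_id": path.stem, "modality": modality,
                         "C": m.clustering_C, "L": m.path_length_L,
                         "sigma": m.sigma, "density": m.density, "seed": m.seed})
    if not rows:
        raise FileNotFoundError("missing upstream connectomes; run stage "
                                "'connectome' first")
    pd.DataFrame(rows).to_csv(out / "small_world_metrics.tsv", sep="\t", index=False)
    tests = {}
    for modality, ms in metrics_by_mod.items():
        if len(ms) >= 2:
            mean, sd, t, p = group_small_world_test(ms)
            tests[modality] = {"mean_sigma": mean, "sd": sd, "t": t, "p": p}
    (out / "group_tests.json").write_text(json.dumps(tests, indent=1))
    _write_provenance(cfg, "graph", rundir, density=cfg.density, n_rand=cfg.n_rand)


def stage_ica(cfg: PipelineConfig, rundir: Path) -> None:
    import nibabel as nib
    out = rundir / "ica"
    out.mkdir(parents=True, exist_ok=True)
    labels = _require(rundir, "simulate/atlas_labels.nii.gz", "simulate (with paint_pet)")
    timing = _require(rundir, "simulate/pet_timing.json", "simulate")
    atlas = mio.load_atlas(labels, cfg.region_table)
    images = [mio.load_dynamic_image(p, timing)
              for p in _subject_paths(rundir, "simulate", "sub-*_pet.nii.gz")]
    if len(images) < 2:
        raise FileNotFoundError("ICA needs >=2 painted PET images; run "
                                "'simulate' with paint_pet")
    maps = group_spatial_ica(images, atlas.mask(), n_components=cfg.n_components,
                             seed=cfg.seed + 2,
                             analysis_window_min=cfg.ica_window_min)
    vol4d = maps.stack_volume()
    nib.save(nib.Nifti1Image(vol4d.astype(np.float32), np.eye(4)),
             str(out / "component_maps.nii.gz"))
    regional_component_scores(maps, atlas).to_csv(
        out / "component_regional_scores.tsv", sep="\t", index=False)
    _write_provenance(cfg, "ica", rundir, n_components=cfg.n_components,
                      window=cfg.ica_window_min)


def stage_challenge(cfg: PipelineConfig, rundir: Path) -> None:
    out = rundir / "challenge"
    out.mkdir(parents=True, exist_ok=True)
    if cfg.challenge_min is None:
        raise ValueError("challenge stage requires challenge_min in the config")
    labels = _require(rundir, "simulate/atlas_labels.nii.gz", "simulate (with paint_pet)")
    timing = _require(rundir, "simulate/pet_timing.json", "simulate")
    atlas = mio.load_atlas(labels, cfg.region_table)
    mask = atlas.mask()
    pet_paths = _subject_paths(rundir, "simulate", "sub-*_pet.nii.gz")
    if not pet_paths:
        raise FileNotFoundError("challenge stage needs painted PET images; run "
                                "'simulate' with paint_pet")
    images = [mio.load_dynamic_image(p, timing) for p in pet_paths]
    statics = {name: [static_uptake(img, window, brain_mask=mask)
                      for img in images]
               for name, window in (("baseline", cfg.baseline_window_min),
                                    ("early", cfg.early_window_min),
                                    ("late", cfg.late_window_min))}
    summaries = {}
    for contrast, (a, b) in (("baseline_vs_early", ("baseline", "early")),
                             ("early_vs_late", ("early", "late"))):
        emap = effect_tmap(statics[a], statics[b], alpha=cfg.alpha, mask=mask,
                           contrast=contrast)
        scores = regional_effect_scores(emap, atlas)
        scores.to_csv(out / f"{contrast}_regional_t.tsv", sep="\t", index=False)
        summaries[contrast] = {"n_fwe_voxels": int(emap.fwe_mask.sum()),
                               "max_abs_t": float(np.abs(emap.t_volume).max())}
    # MC change per region: baseline vs post-challenge window connectomes
    bps = [mio.load_bpseries(p) for p in _subject_paths(rundir, "bp", "sub-*_bp.tsv")]
    if len(bps) < 2:
        raise FileNotFoundError("missing BP series; run stage 'bp' first")
    base = [subject_connectome(b.as_timeseries(), window_min=(20.0, 40.0)) for b in bps]
    post = [subject_connectome(b.as_timeseries(), window_min=(60.0, 80.0)) for b in bps]
    mc_change = regional_mc_change_tscores(base, post)
    mc_change.to_csv(out / "mc_change_t.tsv", sep="\t", index=False)
    bvse = np.asarray(pd.read_csv(
        out / "baseline_vs_early_regional_t.tsv", sep="\t")["mean_t"])
    # sign flip: baseline minus early is positive where binding dropped
    r, table = bp_change_vs_mc_change(-bvse, mc_change["mc_t"].to_numpy(),
                                      region_ids=list(mc_change["region_id"]))
    table.to_csv(out / "bp_vs_mc_change.tsv", sep="\t", index=False)
    summaries["bp_vs_mc_change_r"] = float(r)
    (out / "summary.json").write_text(json.dumps(summaries, indent=1))
    _write_provenance(cfg, "challenge", rundir, alpha=cfg.alpha,
                      windows={"baseline": cfg.baseline_window_min,
                               "early": cfg.early_window_min,
                               "late": cfg.late_window_min})


def stage_report(cfg: PipelineConfig, rundir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    out = rundir / "report"
    out.mkdir(parents=True, exist_ok=True)
    mc_paths = _subject_paths(rundir, "connectome", "sub-*_mc.tsv")
    if not mc_paths:
        raise FileNotFoundError("missing connectomes; run stage 'connectome' first")
    mc = [mio.load_connectome(p, modality="PET") for p in mc_paths]
    fc = [mio.load_connectome(p, modality="BOLD")
          for p in _subject_paths(rundir, "connectome", "sub-*_fc.tsv")]
    summary: dict = {"n_subjects": len(mc)}
    g_mc = group_connectome(mc, alpha=cfg.alpha)
    summary["mc_mean_edge_z"] = float(g_mc.edges().mean())
    if fc:
        g_fc = group_connectome(fc, alpha=cfg.alpha)
        summary["mc_fc_edge_similarity_r"] = edge_similarity(g_mc, g_fc)
    # early/late similarity and sliding-window stability, per modality
    bps = [mio.load_bpseries(p) for p in _subject_paths(rundir, "bp", "sub-*_bp.tsv")]
    early = group_connectome([subject_connectome(b.as_timeseries(),
                                                 window_min=(20.0, 40.0))
                              for b in bps], alpha=cfg.alpha)
    late = group_connectome([subject_connectome(b.as_timeseries(),
                                                window_min=(60.0, 80.0))
                             for b in bps], alpha=cfg.alpha)
    summary["mc_early_late_similarity_r"] = edge_similarity(early, late)
    window_sims = []
    for bp in bps:
        wins = sliding_window_connectomes(bp.as_timeseries(),
                                          window_len_min=cfg.window_len_min,
                                          start_min=cfg.window_start_min,
                                          end_min=cfg.window_end_min,
                                          step_min=cfg.window_step_min)
        window_sims.append([edge_similarity(wins[k], wins[k + 1])
                            for k in range(len(wins) - 1)])
    summary["mc_window_similarity_mean_r"] = float(np.mean(window_sims))
    graph_tests = rundir / "graph" / "group_tests.json"
    if graph_tests.exists():
        summary["small_world"] = json.loads(graph_tests.read_text())

    fig, axes = plt.subplots(2, 2, figsize=(10, 8))
    im = axes[0, 0].imshow(g_mc.thresholded_mean_z(), cmap="RdBu_r", vmin=-1, vmax=1)
    axes[0, 0].set_title("Group MC (FWE-thresholded mean z)")
    fig.colorbar(im, ax=axes[0, 0])
    if fc:
        axes[0, 1].scatter(g_fc.edges(), g_mc.edges(), s=4, alpha=0.4)
        axes[0, 1].set_xlabel("FC edge z")
        axes[0, 1].set_ylabel("MC edge z")
        axes[0, 1].set_title("MC vs FC edges")
    axes[1, 0].scatter(early.edges(), late.edges(), s=4, alpha=0.4)
    axes[1, 0].set_title(f"Early vs late MC "
                         f"(r={summary['mc_early_late_similarity_r']:.2f})")
    for sims in window_sims:
        axes[1, 1].plot(sims, color="gray", alpha=0.4)
    axes[1, 1].set_title("Window-to-window MC similarity")
    axes[1, 1].set_xlabel("window pair")
    axes[1, 1].set_ylabel("r")
    fig.tight_layout()
    fig.savefig(out / "overview.png", dpi=100)
    plt.close(fig)
    for key, val in summary.items():
        if isinstance(val, float) and not np.isfinite(val):
            raise ValueError(f"non-finite summary value for {key}")
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    _write_provenance(cfg, "report", rundir)


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "extract": stage_extract,
    "bp": stage_bp,
    "connectome": stage_connectome,
    "graph": stage_graph,
    "ica": stage_ica,
    "challenge": stage_challenge,
    "report": stage_report,
}


def run_pipeline(cfg: PipelineConfig, outdir, stages=None) -> Path:
    """Execute the requested stages in dependency order; returns the run dir."""
    rundir = Path(outdir)
    rundir.mkdir(parents=True, exist_ok=True)
    if stages is None:
        stages = ["simulate", "extract", "bp", "connectome", "graph", "report"]
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    ordered = [s for s in STAGES if s in set(stages)]
    (rundir / "config.yaml").write_text(yaml.safe_dump(cfg.to_dict()))
    for stage in ordered:
        logger.info("running stage %s", stage)
        _STAGE_FUNCS[stage](cfg, rundir)
    return rundir
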