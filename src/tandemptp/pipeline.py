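"""End-to-end pipeline orchestration with a reproducibility report.

Stages run in dependency order (simulate -> kinetics -> binding -> traj
-> network) in a single process; every stage writes plain files into the
output directory so stages can be re-run and diffed independently. The
JSON report records the package version, a hash of the resolved
configuration, all seeds, per-stage status and every output file — two
runs with the same configuration produce byte-identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from tandemptp import __version__
from tandemptp.annotations import demo_firs, demo_motifs, load_firs, load_motifs
from tandemptp.binding import fit_sensogram_kinetics, fit_site_binding
from tandemptp.contacts import compute_contact_matrix
from tandemptp.kinetics import fit_michaelis_menten
from tandemptp.network import build_network, export_graph, extract_fir_subnetwork, find_clusters
from tandemptp.sasa import compute_buried_surface
from tandemptp.synthetic import (
    MMDatasetSpec,
    SensogramSpec,
    TitrationSpec,
    TrajectorySpec,
    generate_mm_dataset,
    generate_sensogram,
    generate_titration,
    generate_two_domain_trajectory,
)
from tandemptp.trajectory import (
    compute_centroid_distance,
    compute_rmsf,
    motif_rmsf_summary,
    read_trajectory_pdb,
    superpose,
)

log = logging.getLogger("tandemptp.pipeline")

ALL_STAGES = ("simulate", "kinetics", "binding", "traj", "network")


@dataclass
class PipelineConfig:
    """Resolved pipeline configuration (all defaults give a runnable demo
    over synthetic data)."""

    outdir: str = "pipeline_out"
    seed: int = 0
    stages: tuple = ALL_STAGES
    # synthetic truth values
    mm_vmax: float = 20.56          # µmol/min/mg
    mm_km: float = 2.0              # mM
    mm_noise_cv: float = 0.02
    spr_sites: tuple = ((74.7, 65.4e-4, 100.0), (2.88e4, 540e-4, 60.0))
    spr_concs: tuple = (50e-6, 150e-6, 300e-6, 500e-6, 700e-6)
    spr_noise_sd: float = 1.6       # 1% of total Rmax
    titration_sites: tuple = ((100.0, 40.0), (800.0, 30.0))  # µM
    traj_frames: int = 120
    traj_separation_nm: float = 3.74
    traj_separation_sd_nm: float = 0.1
    traj_jitter_sd: float = 0.4
    # analysis parameters
    cutoff: float = 5.0
    window: tuple | None = None
    probe_radius: float = 1.4
    sasa_points: int = 240
    sasa_frames: int = 5
    motifs_path: str | None = None
    firs_path: str | None = None

    def validate(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        for path in (self.motifs_path, self.firs_path):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"configured file does not exist: {path}")

    def config_hash(self) -> str:
        doc = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(doc.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(doc) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        for key in ("stages", "spr_sites", "spr_concs", "titration_sites", "window"):
            if key in doc and doc[key] is not None:
                doc[key] = tuple(
                    tuple(x) if isinstance(x, list) else x for x in doc[key]
                )
        return cls(**doc)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the requested stages and return the reproducibility report.

    A stage failure aborts the run; the report retains the completed
    stages, flags the failing one with its error, and is still written to
    ``report.json`` so partial outputs stay accounted for.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "stages": {},
        "outputs": [],
    }
    state: dict = {}
    handlers = {
        "simulate": _stage_simulate,
        "kinetics": _stage_kinetics,
        "binding": _stage_binding,
        "traj": _stage_traj,
        "network": _stage_network,
    }
    ok = True
    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        t0 = time.time()
        log.info("stage %s: starting", stage)
        try:
            outputs = handlers[stage](config, outdir, state)
        except Exception as exc:  # noqa: BLE001 - report and abort
            report["stages"][stage] = {"status": "failed", "error": str(exc)}
            log.error("stage %s failed: %s", stage, exc)
            ok = False
            break
        report["stages"][stage] = {
            "status": "ok",
            "seconds": round(time.time() - t0, 3),
            "outputs": [str(p) for p in outputs],
        }
        report["outputs"].extend(str(p) for p in outputs)
    report["status"] = "ok" if ok else "failed"
    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, default=str))
    if not ok:
        failed = [s for s, r in report["stages"].items() if r["status"] == "failed"]
        raise RuntimeError(f"pipeline aborted at stage {failed[0]!r}; see {report_path}")
    return report


def _spawn_seed(base: int, idx: int) -> int:
    return int(np.random.SeedSequence(base).spawn(idx + 1)[idx].generate_state(1)[0] % (2**31))


def _stage_simulate(cfg: PipelineConfig, outdir: Path, state: dict) -> list[Path]:
    concs = list(np.geomspace(0.05 * cfg.mm_km, 20 * cfg.mm_km, 12))
    mm = generate_mm_dataset(
        MMDatasetSpec(
            vmax=cfg.mm_vmax, km=cfg.mm_km, substrate_concs=concs,
            replicates=3, noise_cv=cfg.mm_noise_cv, seed=_spawn_seed(cfg.seed, 0),
        )
    )
    spr = generate_sensogram(
        SensogramSpec(
            sites=list(cfg.spr_sites), analyte_concs=list(cfg.spr_concs),
            noise_sd=cfg.spr_noise_sd, seed=_spawn_seed(cfg.seed, 1),
        )
    )
    tit = generate_titration(
        TitrationSpec(
            sites=list(cfg.titration_sites),
            ligand_concs=list(np.geomspace(1.0, 5000.0, 16)),
            noise_cv=0.01, seed=_spawn_seed(cfg.seed, 2),
        )
    )
    traj_path = outdir / "trajectory.pdb"
    generate_two_domain_trajectory(
        TrajectorySpec(
            n_frames=cfg.traj_frames,
            centroid_separation_mean=cfg.traj_separation_nm,
            centroid_separation_sd=cfg.traj_separation_sd_nm,
            per_residue_jitter_sd=cfg.traj_jitter_sd,
            seed=_spawn_seed(cfg.seed, 3),
        ),
        pdb_path=traj_path,
    )
    paths = [outdir / "mm_assay.csv", outdir / "sensograms.csv", outdir / "titration.csv"]
    mm.to_csv(paths[0], index=False)
    spr.to_csv(paths[1], index=False)
    tit.to_csv(paths[2], index=False)
    state["paths"] = {"mm": paths[0], "spr": paths[1], "titration": paths[2], "pdb": traj_path}
    return paths + [traj_path]


def _require(state: dict, key: str, stage: str):
    paths = state.get("paths", {})
    if key not in paths:
        raise RuntimeError(f"stage {stage!r} requires the simulate stage outputs")
    return paths[key]


def _stage_kinetics(cfg: PipelineConfig, outdir: Path, state: dict) -> list[Path]:
    import pandas as pd

    assay = pd.read_csv(_require(state, "mm", "kinetics"))
    fit = fit_michaelis_menten(assay, km_to_molar=1e-3, molar_mass=35000.0)
    out = outdir / "mm_fit.json"
    out.write_text(json.dumps(fit.to_dict(), indent=2, default=float))
    return [out]


def _stage_binding(cfg: PipelineConfig, outdir: Path, state: dict) -> list[Path]:
    import pandas as pd

    spr = pd.read_csv(_require(state, "spr", "binding"))
    tit = pd.read_csv(_require(state, "titration", "binding"))
    kin = fit_sensogram_kinetics(spr, n_sites=2)
    eq = fit_site_binding(tit, n_sites=2)
    doc = {
        "spr": {
            "n_sites": kin.n_sites,
            "converged": kin.converged,
            "rss": kin.rss,
            "sites": [
                {"ka": s.ka, "kd": s.kd, "rmax": s.rmax, "kd_eq_M": s.kd_eq}
                for s in kin.sites
            ],
        },
        "titration": {
            "n_sites": eq.n_sites,
            "f0": eq.f0,
            "sites": [{"kd": kd, "amplitude": a} for kd, a in eq.sites],
            "model_comparison_p": eq.model_comparison_p,
        },
    }
    out = outdir / "binding_fits.json"
    out.write_text(json.dumps(doc, indent=2, default=float))
    return [out]


def _load_annotations(cfg: PipelineConfig):
    motifs = load_motifs(cfg.motifs_path) if cfg.motifs_path else demo_motifs(30)
    firs = load_firs(cfg.firs_path) if cfg.firs_path else demo_firs()
    return motifs, firs


def _stage_traj(cfg: PipelineConfig, outdir: Path, state: dict) -> list[Path]:
    traj = read_trajectory_pdb(_require(state, "pdb", "traj"))
    fitted = superpose(traj)
    profile = compute_rmsf(fitted)
    motifs, _ = _load_annotations(cfg)
    motif_table = motif_rmsf_summary(profile, motifs)
    geometry = compute_centroid_distance(traj)
    cm = compute_contact_matrix(traj, cutoff=cfg.cutoff, window=cfg.window)
    sasa = compute_buried_surface(
        traj, probe=cfg.probe_radius, n_points=cfg.sasa_points,
        frames=np.linspace(0, traj.n_frames - 1, min(cfg.sasa_frames, traj.n_frames)).astype(int),
    )
    import pandas as pd

    outs = []
    p = outdir / "rmsf_per_residue.csv"
    pd.DataFrame(
        {
            "residue": profile.residues["residue"],
            "chain": profile.residues["chain"],
            "res_id": profile.residues["res_id"],
            "rmsf_all_atom": profile.per_residue,
            "rmsf_ca": profile.per_ca,
        }
    ).to_csv(p, index=False)
    outs.append(p)
    p = outdir / "motif_rmsf.csv"
    motif_table.to_csv(p, index=False)
    outs.append(p)
    p = outdir / "contact_matrix.tsv"
    cm.to_tsv(p)
    outs.append(p)
    p = outdir / "geometry.json"
    p.write_text(
        json.dumps(
            {
                "centroid_mean_nm": geometry.mean_nm,
                "centroid_sd_nm": geometry.sd_nm,
                "sasa_domain": sasa["sasa_domain"],
                "sasa_complex": sasa["sasa_complex"],
                "buried_area_A2": sasa["buried_area"],
            },
            indent=2,
        )
    )
    outs.append(p)
    state["contact_matrix"] = cm
    return outs


def _stage_network(cfg: PipelineConfig, outdir: Path, state: dict) -> list[Path]:
    cm = state.get("contact_matrix")
    if cm is None:
        raise RuntimeError("stage 'network' requires the traj stage outputs")
    motifs, firs = _load_annotations(cfg)
    net = build_network(cm, motifs=motifs, firs=None)
    outs = []
    p = outdir / "network.graphml"
    export_graph(net, p, format="graphml")
    outs.append(p)
    p = outdir / "network.sif"
    export_graph(net, p, format="sif")
    outs.append(p)
    # FIR analysis only over the first pseudo-domain (chain A residues)
    sub_net = build_network(cm, motifs=motifs, firs=firs)
    sub = extract_fir_subnetwork(sub_net, firs)
    clusters = find_clusters(sub)
    p = outdir / "fir_clusters.csv"
    clusters.to_csv(p, index=False)
    outs.append(p)
    return outs
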