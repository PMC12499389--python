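"""Config-driven orchestration: simulate -> slopes -> gam -> cluster -> spin -> ssyi.

Each stage reads its inputs from the run directory (TSV + JSON sidecars,
NIfTI-1 volumes) and writes its outputs there, so any stage can be re-run
on externally supplied files in the same schemas.  A manifest records the
full configuration, a content hash of every output and an overall run
hash; reruns with the same config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering, cohort, gam, spectral, spin, ssyi

log = logging.getLogger("boldslope")

_FLOAT_FMT = "%.10g"

STAGES = ("simulate", "slopes", "gam", "cluster", "spin", "ssyi")


@dataclass
class PipelineConfig:
    """All stage parameters with their reference defaults."""

    seed: int = 0
    n_subjects: int = 200
    age_range: tuple[float, float] = (18.0, 88.0)
    n_parcels: int = 100
    n_frames: int = 261
    tr: float = 1.97
    frac_cluster2: float = 0.30
    onset_age: float = 50.0
    outlier_frac: float = 0.10
    noise_floor: float = 0.1
    slope_effect_frac: float = 0.10
    lesion_effect: float = 10.0
    censor_rate: float = 0.10

    band: tuple[float, float] = spectral.DEFAULT_BAND
    n_freq: int = spectral.DEFAULT_N_FREQ

    gam_k: int = 4
    age_grid: tuple[float, float, int] = (20.0, 85.0, 66)
    fdr_alpha: float = 0.05
    exclude_parcels: tuple[int, ...] = ()

    fuzzifier: float = 5.0
    max_iter: int = 10000
    tol: float = 1e-5
    cluster_candidates: tuple[int, ...] = tuple(range(2, 16))

    n_rotations: int = 10000

    vlsm_alpha: float = 0.05
    mad_k: float = 3.0
    ss_reference_cutoff: float = 45.0
    atlas_cutoff: float = 40.0
    regression_min_age: float = 45.0

    stages: tuple[str, ...] = STAGES

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        data.update(overrides)
        cfg = cls(**data)
        return cfg

    def cohort_spec(self) -> cohort.CohortSpec:
        return cohort.CohortSpec(
            n_subjects=self.n_subjects,
            age_range=tuple(self.age_range),
            n_parcels=self.n_parcels,
            n_frames=self.n_frames,
            tr=self.tr,
            seed=self.seed,
            frac_cluster2=self.frac_cluster2,
            onset_age=self.onset_age,
            outlier_frac=self.outlier_frac,
            noise_floor=self.noise_floor,
            slope_effect_frac=self.slope_effect_frac,
            lesion_effect=self.lesion_effect,
            censor_rate=self.censor_rate,
        )

    def age_grid_array(self) -> np.ndarray:
        lo, hi, n = self.age_grid
        return np.linspace(lo, hi, int(n))

    def canonical(self) -> str:
        d = asdict(self)
        return json.dumps(d, sort_keys=True, default=list)


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)


def _write_nifti(data: np.ndarray, affine: np.ndarray, path: Path) -> None:
    import nibabel as nib

    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    img.to_filename(str(path))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: PipelineConfig, run: Path) -> dict:
    spec = cfg.cohort_spec()
    out = run / "cohort"
    (out / "timeseries").mkdir(parents=True, exist_ok=True)
    (out / "t2w").mkdir(exist_ok=True)

    subjects = cohort.generate_subject_table(spec)
    geometry = cohort.generate_parcel_geometry(spec)
    traj = cohort.assign_trajectories(spec, geometry)
    metabolic = cohort.generate_metabolic_maps(geometry, traj, spec)
    _write_tsv(subjects, out / "subjects.tsv")
    _write_tsv(geometry, out / "geometry.tsv")
    _write_tsv(traj, out / "trajectories.tsv")
    _write_tsv(metabolic, out / "metabolic.tsv")

    series = cohort.generate_cohort_timeseries(spec, subjects, traj, geometry)
    for sid, (values, valid) in series.items():
        df = pd.DataFrame(values, columns=geometry["parcel_id"].to_numpy())
        _write_tsv(df, out / "timeseries" / f"{sid}.tsv")
        sidecar = {"tr_seconds": spec.tr, "valid_mask": valid.astype(int).tolist()}
        (out / "timeseries" / f"{sid}.json").write_text(
            json.dumps(sidecar, sort_keys=True)
        )

    t2w = cohort.generate_t2w_volumes(subjects, spec)
    for i, sid in enumerate(t2w.subject_ids):
        _write_nifti(t2w.volumes[i], t2w.affine, out / "t2w" / f"{sid}.nii")
    _write_nifti(t2w.roi_mask.astype(np.float32), t2w.affine, out / "t2w" / "flwm_mask.nii")
    _write_nifti(t2w.atlas_mean, t2w.affine, out / "t2w" / "atlas_mean.nii")
    _write_nifti(t2w.atlas_sd, t2w.affine, out / "t2w" / "atlas_sd.nii")
    return {"n_subjects": len(subjects), "n_parcels": len(geometry)}


def _load_geometry(run: Path) -> pd.DataFrame:
    return pd.read_csv(run / "cohort" / "geometry.tsv", sep="\t")


def _load_subjects(run: Path) -> pd.DataFrame:
    return pd.read_csv(run / "cohort" / "subjects.tsv", sep="\t")


def stage_slopes(cfg: PipelineConfig, run: Path) -> dict:
    geometry = _load_geometry(run)
    subjects = _load_subjects(run)
    nonmed = ~geometry["medial_wall"].to_numpy(dtype=bool)
    pids = geometry["parcel_id"].to_numpy()[nonmed]
    out = run / "slopes"
    out.mkdir(exist_ok=True)
    rows = {}
    for sid in subjects["subject_id"]:
        ts_path = run / "cohort" / "timeseries" / f"{sid}.tsv"
        side = json.loads((run / "cohort" / "timeseries" / f"{sid}.json").read_text())
        values = pd.read_csv(ts_path, sep="\t").to_numpy(dtype=float)
        valid = np.asarray(side["valid_mask"], dtype=bool)
        try:
            ss, r2 = spectral.estimate_ss_matrix(
                values[:, nonmed],
                side["tr_seconds"],
                valid,
                band=tuple(cfg.band),
                n_freq=cfg.n_freq,
            )
        except ValueError as exc:
            raise RuntimeError(f"stage slopes failed for subject {sid}: {exc}") from exc
        rows[sid] = ss
    maps = pd.DataFrame(rows).T
    maps.columns = pids
    maps.index.name = "subject_id"
    _write_tsv(maps, out / "ss_maps.tsv", index=True)
    return {"n_maps": len(maps)}


def _load_ss_maps(run: Path) -> pd.DataFrame:
    maps = pd.read_csv(run / "slopes" / "ss_maps.tsv", sep="\t", index_col="subject_id")
    maps.columns = maps.columns.astype(int)
    return maps


def stage_gam(cfg: PipelineConfig, run: Path) -> dict:
    maps = _load_ss_maps(run)
    subjects = _load_subjects(run)
    cov = subjects.set_index("subject_id").loc[maps.index, ["age", "sex", "head_motion"]]
    keep = [p for p in maps.columns if p not in set(cfg.exclude_parcels)]
    tab = gam.fit_parcel_gams(
        maps[keep], cov.reset_index(drop=True), cfg.age_grid_array(), k=cfg.gam_k
    )
    fdr = gam.fdr_correct(tab.results["p_age"].to_numpy(), alpha=cfg.fdr_alpha)
    fdr.index = tab.results.index
    out = run / "gam"
    out.mkdir(exist_ok=True)
    res = tab.results.copy()
    res["q"] = fdr["q"]
    res["significant"] = fdr["significant"]
    _write_tsv(res, out / "results.tsv", index=True)
    curves = gam.trajectory_curves(tab, fdr)
    _write_tsv(curves, out / "trajectories.tsv", index=True)
    return {"n_parcels_fit": len(res), "n_significant": int(fdr["significant"].sum())}


def stage_cluster(cfg: PipelineConfig, run: Path) -> dict:
    curves = pd.read_csv(run / "gam" / "trajectories.tsv", sep="\t", index_col=0)
    curves.index = curves.index.astype(int)
    geometry = _load_geometry(run).set_index("parcel_id")
    X = curves.to_numpy(dtype=float)
    sel = clustering.silhouette_select(
        X,
        candidates=tuple(cfg.cluster_candidates),
        seed=cfg.seed,
        fuzzifier=cfg.fuzzifier,
        max_iter=cfg.max_iter,
        tol=cfg.tol,
    )
    m = sel.memberships[sel.chosen_n]
    out = run / "cluster"
    out.mkdir(exist_ok=True)
    u = pd.DataFrame(
        m.u,
        index=pd.Index(curves.index, name="parcel_id"),
        columns=[f"cluster{i + 1}" for i in range(m.u.shape[1])],
    )
    _write_tsv(u, out / "membership.tsv", index=True)
    labels = pd.DataFrame(
        {"label": m.labels + 1, "tie": m.tie_flags},
        index=pd.Index(curves.index, name="parcel_id"),
    )
    _write_tsv(labels, out / "labels.tsv", index=True)
    (out / "selection.json").write_text(
        json.dumps(
            {
                "candidate_n": list(sel.candidate_n),
                "silhouette": [round(float(s), 10) for s in sel.silhouette],
                "chosen_n": sel.chosen_n,
            },
            sort_keys=True,
        )
    )
    rsn_cols = [c for c in geometry.columns if c.startswith("rsn_")]
    rsn = clustering.rsn_correspondence_index(m, geometry.loc[curves.index, rsn_cols])
    _write_tsv(rsn, out / "rsn_index.tsv", index=True)
    return {"chosen_n": sel.chosen_n, "n_clustered": len(curves)}


def stage_spin(cfg: PipelineConfig, run: Path) -> dict:
    res = pd.read_csv(run / "gam" / "results.tsv", sep="\t", index_col="parcel_id")
    metabolic = pd.read_csv(run / "cohort" / "metabolic.tsv", sep="\t").set_index("parcel_id")
    geometry = _load_geometry(run)
    a = res["delta_r2"]
    b = metabolic["cmrglc"]
    result = spin.spin_pvalue(
        a, b, geometry, n_rotations=cfg.n_rotations, seed=cfg.seed
    )
    out = run / "spin"
    out.mkdir(exist_ok=True)
    (out / "spin.json").write_text(
        json.dumps(
            {
                "rho": round(result.rho, 10),
                "p_spin": round(result.p_spin, 10),
                "n_rotations": result.n_rotations,
                "seed": result.seed,
            },
            sort_keys=True,
        )
    )
    _write_tsv(
        pd.DataFrame({"null_rho": result.null_corrs}), out / "null_corrs.tsv"
    )
    return {"rho": result.rho, "p_spin": result.p_spin}


def stage_ssyi(cfg: PipelineConfig, run: Path) -> dict:
    import nibabel as nib

    maps = _load_ss_maps(run)
    subjects = _load_subjects(run)
    ref = ssyi.young_reference_map(maps, subjects, cutoff=cfg.ss_reference_cutoff)
    vals = np.array(
        [ssyi.compute_ssyi(maps.loc[sid], ref) for sid in maps.index]
    )
    flags = ssyi.mad_outliers(vals, k=cfg.mad_k)

    atlas_mean = nib.load(run / "cohort" / "t2w" / "atlas_mean.nii").get_fdata()
    atlas_sd = nib.load(run / "cohort" / "t2w" / "atlas_sd.nii").get_fdata()
    affine = nib.load(run / "cohort" / "t2w" / "atlas_mean.nii").affine
    norm = np.stack(
        [
            ssyi.normalize_t2w(
                nib.load(run / "cohort" / "t2w" / f"{sid}.nii").get_fdata(),
                atlas_mean,
                atlas_sd,
            )
            for sid in maps.index
        ]
    )
    rvol, mask, _ = ssyi.voxelwise_ssyi_correlation(norm, vals, alpha=cfg.vlsm_alpha)
    # restrict the representative ROI to negatively correlated significant voxels
    roi = mask & (np.nan_to_num(rvol) < 0)
    if not roi.any():
        roi = mask
    flwm = np.array([ssyi.roi_mean_intensity(norm[i], roi) for i in range(len(vals))])

    out = run / "ssyi"
    out.mkdir(exist_ok=True)
    table = subjects.set_index("subject_id").loc[maps.index].reset_index()
    table["ssyi"] = vals
    table["outlier_flag"] = flags
    table["flwm_t2w"] = flwm
    _write_tsv(
        table[
            ["subject_id", "ssyi", "outlier_flag", "age", "sex", "head_motion", "gmv", "flwm_t2w"]
        ],
        out / "ssyi.tsv",
    )
    _write_nifti(np.nan_to_num(rvol), affine, out / "correlation.nii")
    _write_nifti(mask.astype(np.float32), affine, out / "sig_mask.nii")

    reg = ssyi.outlier_regression(table, min_age=cfg.regression_min_age)
    (out / "regression.json").write_text(
        json.dumps(
            {
                "terms": {
                    t: {
                        "estimate": round(float(r["estimate"]), 10),
                        "se": round(float(r["se"]), 10),
                        "p": round(float(r["p"]), 12),
                    }
                    for t, r in reg.coefficients.iterrows()
                },
                "n_used": reg.n_used,
            },
            sort_keys=True,
        )
    )
    return {"n_outliers": int(flags.sum()), "n_regression": reg.n_used}


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "slopes": stage_slopes,
    "gam": stage_gam,
    "cluster": stage_cluster,
    "spin": stage_spin,
    "ssyi": stage_ssyi,
}


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute the enabled stages in order and write the manifest."""
    run = Path(out_dir)
    run.mkdir(parents=True, exist_ok=True)
    counts: dict[str, dict] = {}
    for name in STAGES:
        if name not in cfg.stages:
            log.info("stage %s disabled", name)
            continue
        log.info("running stage %s", name)
        try:
            counts[name] = _STAGE_FUNCS[name](cfg, run)
        except Exception as exc:
            raise RuntimeError(f"stage '{name}' failed: {exc}") from exc

    files = sorted(
        str(p.relative_to(run))
        for p in run.rglob("*")
        if p.is_file() and p.name != "manifest.json"
    )
    hashes = {f: _sha256(run / f) for f in files}
    overall = hashlib.sha256(
        (cfg.canonical() + json.dumps(hashes, sort_keys=True)).encode()
    ).hexdigest()
    manifest = {
        "config": json.loads(cfg.canonical()),
        "stage_counts": counts,
        "files": hashes,
        "run_hash": overall,
    }
    (run / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
    return run


def write_report(run_dir: str | Path) -> dict:
    """Machine-readable summary of a completed run."""
    run = Path(run_dir)
    manifest_path = run / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError("run has no manifest; did the pipeline complete?")
    manifest = json.loads(manifest_path.read_text())
    done = set(manifest["stage_counts"])
    report: dict = {"run_hash": manifest["run_hash"]}
    if "gam" in done:
        res = pd.read_csv(run / "gam" / "results.tsv", sep="\t")
        report["frac_parcels_significant"] = float(res["significant"].mean())
        report["delta_r2_range"] = [float(res["delta_r2"].min()), float(res["delta_r2"].max())]
    if "cluster" in done:
        report["chosen_n"] = json.loads((run / "cluster" / "selection.json").read_text())[
            "chosen_n"
        ]
    if "spin" in done:
        report.update(json.loads((run / "spin" / "spin.json").read_text()))
    if "ssyi" in done:
        tab = pd.read_csv(run / "ssyi" / "ssyi.tsv", sep="\t")
        report["n_outliers"] = int(tab["outlier_flag"].sum())
        report["regression"] = json.loads((run / "ssyi" / "regression.json").read_text())
    (run / "report.json").write_text(json.dumps(report, sort_keys=True, indent=1))
    return report
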