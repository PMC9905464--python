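"""End-to-end synthetic study: cohort -> acquisition -> both reconstruction
arms -> VOIs -> dosimetry -> comparison metrics -> report bundle.

Both arms (conventional "3D" and motion-compensated "3Dcomp") consume the
same list-mode data, so per-patient differences isolate the reconstruction
method.  Ground-truth doses are computed from the true activity map with the
same dose engine, which the synthetic design makes available.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from mocospect import dose as dose_mod
from mocospect import metrics as metrics_mod
from mocospect.acquisition import AcquisitionSpec, acquire_listmode, expected_phase_projections
from mocospect.phantom import (
    LABEL_LIVER,
    LABEL_LUNG,
    LABEL_TUMOR,
    CohortConfig,
    Phantom4D,
    PhantomSpec,
    generate_phase_set,
    sample_cohort,
)
from mocospect.recon import (
    ReconConfig,
    reconstruct_3d,
    reconstruct_3dcomp,
    reconstruct_gated_4d,
)
from mocospect.respiratory import (
    assign_phases,
    laplacian_eigenmap_signal,
    rebin_listmode_features,
    select_reference_phase,
)
from mocospect.voi import VOISet, derive_vois, perfused_liver

VOI_NAMES = ("liver", "lungs", "tumor", "PL", "HR", "HPL", "HL")


@dataclass
class RunConfig:
    """Study configuration; the default is the desk-scale preset."""

    n_patients: int = 10
    seed: int = 0
    out_dir: str | None = None
    n_phases: int = 8
    target_events: float = 2.0e6
    injected_gbq: float = 1.6
    prescription_gy: float = 120.0
    dose_engine: str = "kernel"
    resp_dt_s: float = 0.5
    resp_coarse: tuple[int, int] = (16, 16)
    resp_k_neighbors: int = 20
    affine_registration: bool = True
    ct_phase: int | None = None  # None: seeded random phase per patient
    cohort: CohortConfig = field(default_factory=CohortConfig)
    acquisition: AcquisitionSpec = field(default_factory=AcquisitionSpec)
    recon: ReconConfig = field(default_factory=lambda: ReconConfig(15, 15))
    gated_recon: ReconConfig = field(default_factory=lambda: ReconConfig(8, 4))


def desk_config(**overrides) -> RunConfig:
    """Small, fast preset: 32^3 grid / 6 mm voxels, 24 projections, 4 phases."""
    cfg = RunConfig(
        n_phases=4,
        target_events=1.5e6,
        cohort=CohortConfig(grid_shape=(32, 32, 32), spacing_mm=(6.0, 6.0, 6.0)),
        acquisition=AcquisitionSpec(n_projections=24, time_per_projection_s=25.0),
        recon=ReconConfig(6, 5),
        gated_recon=ReconConfig(6, 3),
        resp_coarse=(8, 8),
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


def paper_config(**overrides) -> RunConfig:
    """Full-scale preset mirroring the clinical acquisition geometry."""
    cfg = RunConfig(
        n_phases=8,
        target_events=2.0e7,
        cohort=CohortConfig(grid_shape=(128, 128, 128), spacing_mm=(4.41806,) * 3),
        acquisition=AcquisitionSpec(n_projections=60, time_per_projection_s=25.0),
        recon=ReconConfig(15, 15),
        gated_recon=ReconConfig(15, 5),
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


@dataclass
class PatientResult:
    """Flat record of everything the comparison layer needs for one patient."""

    patient: int
    spec: PhantomSpec
    record: dict
    failure_stage: str | None = None


def _phantom_masks(phantom: Phantom4D, phase: int):
    labels = phantom.phases[phase].labels
    liver = (labels == LABEL_LIVER) | (labels == LABEL_TUMOR)
    lungs = labels == LABEL_LUNG
    from scipy import ndimage

    lab, n = ndimage.label(labels == LABEL_TUMOR)
    lesions = [lab == i for i in range(1, n + 1)]
    return liver, lungs, lesions


def _arm_dosimetry(recon, vois: VOISet, cfg: RunConfig):
    act = dose_mod.calibrate_activity(recon, vois, cfg.injected_gbq * 1e9)
    rate = dose_mod.dose_rate(act, engine=cfg.dose_engine)
    dmap = dose_mod.integrate_decay(rate)
    doses = {}
    for name, mask in vois.masks().items():
        doses[name] = dose_mod.mean_dose(dmap, mask) if mask.any() else np.nan
    return act, dmap, doses


def run_patient(spec: PhantomSpec, cfg: RunConfig, patient_id: int = 0) -> PatientResult:
    """Run one phantom through acquisition, both arms, VOIs and dosimetry."""
    rec: dict = {"patient": patient_id}
    stage = "phantom"
    try:
        rng = np.random.default_rng((cfg.seed, spec.seed, patient_id))
        phantom = generate_phase_set(spec, cfg.n_phases)
        grid = phantom.grid
        acq = cfg.acquisition
        projector = acq.projector(grid)

        stage = "acquisition"
        primary, scatter = expected_phase_projections(phantom, acq, projector)
        dwell = acq.time_per_projection_s / cfg.n_phases
        expected_total = (primary.sum() + scatter.sum()) * dwell
        scale = cfg.target_events / max(expected_total, 1e-30)
        lm = acquire_listmode(
            phantom, acq, seed=int(rng.integers(2**31)),
            projector=projector, expected=(primary * scale, scatter * scale),
        )
        rec["n_events"] = len(lm)

        # the "CT" is acquired at a seeded (or pinned) phase of the cycle
        ct_phase = (
            int(rng.integers(cfg.n_phases)) if cfg.ct_phase is None else cfg.ct_phase
        )
        mu_ct = phantom.phases[ct_phase].attenuation
        rec["ct_phase"] = ct_phase

        stage = "recon_3d"
        recon3d = reconstruct_3d(lm, mu_ct, projector, cfg.recon)

        stage = "respiratory_signal"
        feats = rebin_listmode_features(lm, cfg.resp_dt_s, cfg.resp_coarse)
        sig = laplacian_eigenmap_signal(feats, cfg.resp_k_neighbors)
        labels_ev, sig = assign_phases(sig, feats, cfg.n_phases)
        rec["signal_degenerate"] = bool(sig.degenerate)
        rec["quantile_fallback"] = bool(sig.quantile_fallback)

        stage = "gated_recon"
        gated = reconstruct_gated_4d(lm, labels_ev, mu_ct, projector, cfg.gated_recon)
        ref, scores = select_reference_phase([g.values for g in gated], mu_ct)
        rec["reference_phase"] = ref
        rec["reference_scores"] = [float(s) for s in scores]

        stage = "recon_3dcomp"
        recon3dc = reconstruct_3dcomp(
            lm, labels_ev, ref, mu_ct, projector, cfg.recon,
            affine=cfg.affine_registration,
        )
        rec["dropped_event_weight"] = recon3dc.meta.get("dropped_event_weight", 0.0)

        stage = "vois"
        liver, lungs, lesions = _phantom_masks(phantom, ct_phase)
        vois = {}
        for arm, recon in (("3D", recon3d), ("3Dcomp", recon3dc)):
            pl = perfused_liver(recon.values, liver)
            vois[arm] = derive_vois(liver, lungs, lesions, pl)

        stage = "dosimetry"
        vol_ml = grid.voxel_volume_ml
        doses = {}
        for arm, recon in (("3D", recon3d), ("3Dcomp", recon3dc)):
            vs = vois[arm]
            _, _, d = _arm_dosimetry(recon, vs, cfg)
            doses[arm] = d
            c_lungs = float(recon.values[vs.lungs].sum())
            c_liver = float(recon.values[vs.liver].sum())
            rec[f"lsf_{arm}"] = metrics_mod.lsf(c_lungs, c_liver)
            if vs.tumor.any() and vs.hl.any():
                rec[f"tn_{arm}"] = metrics_mod.tn_ratio(
                    float(recon.values[vs.tumor].sum()), vs.tumor.sum() * vol_ml,
                    float(recon.values[vs.hl].sum()), vs.hl.sum() * vol_ml,
                )
            dose_pl_per_gbq = d["PL"] / cfg.injected_gbq
            rec[f"activity_{arm}_gbq"] = dose_mod.prescribe_activity(
                dose_pl_per_gbq, cfg.prescription_gy
            )
            for name in VOI_NAMES:
                rec[f"dose_{name}_{arm}"] = d.get(name, np.nan)

        # ground truth from the true activity map at the CT phase
        true_recon = dataclasses.replace(
            recon3d, values=phantom.phases[ct_phase].activity.copy(), method="truth"
        )
        pl_true = perfused_liver(true_recon.values, liver)
        vois_true = derive_vois(liver, lungs, lesions, pl_true)
        _, _, d_true = _arm_dosimetry(true_recon, vois_true, cfg)
        for name in VOI_NAMES:
            rec[f"dose_{name}_true"] = d_true.get(name, np.nan)

        stage = "metrics"
        for name in VOI_NAMES:
            d3, dc = rec[f"dose_{name}_3D"], rec[f"dose_{name}_3Dcomp"]
            rec[f"pdd_{name}"] = (
                metrics_mod.pdd(dc, d3) if np.isfinite(d3) and d3 > 0 else np.nan
            )
        rec["pda"] = metrics_mod.pda(rec["activity_3Dcomp_gbq"], rec["activity_3D_gbq"])
        rec["amplitude_true_mm"] = float(
            np.linalg.norm(phantom.true_liver_translation_mm, axis=1).max()
        )
        rec["amplitude_spec_mm"] = float(
            np.linalg.norm(np.asarray(spec.motion_amplitude_mm))
        )

        # amplitude from extreme-phase gated reconstructions
        try:
            phase_amp = np.array([
                sig.amplitude[sig.phase_of_bin == p].mean() if np.any(sig.phase_of_bin == p) else np.nan
                for p in range(cfg.n_phases)
            ])
            inh, exh = int(np.nanargmax(phase_amp)), int(np.nanargmin(phase_amp))
            if inh != exh and gated[inh].values.any() and gated[exh].values.any():
                rec["amplitude_est_mm"] = metrics_mod.estimate_amplitude(
                    gated[inh].values, gated[exh].values, liver, grid.spacing
                )
            else:
                rec["amplitude_est_mm"] = np.nan
        except metrics_mod.AmplitudeNotEstimable:
            rec["amplitude_est_mm"] = np.nan

        if lesions:
            feats_t = metrics_mod.tumor_features(
                lesions[0], liver, grid.spacing,
                cc_amplitude_mm=abs(phantom.true_liver_translation_mm[:, 2]).max(),
            )
            for k, v in feats_t.items():
                rec[f"tumor_{k}"] = v

        return PatientResult(patient_id, spec, rec)
    except Exception as err:  # record partial results, never silently skip
        warnings.warn(f"patient {patient_id} failed at stage {stage}: {err}")
        rec["error"] = str(err)
        return PatientResult(patient_id, spec, rec, failure_stage=stage)


@dataclass
class CohortReport:
    table: pd.DataFrame
    stats: dict
    config: RunConfig
    figures: list = field(default_factory=list)


def run_cohort(cfg: RunConfig, specs: list[PhantomSpec] | None = None) -> CohortReport:
    """Run the whole synthetic study and aggregate tables, tests and figures."""
    if specs is None:
        specs = sample_cohort(cfg.n_patients, cfg.seed, cfg.cohort)
    if len(specs) < 1:
        raise ValueError("cohort must contain at least one patient")
    results = [run_patient(s, cfg, i) for i, s in enumerate(specs)]
    table = pd.DataFrame([r.record for r in results])
    table["failure_stage"] = [r.failure_stage for r in results]

    stats: dict = {"n_patients": len(specs)}
    ok = table[table["failure_stage"].isna()]
    if len(ok) >= 3:
        for name in VOI_NAMES:
            a = ok.get(f"dose_{name}_3Dcomp")
            b = ok.get(f"dose_{name}_3D")
            if a is None or b is None:
                continue
            mask = np.isfinite(a) & np.isfinite(b)
            if mask.sum() >= 3:
                stats[f"paired_{name}"] = metrics_mod.stats_suite(a[mask], b[mask])
        feat_cols = {
            c[len("tumor_"):]: ok[c].to_numpy()
            for c in ok.columns
            if c.startswith("tumor_")
        }
        if "pdd_tumor" in ok and np.isfinite(ok["pdd_tumor"]).sum() >= 3:
            stats["spearman_tumor_pdd"] = metrics_mod.spearman_screen(
                ok["pdd_tumor"].to_numpy(), feat_cols
            )
    else:
        stats["note"] = "fewer than 3 evaluable patients; paired tests skipped"

    figures = []
    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "cohort_table.csv", index=False)
        (out / "cohort_stats.json").write_text(
            json.dumps(stats, indent=2, default=_jsonable)
        )
        figures = make_figures(table, out)
    return CohortReport(table, stats, cfg, figures)


def _jsonable(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    return str(o)


def make_figures(table: pd.DataFrame, out_dir: Path) -> list[str]:
    """PDD boxplots (with contour counts annotated), Bland-Altman plots and
    PDD-vs-volume / PDD-vs-amplitude scatter plots."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths = []

    fig, ax = plt.subplots(figsize=(7, 4))
    data, names, counts = [], [], []
    for name in VOI_NAMES:
        col = table.get(f"pdd_{name}")
        if col is None:
            continue
        vals = col.dropna().to_numpy()
        if len(vals):
            data.append(vals)
            names.append(name)
            counts.append(len(vals))
    if data:
        ax.boxplot(data, tick_labels=names)
        for i, c in enumerate(counts):
            ax.annotate(str(c), (i + 1, ax.get_ylim()[1]), ha="center", va="top")
        ax.set_ylabel("PDD (%)")
        ax.axhline(0, color="gray", lw=0.5)
        p = out_dir / "fig_pdd_boxplot.png"
        fig.savefig(p, dpi=110)
        paths.append(str(p))
    plt.close(fig)

    for a_col, b_col, label, fname in (
        ("dose_lungs_3Dcomp", "dose_lungs_3D", "lung dose (Gy)", "fig_ba_lung_dose.png"),
        ("lsf_3Dcomp", "lsf_3D", "LSF (%)", "fig_ba_lsf.png"),
        ("tn_3Dcomp", "tn_3D", "TN ratio", "fig_ba_tn.png"),
    ):
        if a_col not in table or b_col not in table:
            continue
        a = table[a_col].to_numpy(dtype=float)
        b = table[b_col].to_numpy(dtype=float)
        ok = np.isfinite(a) & np.isfinite(b)
        if ok.sum() < 2:
            continue
        ba = metrics_mod.bland_altman(a[ok], b[ok])
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.scatter(ba.means, ba.diffs)
        for y, style in ((ba.mean_diff, "-"), (ba.loa_low, "--"), (ba.loa_high, "--")):
            ax.axhline(y, color="k", ls=style, lw=0.8)
        ax.set_xlabel(f"mean {label}")
        ax.set_ylabel(f"difference {label}")
        p = out_dir / fname
        fig.savefig(p, dpi=110)
        paths.append(str(p))
        plt.close(fig)

    for x_col, xlabel, fname in (
        ("tumor_volume_ml", "tumor volume (mL)", "fig_pdd_vs_volume.png"),
        ("amplitude_true_mm", "motion amplitude (mm)", "fig_pdd_vs_amplitude.png"),
    ):
        if x_col not in table or "pdd_tumor" not in table:
            continue
        x = table[x_col].to_numpy(dtype=float)
        y = table["pdd_tumor"].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        if not ok.any():
            continue
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.scatter(x[ok], y[ok])
        if x_col == "tumor_volume_ml":
            ax.set_xscale("log")
        ax.set_xlabel(xlabel)
        ax.set_ylabel("tumor PDD (%)")
        ax.axhline(0, color="gray", lw=0.5)
        p = out_dir / fname
        fig.savefig(p, dpi=110)
        paths.append(str(p))
        plt.close(fig)

    return paths
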