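"""End-to-end orchestration: simulate/read -> preprocess -> inverse -> ROI power
-> lagged coherence -> Granger -> PAC -> group inference, from a single config.

Every stage writes a CSV (with the config hash embedded in a header comment)
into the output directory; a stage whose output already exists for the same
config hash is loaded instead of recomputed.  A JSON summary collects the
group-level findings, including the parahippocampal loop report.

The loop report classifies directionality through a volume-conduction-aware
contrast: instantaneous leakage inflates both directions of a pair alike, so
per-direction comparison against controls overstates reverse links, while
the between-patient-group difference of the within-pair asymmetry
Delta_X = GC(PHC->X) - GC(X->PHC) isolates the genuinely directed part.
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
import pandas as pd
from scipy import stats as _st

from . import inference
from .granger import gc_table
from .headmodel import build_leadfield, make_solution_space
from .inverse import (roi_band_power_chunked, roi_timeseries_direct,
                      sloreta_operator, voxel_relative_band_power_fast)
from .lagged import lpc_table
from .pac import band_pc1, roi_pac_table
from .recording import MONTAGE_1020, common_average_reference, preprocess, read_recording
from .simulate import LOOP_ROIS, simulate_cohort
from .spectra import epoch_and_cross_spectra

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Flat, fully-seeded configuration of one pipeline run."""

    # cohort source: either a directory of recordings + manifest, or simulation
    input_dir: str | None = None
    n_per_group: int = 25
    duration_s: float = 300.0
    fs: float = 128.0
    noise_sd: float = 2.0
    jitter_cv: float = 0.2
    seed: int = 0
    # head model / inverse
    grid: str = "test"
    alpha: float | None = None
    # preprocessing / spectra
    band_lo: float = 2.0
    band_hi: float = 44.0
    epoch_len_s: float = 4.0
    taper: str = "hann"
    amp_reject_uv: float = 100.0
    # connectivity
    gc_band: str = "theta"
    gc_order: int = 5
    lpc_surrogates: int = 200
    pac_surrogates: int = 200
    # group stats
    n_perm: int = 1000
    alpha_level: float = 0.05
    z_thresh: float = 1.96
    whole_brain: bool = True
    out_dir: str = "srcconn_out"

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def write_table(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    """CSV with the config hash in a leading comment; 6 significant digits."""
    with open(path, "w") as fh:
        fh.write(f"# config_hash: {config_hash}\n")
        df.to_csv(fh, index=False, float_format="%.6g")


def read_table(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def _cached(path: Path, config_hash: str) -> pd.DataFrame | None:
    if not path.exists():
        return None
    with open(path) as fh:
        first = fh.readline()
    if config_hash in first:
        logger.info("reusing cached %s", path.name)
        return read_table(path)
    return None


@dataclass
class PipelineResult:
    config: PipelineConfig
    roi_power: pd.DataFrame
    lpc: pd.DataFrame
    gc: pd.DataFrame
    pac: pd.DataFrame
    summary: dict
    out_dir: Path
    voxel_power: pd.DataFrame | None = None


def _load_cohort_recordings(config: PipelineConfig):
    """Yield (subject_id, group, recording) from a saved cohort directory."""
    base = Path(config.input_dir)
    manifest = pd.read_csv(base / "manifest.csv")
    for _, row in manifest.iterrows():
        stem = base / str(row.subject_id)
        path = stem.with_suffix(".csv") if stem.with_suffix(".csv").exists() \
            else stem.with_suffix(".edf")
        yield str(row.subject_id), str(row.group), read_recording(path)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis chain and write the report bundle."""
    t_start = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    log_lines = [f"config_hash {chash}", f"seed {config.seed}"]
    config.to_yaml(out / "config.yaml")

    space = make_solution_space(config.grid)
    leadfield = build_leadfield(MONTAGE_1020, space, model="three_shell_sphere")
    operator = sloreta_operator(leadfield, alpha=config.alpha)

    if config.input_dir is not None:
        subjects = list(_load_cohort_recordings(config))
    else:
        cohort = simulate_cohort(
            n_per_group=config.n_per_group, duration_s=config.duration_s,
            fs=config.fs, seed=config.seed, leadfield=leadfield, space=space,
            noise_sd=config.noise_sd, jitter_cv=config.jitter_cv)
        subjects = [(s.subject_id, s.group, s.recording) for s in cohort.subjects]
    log_lines.append(f"subjects {len(subjects)}")

    cached = {name: _cached(out / f"{name}.csv", chash)
              for name in ("roi_power", "voxel_power", "lpc", "gc", "pac")}
    need_subject_pass = any(cached[n] is None for n in
                            ("roi_power", "lpc", "gc", "pac")) or (
        config.whole_brain and cached["voxel_power"] is None)

    roi_rows, vox_rows, lpc_frames, gc_frames, pac_frames = [], [], [], [], []
    if need_subject_pass:
        seed_rng = np.random.default_rng(config.seed + 1)
        for sid, group, rec in subjects:
            try:
                sub_seed = int(seed_rng.integers(0, 2**31 - 1))
                rec_p = preprocess(rec, config.band_lo, config.band_hi,
                                   fs_target=min(128.0, rec.fs))
                rec_p = common_average_reference(rec_p)
                # voxel/ROI relative power (ROI values are voxel values at
                # the ROI's single voxel, so one whole-brain pass serves both)
                if config.whole_brain:
                    rel = voxel_relative_band_power_fast(operator, rec_p)
                    for band, vals in rel.items():
                        vox_rows.append({"subject_id": sid, "group": group, "band": band,
                                         **{f"v{i}": float(np.log(x))
                                            for i, x in enumerate(vals)}})
                        for roi, idx in space.roi_map.items():
                            roi_rows.append({"subject_id": sid, "group": group,
                                             "roi": roi, "band": band,
                                             "log_rel_power": float(np.log(vals[idx]))})
                else:
                    rbp = roi_band_power_chunked(operator, rec_p, space)
                    for roi, bands in rbp.values.items():
                        for band, val in bands.items():
                            roi_rows.append({"subject_id": sid, "group": group,
                                             "roi": roi, "band": band,
                                             "log_rel_power": val})
                # ROI series
                roi_3c = roi_timeseries_direct(operator, rec_p, space)
                theta_series = {r: band_pc1(x, "theta", rec_p.fs)
                                for r, x in roi_3c.items()}
                broad = {}
                for r, x in roi_3c.items():
                    xc = x - x.mean(axis=1, keepdims=True)
                    w, V = np.linalg.eigh(xc @ xc.T)
                    broad[r] = V[:, -1] @ xc
                # lagged phase coherence on broadband ROI series
                from .recording import EEGRecording

                roi_rec = EEGRecording(np.vstack(list(broad.values())), rec_p.fs,
                                       tuple(broad), reference="common_average")
                cs = epoch_and_cross_spectra(roi_rec, config.epoch_len_s,
                                             taper=config.taper, amp_reject_uv=None)
                lt = lpc_table(cs, n_surrogates=config.lpc_surrogates, seed=sub_seed)
                lt.insert(0, "subject_id", sid)
                lt.insert(1, "group", group)
                lpc_frames.append(lt)
                # directed connectivity
                gt = gc_table(theta_series, rec_p.fs, band=config.gc_band,
                              order=config.gc_order)
                gt.insert(0, "subject_id", sid)
                gt.insert(1, "group", group)
                gc_frames.append(gt)
                # phase-amplitude coupling
                pt = roi_pac_table(roi_3c, rec_p.fs, n_surrogates=config.pac_surrogates,
                                   seed=sub_seed, rois=LOOP_ROIS)
                pt.insert(0, "subject_id", sid)
                pt.insert(1, "group", group)
                pac_frames.append(pt)
            except Exception as err:
                raise RuntimeError(f"pipeline stage failed for subject {sid}: {err}") from err

    roi_power = cached["roi_power"] if cached["roi_power"] is not None \
        else pd.DataFrame(roi_rows)
    lpc = cached["lpc"] if cached["lpc"] is not None else pd.concat(lpc_frames, ignore_index=True)
    gc = cached["gc"] if cached["gc"] is not None else pd.concat(gc_frames, ignore_index=True)
    pac = cached["pac"] if cached["pac"] is not None else pd.concat(pac_frames, ignore_index=True)
    voxel_power = None
    if config.whole_brain:
        voxel_power = cached["voxel_power"] if cached["voxel_power"] is not None \
            else pd.DataFrame(vox_rows)

    summary = group_statistics(config, space, roi_power, gc, pac, voxel_power)
    summary["runtime_s"] = round(time.time() - t_start, 1)
    summary["config_hash"] = chash

    write_table(roi_power, out / "roi_power.csv", chash)
    write_table(lpc, out / "lpc.csv", chash)
    write_table(gc, out / "gc.csv", chash)
    write_table(pac, out / "pac.csv", chash)
    if voxel_power is not None:
        write_table(voxel_power, out / "voxel_power.csv", chash)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, default=float)
    log_lines.append(f"runtime_s {summary['runtime_s']}")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return PipelineResult(config=config, roi_power=roi_power, lpc=lpc, gc=gc,
                          pac=pac, summary=summary, out_dir=out,
                          voxel_power=voxel_power)


# ---------------------------------------------------------------------------
# group-level statistics


def _pivot_roi_power(roi_power: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    wide = roi_power.pivot_table(index=["subject_id", "group"],
                                 columns=["roi", "band"], values="log_rel_power")
    wide.columns = [f"{r}:{b}" for r, b in wide.columns]
    groups = wide.index.get_level_values("group").to_numpy()
    return wide.reset_index(drop=True), groups


def group_statistics(config: PipelineConfig, space, roi_power: pd.DataFrame,
                     gc: pd.DataFrame, pac: pd.DataFrame,
                     voxel_power: pd.DataFrame | None = None) -> dict:
    """Conjunction, step-down and loop-asymmetry inference on stage outputs."""
    alpha = config.alpha_level
    rng = np.random.default_rng(config.seed + 2)
    summary: dict = {}

    wide, groups = _pivot_roi_power(roi_power)
    features = wide.to_numpy(float)
    names = list(wide.columns)

    # patient-minus-control contrasts and their conjunction
    z_tin = inference.contrast_z(features, groups, "tinnitus", "control",
                                 n_perm=config.n_perm, seed=int(rng.integers(2**31)))
    z_pain = inference.contrast_z(features, groups, "pain", "control",
                                  n_perm=config.n_perm, seed=int(rng.integers(2**31)))
    min_z, sig = inference.conjunction(z_tin, z_pain, config.z_thresh)
    summary["conjunction"] = {
        "z_thresh": config.z_thresh,
        "significant_features": [n for n, s in zip(names, sig) if s],
        "min_z": dict(zip(names, np.round(min_z, 3))),
    }

    # whole-brain permutation max-statistic over voxels x bands
    if voxel_power is not None and len(voxel_power):
        vcols = [c for c in voxel_power.columns if c.startswith("v")]
        stacked = voxel_power.pivot_table(index=["subject_id", "group"],
                                          columns="band", values=vcols)
        vg = stacked.index.get_level_values("group").to_numpy()
        pr = inference.permutation_maxstat(stacked.to_numpy(float), vg,
                                           n_perm=config.n_perm, alpha=alpha,
                                           seed=int(rng.integers(2**31)))
        summary["whole_brain"] = {
            "n_features": int(stacked.shape[1]),
            "n_significant": int(pr.significant.sum()),
            "threshold_F": pr.threshold,
            "min_corrected_p": float(pr.corrected_p.min()),
        }

    # ROI power step-down (pgACC theta family; sensory/PHC gamma family)
    fams = [
        {"name": "pgACC_theta", "features": ["pgACC:theta"]},
        {"name": "sensory_gamma",
         "features": [f"{r}:gamma" for r in LOOP_ROIS]},
    ]
    summary["roi_power_stepdown"] = _stepdown_safe(wide, groups, fams, alpha)

    # GC step-down over the paper's nested families
    gcw = gc.pivot_table(index=["subject_id", "group"],
                         columns=["source_roi", "target_roi"], values="gc")
    gcw.columns = [f"{s}->{t}" for s, t in gcw.columns]
    gc_groups = gcw.index.get_level_values("group").to_numpy()
    gcw = gcw.reset_index(drop=True)
    summary["gc_stepdown"] = _stepdown_safe(gcw, gc_groups, _gc_families(), alpha)

    # PAC step-down
    pacw = pac.pivot_table(index=["subject_id", "group"], columns="roi", values="mvl")
    pac_groups = pacw.index.get_level_values("group").to_numpy()
    pacw = pacw.reset_index(drop=True)
    summary["pac_stepdown"] = _stepdown_safe(
        pacw, pac_groups, [{"name": "pac_mvl", "features": list(pacw.columns)}], alpha)

    summary["loop_report"] = loop_asymmetry_report(gcw, gc_groups, alpha=alpha)
    return summary


def _gc_families() -> list[dict]:
    pg = [f"pgACC->{r}" for r in ("L_AUD", "R_AUD", "L_SOM", "R_SOM", "L_PHC", "R_PHC")]
    pg += [f"{r}->pgACC" for r in ("L_AUD", "R_AUD", "L_SOM", "R_SOM", "L_PHC", "R_PHC")]
    pg_subs = [{"name": f"pgACC~{r}", "features": [f"pgACC->{r}", f"{r}->pgACC"]}
               for r in ("L_AUD", "R_AUD", "L_SOM", "R_SOM", "L_PHC", "R_PHC")]
    sens = []
    sens_subs = []
    for hemi in ("L", "R"):
        for s in ("AUD", "SOM"):
            a, b = f"{hemi}_{s}->{hemi}_PHC", f"{hemi}_PHC->{hemi}_{s}"
            sens += [a, b]
            sens_subs.append({"name": f"{hemi}_{s}~{hemi}_PHC", "features": [a, b]})
    return [
        {"name": "pgACC_links", "features": pg, "subfamilies": pg_subs},
        {"name": "sensory_phc_links", "features": sens, "subfamilies": sens_subs},
        {"name": "interhemispheric_phc",
         "features": ["L_PHC->R_PHC", "R_PHC->L_PHC"]},
    ]


def _report_dict(rep: inference.StepdownReport) -> dict:
    return {"multivariate": rep.multivariate, "univariate": rep.univariate,
            "pairwise": rep.pairwise}


def _stepdown_safe(table, groups, families, alpha) -> dict:
    """Run the step-down per family, recording (not raising) families that
    are too large for the available group sizes."""
    merged = inference.StepdownReport()
    skipped = []
    for fam in families:
        try:
            rep = inference.manova_stepdown(table, groups, [fam], alpha=alpha)
        except ValueError as err:
            skipped.append({"family": fam["name"], "reason": str(err)})
            continue
        merged.multivariate += rep.multivariate
        merged.univariate += rep.univariate
        merged.pairwise += rep.pairwise
    out = _report_dict(merged)
    if skipped:
        out["skipped_families"] = skipped
    return out


def loop_asymmetry_report(gc_wide: pd.DataFrame, groups: np.ndarray,
                          alpha: float = 0.05) -> dict:
    """Directionality of the parahippocampal-sensory theta loops.

    Per patient group: which of the eight sensory<->PHC links are elevated
    against controls (Holm-corrected two-group ANOVA); and the
    leakage-robust directionality contrast: the within-pair asymmetry
    Delta_X = GC(PHC->X) - GC(X->PHC), pooled over hemispheres, compared
    between tinnitus and pain.  The group with the significantly larger
    Delta_X carries the unidirectional PHC->X coupling, the other the
    bidirectional one.
    """
    links = [(f"{h}_PHC", f"{h}_{s}") for h in ("L", "R") for s in ("AUD", "SOM")]
    links += [(t, s) for s, t in links]
    out: dict = {"elevated_links": {}, "asymmetry": {}}
    ctrl = groups == "control"
    for grp in ("tinnitus", "pain"):
        sel = groups == grp
        pvals, recs = [], []
        for s, t in links:
            col = gc_wide[f"{s}->{t}"].to_numpy(float)
            F, p = _st.f_oneway(col[sel], col[ctrl])
            pvals.append(p)
            recs.append({"link": f"{s}->{t}", "F": float(F), "p": float(p),
                         "patient_mean": float(col[sel].mean()),
                         "control_mean": float(col[ctrl].mean())})
        adj = inference.holm_bonferroni(pvals)
        for r, pa in zip(recs, adj):
            r["p_holm"] = float(pa)
            r["elevated"] = bool(pa < alpha and r["patient_mean"] > r["control_mean"])
        out["elevated_links"][grp] = recs

    def delta(grp: str, modality: str) -> np.ndarray:
        sel = groups == grp
        fwd = sum(gc_wide[f"{h}_PHC->{h}_{modality}"].to_numpy(float)[sel]
                  for h in ("L", "R"))
        rev = sum(gc_wide[f"{h}_{modality}->{h}_PHC"].to_numpy(float)[sel]
                  for h in ("L", "R"))
        return (fwd - rev) / 2.0

    for modality in ("AUD", "SOM"):
        d_tin, d_pain = delta("tinnitus", modality), delta("pain", modality)
        t, p = _st.ttest_ind(d_tin, d_pain)
        out["asymmetry"][modality] = {
            "delta_tinnitus": float(d_tin.mean()), "delta_pain": float(d_pain.mean()),
            "t": float(t), "p": float(p),
        }
    # the planted hypothesis is a double dissociation (each patient group
    # unidirectional toward its non-dominant modality), so the omnibus test
    # is the group x modality interaction on the asymmetries; a significant
    # interaction gates the per-modality sign assignment (step-down logic)
    D_tin = delta("tinnitus", "SOM") - delta("tinnitus", "AUD")
    D_pain = delta("pain", "SOM") - delta("pain", "AUD")
    t_int, p_int = _st.ttest_ind(D_tin, D_pain)
    out["interaction"] = {"D_tinnitus": float(D_tin.mean()),
                          "D_pain": float(D_pain.mean()),
                          "t": float(t_int), "p": float(p_int)}
    # a significant interaction selects one of the two mirrored
    # configurations; both modality assignments follow from its sign
    # (t > 0: tinnitus is the SOM-unidirectional / AUD-bidirectional group)
    if p_int < alpha:
        som_uni = "tinnitus" if t_int > 0 else "pain"
        aud_uni = "pain" if t_int > 0 else "tinnitus"
        classification = {
            "SOM": {"unidirectional_PHC_to_SOM": som_uni,
                    "bidirectional": "pain" if som_uni == "tinnitus" else "tinnitus"},
            "AUD": {"unidirectional_PHC_to_AUD": aud_uni,
                    "bidirectional": "pain" if aud_uni == "tinnitus" else "tinnitus"},
        }
    else:
        classification = {m: {"unresolved": True} for m in ("AUD", "SOM")}
    out["classification"] = classification
    return out
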