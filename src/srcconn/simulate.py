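"""Synthetic resting-state cohorts with planted group structure.

Each subject is built from seven band-limited cortical sources (the seven
analysis ROIs).  Narrowband components are white noise zero-phase filtered
into the canonical bands (not pure sinusoids, so spectral estimators face
realistic spectra).  The planted pathology follows the modality-specific
parahippocampal loop pattern:

* tinnitus: theta edges PHC<->AUD in both directions, PHC->SOM only;
* pain:     theta edges PHC<->SOM in both directions, PHC->AUD only;
* both patient groups raise pgACC theta power, sensory gamma power and
  theta-gamma nesting depth relative to control;
* control: no pathological edges, baseline powers and nesting.

Directed edges act on the theta components with an integer-sample lag
(default 3 samples at the 128 Hz analysis rate, ~23 ms, near a quarter
theta cycle).  Gamma amplitude is nested on the ROI's own theta phase with
envelope (1 + m cos theta) / sqrt(1 + m^2/2), whose normalized mean vector
length has expectation m/2.  Scalp EEG is the lead-field projection of the
sources (instantaneous volume conduction) plus independent sensor noise.
Ground truth is attached to every simulated subject.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.signal import hilbert

from .bands import BAND_BY_NAME
from .headmodel import LeadField, SolutionSpace, ROI_NAMES, build_leadfield, make_solution_space
from .recording import EEGRecording, MONTAGE_1020, bandpass_filter, write_csv, write_edf

CONDITIONS = ("control", "tinnitus", "pain")

#: reference analysis rate for edge lags (samples at 128 Hz)
LAG_REFERENCE_FS = 128.0

#: baseline narrowband amplitudes (arbitrary units, SD of the component)
BASELINE_POWERS = {"delta": 0.5, "theta": 1.0, "alpha": 1.5, "beta": 0.5, "gamma": 0.5}
BASELINE_PAC_DEPTH = 0.1

#: patient deviations: multiplicative amplitude factors and nesting depth
PGACC_THETA_FACTOR = 1.8
SENSORY_GAMMA_FACTOR = 2.5
PATIENT_PAC_DEPTH = 0.5
EDGE_STRENGTH = 0.7
EDGE_LAG_SAMPLES = 3  # at 128 Hz

#: distributed background activity (resting-state "brain noise"): number of
#: extra grid sources and their total power relative to the ROI sources
BACKGROUND_N_SOURCES = 40
BACKGROUND_POWER_RATIO = 0.5

SENSORY_ROIS = ("L_AUD", "R_AUD", "L_SOM", "R_SOM")
LOOP_ROIS = SENSORY_ROIS + ("L_PHC", "R_PHC")


@dataclass(frozen=True)
class DirectedEdge:
    """A planted lagged linear influence between two ROIs' band components.

    ``lag`` is in samples at the 128 Hz reference rate and is rescaled when
    simulating at other rates so the physical delay is preserved.
    """

    source_roi: str
    target_roi: str
    band: str = "theta"
    strength: float = EDGE_STRENGTH
    lag: int = EDGE_LAG_SAMPLES

    def __post_init__(self) -> None:
        if self.lag < 1:
            raise ValueError("edge lag must be >= 1 sample")
        if self.source_roi == self.target_roi:
            raise ValueError("self-edges are not allowed")


@dataclass
class GroupTemplate:
    condition: str
    node_powers: dict[str, dict[str, float]]
    pac_depth: dict[str, float]
    edges: list[DirectedEdge] = field(default_factory=list)

    def __post_init__(self) -> None:
        for roi, m in self.pac_depth.items():
            if not 0.0 <= m <= 1.0:
                raise ValueError(f"pac_depth[{roi!r}] = {m} outside [0, 1]")
        for e in self.edges:
            for roi in (e.source_roi, e.target_roi):
                if roi not in self.node_powers:
                    raise ValueError(f"edge references unknown ROI {roi!r}")

    def has_edge(self, src: str, tgt: str) -> bool:
        return any(e.source_roi == src and e.target_roi == tgt for e in self.edges)


def make_group_template(condition: str, overrides: dict | None = None) -> GroupTemplate:
    """Build the planted template for one condition.

    ``overrides`` may replace ``node_powers``, ``pac_depth`` or ``edges``
    wholesale, or provide scalar knobs ``edge_strength``, ``edge_lag``,
    ``pac_depth_patient``.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    overrides = dict(overrides or {})
    unknown = set(overrides) - {"node_powers", "pac_depth", "edges",
                                "edge_strength", "edge_lag", "pac_depth_patient"}
    if unknown:
        raise ValueError(f"unknown override fields: {sorted(unknown)}")
    strength = overrides.get("edge_strength", EDGE_STRENGTH)
    lag = overrides.get("edge_lag", EDGE_LAG_SAMPLES)
    m_patient = overrides.get("pac_depth_patient", PATIENT_PAC_DEPTH)

    powers = {roi: dict(BASELINE_POWERS) for roi in ROI_NAMES}
    pac = {roi: BASELINE_PAC_DEPTH for roi in ROI_NAMES}
    edges: list[DirectedEdge] = []
    if condition in ("tinnitus", "pain"):
        powers["pgACC"]["theta"] *= PGACC_THETA_FACTOR
        for roi in SENSORY_ROIS:
            powers[roi]["gamma"] *= SENSORY_GAMMA_FACTOR
        for roi in LOOP_ROIS:
            pac[roi] = m_patient
        bidi = "AUD" if condition == "tinnitus" else "SOM"
        uni = "SOM" if condition == "tinnitus" else "AUD"
        for hemi in ("L", "R"):
            edges.append(DirectedEdge(f"{hemi}_PHC", f"{hemi}_{bidi}", "theta", strength, lag))
            edges.append(DirectedEdge(f"{hemi}_{bidi}", f"{hemi}_PHC", "theta", strength, lag))
            edges.append(DirectedEdge(f"{hemi}_PHC", f"{hemi}_{uni}", "theta", strength, lag))

    if "node_powers" in overrides:
        powers = overrides["node_powers"]
    if "pac_depth" in overrides:
        pac = overrides["pac_depth"]
    if "edges" in overrides:
        edges = list(overrides["edges"])
    return GroupTemplate(condition=condition, node_powers=powers,
                         pac_depth=pac, edges=edges)


@dataclass
class SourceSet:
    """Ground-truth source activity: per-ROI 3-component currents."""

    roi_currents: dict[str, np.ndarray]  # roi -> (3, T)
    components: dict[str, dict[str, np.ndarray]]  # band -> roi -> (T,)
    fs: float
    truth: GroupTemplate


@dataclass
class SubjectRecord:
    subject_id: str
    group: str
    recording: EEGRecording
    sources: SourceSet
    seed: int


@dataclass
class Cohort:
    subjects: list[SubjectRecord]
    seed: int
    fs: float


def check_edge_stability(template: GroupTemplate, rois=ROI_NAMES) -> float:
    """Spectral radius of the companion matrix of the planted edge system."""
    if not template.edges:
        return 0.0
    idx = {r: i for i, r in enumerate(rois)}
    k = len(rois)
    max_lag = max(e.lag for e in template.edges)
    C = np.zeros((k * max_lag, k * max_lag))
    for e in template.edges:
        C[idx[e.target_roi], (e.lag - 1) * k + idx[e.source_roi]] += e.strength
    if max_lag > 1:
        C[k:, : k * (max_lag - 1)] = np.eye(k * (max_lag - 1))
    return float(np.max(np.abs(np.linalg.eigvals(C))))


def _narrowband(rng: np.random.Generator, band_name: str, n: int, fs: float) -> np.ndarray:
    b = BAND_BY_NAME[band_name]
    x = bandpass_filter(rng.standard_normal(n), b.lo, b.hi, fs)
    sd = x.std()
    return x / sd if sd > 0 else x


def simulate_subject(template: GroupTemplate, duration_s: float = 300.0,
                     fs: float = 128.0, leadfield: "LeadField | np.ndarray | None" = None,
                     space: SolutionSpace | None = None, noise_sd: float = 2.0,
                     seed: int | None = None, target_rms_uv: float = 20.0,
                     background_n: int = BACKGROUND_N_SOURCES,
                     background_ratio: float = BACKGROUND_POWER_RATIO,
                     ) -> tuple[SourceSet, EEGRecording]:
    """Simulate one subject: source currents and their scalp projection.

    ``leadfield`` may be a LeadField (with ``space`` giving the ROI voxel
    indices), a plain (n_channels, n_rois) instantaneous mixing matrix for
    fast volume-conduction unit tests, or None (identity mixing: one sensor
    per ROI).  With a LeadField, ``background_n`` additional sources with
    the baseline band spectrum are placed at random non-ROI grid voxels
    (total power ``background_ratio`` times the ROI sources' baseline
    power), emulating distributed resting activity; they carry no group
    differences.  The clean scalp signal is scaled to ``target_rms_uv``
    before independent Gaussian sensor noise of SD ``noise_sd`` (uV) is
    added.
    """
    if fs < 128:
        raise ValueError("fs must be >= 128 Hz")
    if duration_s < 10:
        raise ValueError("duration must be >= 10 s")
    radius = check_edge_stability(template)
    if radius >= 1.0:
        raise ValueError(
            f"unstable edge configuration (companion spectral radius {radius:.3f}): "
            + "; ".join(f"{e.source_roi}->{e.target_roi} c={e.strength}" for e in template.edges))
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    rois = list(template.node_powers)

    components: dict[str, dict[str, np.ndarray]] = {}
    for band_name in BASELINE_POWERS:
        components[band_name] = {roi: _narrowband(rng, band_name, n, fs) for roi in rois}

    # lagged linear influences on the theta components
    edges_by_band: dict[str, list[DirectedEdge]] = {}
    for e in template.edges:
        edges_by_band.setdefault(e.band, []).append(e)
    for band_name, edges in edges_by_band.items():
        comp = components[band_name]
        idx = {r: i for i, r in enumerate(rois)}
        X = np.vstack([comp[r] for r in rois])
        lags = sorted({max(1, int(round(e.lag * fs / LAG_REFERENCE_FS))) for e in edges})
        mats = {}
        for e in edges:
            lag = max(1, int(round(e.lag * fs / LAG_REFERENCE_FS)))
            mats.setdefault(lag, np.zeros((len(rois), len(rois))))[
                idx[e.target_roi], idx[e.source_roi]] += e.strength
        start = max(lags)
        for t in range(start, n):
            for lag in lags:
                X[:, t] += mats[lag] @ X[:, t - lag]
        X /= X.std(axis=1, keepdims=True)
        for r in rois:
            comp[r] = X[idx[r]]

    # theta-gamma nesting on the ROI's own theta phase
    for roi in rois:
        m = template.pac_depth.get(roi, 0.0)
        if m > 0:
            phase = np.angle(hilbert(components["theta"][roi]))
            components["gamma"][roi] = (
                components["gamma"][roi] * (1.0 + m * np.cos(phase))
                / np.sqrt(1.0 + m**2 / 2.0))

    orientations = {roi: _random_unit(rng) for roi in rois}
    roi_currents = {}
    scalar = {}
    for roi in rois:
        s = sum(template.node_powers[roi].get(b, 0.0) * components[b][roi]
                for b in components)
        scalar[roi] = s
        roi_currents[roi] = orientations[roi][:, None] * s

    sources = SourceSet(roi_currents=roi_currents, components=components,
                        fs=fs, truth=template)

    # scalp projection
    if leadfield is None:
        mix = np.eye(len(rois))
        labels = tuple(rois)
    elif isinstance(leadfield, LeadField):
        if space is None:
            raise ValueError("a SolutionSpace is required with a LeadField")
        mix = np.column_stack([
            leadfield.voxel_gain(space.roi_index(roi)) @ orientations[roi] for roi in rois])
        labels = leadfield.montage
    else:
        mix = np.asarray(leadfield, float)
        if mix.shape[1] != len(rois):
            raise ValueError(f"mixing matrix must have {len(rois)} columns")
        labels = tuple(f"S{i}" for i in range(mix.shape[0]))

    S = np.vstack([scalar[r] for r in rois])
    clean = mix @ S
    if isinstance(leadfield, LeadField) and background_n > 0 and background_ratio > 0:
        clean = clean + _background_projection(
            rng, leadfield, space, rois, background_n, background_ratio, n, fs)
    rms = np.sqrt(np.mean(clean**2))
    if rms > 0:
        clean *= target_rms_uv / rms
    data = clean + noise_sd * rng.standard_normal(clean.shape)
    rec = EEGRecording(data, fs, labels)
    return sources, rec


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


def _background_projection(rng, leadfield: LeadField, space: SolutionSpace,
                           rois, n_src: int, power_ratio: float,
                           n: int, fs: float) -> np.ndarray:
    """Scalp contribution of distributed background sources.

    Each background source has the baseline band spectrum and a random
    orientation at a random non-ROI voxel; per-source amplitude is set so
    the summed background power equals ``power_ratio`` times the baseline
    power of the ROI sources.
    """
    taken = set(space.roi_map.values())
    candidates = np.array([v for v in range(space.n_voxels) if v not in taken])
    voxels = rng.choice(candidates, size=min(n_src, len(candidates)), replace=False)
    roi_baseline_power = len(rois) * sum(a**2 for a in BASELINE_POWERS.values())
    per_source_scale = np.sqrt(power_ratio * roi_baseline_power
                               / (len(voxels) * sum(a**2 for a in BASELINE_POWERS.values())))
    series = np.zeros((len(voxels), n))
    for band_name, amp in BASELINE_POWERS.items():
        b = BAND_BY_NAME[band_name]
        x = bandpass_filter(rng.standard_normal((len(voxels), n)), b.lo, b.hi, fs, axis=-1)
        x /= x.std(axis=1, keepdims=True)
        series += amp * x
    series *= per_source_scale
    patterns = np.column_stack([
        leadfield.voxel_gain(int(v)) @ _random_unit(rng) for v in voxels])
    return patterns @ series


def _jitter_template(template: GroupTemplate, rng: np.random.Generator,
                     cv: float) -> GroupTemplate:
    """Log-normal multiplicative inter-subject jitter (CV ~ ``cv``)."""
    if cv <= 0:
        return template
    sigma = np.sqrt(np.log(1.0 + cv**2))

    def jit() -> float:
        return float(np.exp(rng.normal(-sigma**2 / 2.0, sigma)))

    powers = {roi: {b: a * jit() for b, a in bands.items()}
              for roi, bands in template.node_powers.items()}
    pac = {roi: float(np.clip(m * jit(), 0.0, 1.0))
           for roi, m in template.pac_depth.items()}
    edges = [DirectedEdge(e.source_roi, e.target_roi, e.band,
                          e.strength * jit(), e.lag) for e in template.edges]
    out = GroupTemplate(template.condition, powers, pac, edges)
    # jitter must not push the coupled system out of stationarity: shrink
    # all strengths together until the companion radius is safely < 1
    while edges and check_edge_stability(out) >= 0.95:
        edges = [DirectedEdge(e.source_roi, e.target_roi, e.band,
                              e.strength * 0.9, e.lag) for e in edges]
        out = GroupTemplate(template.condition, powers, pac, edges)
    return out


def simulate_cohort(n_per_group: int = 25, duration_s: float = 300.0,
                    fs: float = 128.0, seed: int = 0,
                    leadfield: "LeadField | np.ndarray | None" = None,
                    space: SolutionSpace | None = None,
                    noise_sd: float = 2.0, jitter_cv: float = 0.2,
                    conditions: tuple[str, ...] = CONDITIONS,
                    grid_preset: str = "test") -> Cohort:
    """Simulate a three-group cohort with per-subject seeds and jitter.

    Subject seeds derive deterministically from the master seed; the same
    seed reproduces the cohort bit for bit.  When no lead field is given, a
    three-shell spherical one on the requested grid preset is built.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if leadfield is None:
        space = space or make_solution_space(grid_preset)
        leadfield = build_leadfield(MONTAGE_1020, space, model="three_shell_sphere")
    master = np.random.default_rng(seed)
    subjects: list[SubjectRecord] = []
    for cond in conditions:
        template = make_group_template(cond)
        for i in range(n_per_group):
            sub_seed = int(master.integers(0, 2**31 - 1))
            jrng = np.random.default_rng(sub_seed)
            jittered = _jitter_template(template, jrng, jitter_cv)
            src, rec = simulate_subject(jittered, duration_s, fs, leadfield,
                                        space, noise_sd, seed=sub_seed)
            subjects.append(SubjectRecord(f"{cond}_{i:03d}", cond, rec, src, sub_seed))
    return Cohort(subjects=subjects, seed=seed, fs=fs)


# ---------------------------------------------------------------------------
# serialization


def save_cohort(cohort: Cohort, out_dir: str | Path, format: str = "csv") -> None:
    """Write one file per subject plus ground-truth sidecars and a manifest."""
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for sub in cohort.subjects:
        stem = out / sub.subject_id
        if format == "csv":
            write_csv(sub.recording, stem.with_suffix(".csv"))
        elif format == "edf":
            write_edf(sub.recording, stem.with_suffix(".edf"))
        else:
            raise ValueError(f"unknown format {format!r}")
        truth = sub.sources.truth
        sidecar = {
            "subject_id": sub.subject_id, "group": sub.group, "seed": sub.seed,
            "condition": truth.condition,
            "node_powers": truth.node_powers, "pac_depth": truth.pac_depth,
            "edges": [asdict(e) for e in truth.edges],
        }
        with open(stem.with_suffix(".json"), "w") as fh:
            json.dump(sidecar, fh, indent=1)
        rows.append({"subject_id": sub.subject_id, "group": sub.group, "seed": sub.seed})
    pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)
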