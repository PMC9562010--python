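"""Synthetic resting-state cohorts with planted modular structure.

No public accession exists for the patient fMRI data this kind of analysis
is run on, so the package ships a generator that emulates the statistical
structure the pipeline assumes: per-subject 160-ROI, 130-frame BOLD series
(TR = 2 s) drawn from a zero-mean Gaussian with block-modular spatial
covariance (six functional systems), optional AR(1) temporal smoothing,
rigid-body motion traces with occasional displacement spikes, and clinical
covariates in which seizure frequency is tied to each patient's realised
intra-DMN (default-mode) connectivity with a negative slope.

The patient group differs from controls by configurable correlation offsets
on module blocks — by default reduced intra-DMN correlation and elevated
cingulo-opercular <-> occipital coupling — so the downstream pipeline has a
known ground truth to recover.  Analytic benchmark graph families
(lattices, small-world, random, complete, path, star) support metric
validation.

All randomness flows from a single master seed; per-subject streams are
derived from the master seed plus a stable hash of the subject id, so
results do not depend on generation order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .modular_analysis import (
    DEFAULT_MODULE_LABELS,
    DEFAULT_MODULE_SIZES,
    ModulePartition,
)
from .network_construction import pearson_matrix
from .signal_cleaning import MotionTrace, RoiTimeSeries

#: Eigenvalue floor used when repairing an indefinite block matrix.
PSD_FLOOR = 1e-6


@dataclass
class ClinicalLink:
    """Linear link from realised intra-DMN mean z to seizure frequency.

    ``freq = max(0, intercept + slope * z + noise)``; the default slope is
    negative so stronger intra-DMN connectivity means fewer daily spasms.
    """

    intercept: float = 13.0
    slope: float = -40.0
    noise_sd: float = 1.0


@dataclass
class SubjectRecord:
    """One row of the cohort metadata table."""

    subject_id: str
    group: str  # "patient" | "control"
    age_months: float
    sex: str  # "F" | "M"
    seizure_freq_per_day: float | None = None
    duration_months: float | None = None

    def __post_init__(self) -> None:
        if self.group not in ("patient", "control"):
            raise ValueError("group must be 'patient' or 'control'")
        if self.sex not in ("F", "M"):
            raise ValueError("sex must be 'F' or 'M'")
        if self.group == "control" and (
            self.seizure_freq_per_day is not None
            or self.duration_months is not None
        ):
            raise ValueError("controls must have clinical fields missing")


@dataclass
class CohortSpec:
    """Study-design parameters of a synthetic cohort.

    Defaults mirror the target study conditions: 16 analysed patients vs 34
    matched controls, 160 ROIs in six functional modules, 130 frames at
    TR = 2 s, within-module correlation 0.4 against a 0.1 background, a
    -0.15 intra-DMN offset and +0.10 cingulo-opercular/occipital offset in
    patients, and a negative seizure-frequency link.
    """

    n_patients: int = 16
    n_controls: int = 34
    n_rois: int = 160
    n_frames: int = 130
    tr: float = 2.0
    module_sizes: tuple[int, ...] = DEFAULT_MODULE_SIZES
    module_labels: tuple[str, ...] = DEFAULT_MODULE_LABELS
    r_within_control: float | tuple[float, ...] = 0.4
    r_between_control: float = 0.1
    patient_deltas: dict[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("default", "default"): -0.15,
            ("cingulo-opercular", "occipital"): 0.10,
        }
    )
    clinical_link: ClinicalLink = field(default_factory=ClinicalLink)
    ar_coeff: float = 0.3
    spike_prob: float = 0.05
    spike_scale: float = 0.6
    walk_sd: float = 0.02
    rot_walk_sd: float = 4e-4
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.n_controls < 1:
            raise ValueError("need at least one subject per group")
        if len(self.module_sizes) != len(self.module_labels):
            raise ValueError("module_sizes and module_labels length mismatch")
        if sum(self.module_sizes) != self.n_rois:
            raise ValueError(
                f"module sizes sum to {sum(self.module_sizes)}, "
                f"expected n_rois={self.n_rois}"
            )
        for r in np.atleast_1d(self.r_within_control):
            if not -1 < r < 1:
                raise ValueError("within-module correlations must be in (-1, 1)")
        if not -1 < self.r_between_control < 1:
            raise ValueError("between-module correlation must be in (-1, 1)")

    def r_within_list(self) -> list[float]:
        r = self.r_within_control
        if np.isscalar(r):
            return [float(r)] * len(self.module_sizes)
        if len(r) != len(self.module_sizes):
            raise ValueError("per-module r_within length mismatch")
        return [float(v) for v in r]


@dataclass
class SubjectData:
    """Everything generated for one subject."""

    record: SubjectRecord
    timeseries: RoiTimeSeries
    motion: MotionTrace
    nuisance: np.ndarray  # frames x 3 surrogate global/WM/CSF columns


@dataclass
class Cohort:
    """A generated cohort: subjects, partition, and generation metadata."""

    spec: CohortSpec
    subjects: list[SubjectData]
    partition: ModulePartition
    roi_ids: list[str]
    roi_coords: np.ndarray  # n_rois x 3 synthetic MNI-like mm coordinates
    info: dict = field(default_factory=dict)

    def metadata(self) -> pd.DataFrame:
        rows = [
            {
                "subject_id": s.record.subject_id,
                "group": s.record.group,
                "age_months": s.record.age_months,
                "sex": s.record.sex,
                "seizure_freq_per_day": s.record.seizure_freq_per_day,
                "duration_months": s.record.duration_months,
            }
            for s in self.subjects
        ]
        return pd.DataFrame(rows)

    def patients(self) -> list[SubjectData]:
        return [s for s in self.subjects if s.record.group == "patient"]

    def controls(self) -> list[SubjectData]:
        return [s for s in self.subjects if s.record.group == "control"]


def subject_seed_sequence(
    master_seed: int, subject_id: str
) -> np.random.SeedSequence:
    """Seed stream for one subject: master seed + stable id hash.

    Uses CRC-32 of the subject id so the stream does not depend on the
    order in which subjects are generated.
    """
    return np.random.SeedSequence(
        [int(master_seed), zlib.crc32(subject_id.encode("utf8"))]
    )


def make_block_covariance(
    module_sizes,
    r_within,
    r_between: float,
    overrides: dict[tuple[int, int], float] | None = None,
) -> tuple[np.ndarray, bool]:
    """Block-structured correlation matrix over ROIs.

    Entries are ``r_within[i]`` inside module ``i``, ``r_between``
    elsewhere, with optional per-block overrides keyed by module index
    pairs ``(i, j)``; the diagonal is 1.  If the raw matrix is indefinite
    its eigenvalues are clipped at a small floor and the result rescaled to
    unit diagonal.

    Returns
    -------
    (cov, repaired)
        The positive semidefinite matrix and whether repair occurred.
    """
    sizes = [int(s) for s in np.atleast_1d(module_sizes)]
    if any(s <= 0 for s in sizes):
        raise ValueError("module sizes must be positive")
    r_within = np.atleast_1d(np.asarray(r_within, dtype=float))
    if r_within.size == 1:
        r_within = np.repeat(r_within, len(sizes))
    if r_within.size != len(sizes):
        raise ValueError("r_within must be scalar or one value per module")
    vals = np.concatenate([r_within, [r_between]])
    if overrides:
        vals = np.concatenate([vals, list(overrides.values())])
    if np.any((vals <= -1) | (vals >= 1)):
        raise ValueError("correlations must lie in (-1, 1)")

    n = sum(sizes)
    cov = np.full((n, n), float(r_between))
    starts = np.cumsum([0] + sizes)
    slices = [slice(starts[i], starts[i + 1]) for i in range(len(sizes))]
    for i, sl in enumerate(slices):
        cov[sl, sl] = r_within[i]
    for (i, j), value in (overrides or {}).items():
        if not (0 <= i < len(sizes) and 0 <= j < len(sizes)):
            raise ValueError(f"override block ({i}, {j}) out of range")
        cov[slices[i], slices[j]] = value
        cov[slices[j], slices[i]] = value
    np.fill_diagonal(cov, 1.0)

    repaired = False
    evals = np.linalg.eigvalsh(cov)
    if evals[0] < PSD_FLOOR:
        repaired = True
        w, v = np.linalg.eigh(cov)
        w = np.maximum(w, PSD_FLOOR)
        cov = (v * w) @ v.T
        d = np.sqrt(np.diag(cov))
        cov = cov / np.outer(d, d)
        cov = (cov + cov.T) / 2.0
        np.fill_diagonal(cov, 1.0)
    return cov, repaired


def simulate_subject_timeseries(
    cov: np.ndarray,
    n_frames: int,
    ar_coeff: float = 0.0,
    seed: int | np.random.SeedSequence = 0,
    tr: float = 2.0,
    roi_ids: list[str] | None = None,
) -> RoiTimeSeries:
    """Zero-mean Gaussian frames with given spatial covariance.

    With ``ar_coeff = phi > 0`` frames follow a stationary AR(1)
    process ``x_t = phi x_{t-1} + sqrt(1 - phi^2) e_t`` whose marginal
    spatial covariance is still ``cov``.  Identical seeds give identical
    output.
    """
    cov = np.asarray(cov, dtype=float)
    if not 0 <= ar_coeff < 1:
        raise ValueError("ar_coeff must lie in [0, 1)")
    w, v = np.linalg.eigh(cov)
    if w[0] < -1e-8:
        raise ValueError(
            f"covariance is not positive semidefinite "
            f"(min eigenvalue {w[0]:.3e})"
        )
    factor = v * np.sqrt(np.maximum(w, 0.0))
    rng = np.random.default_rng(seed)
    innov = rng.standard_normal((n_frames, cov.shape[0])) @ factor.T
    if ar_coeff == 0.0:
        values = innov
    else:
        values = np.empty_like(innov)
        values[0] = innov[0]
        scale = np.sqrt(1.0 - ar_coeff**2)
        for t in range(1, n_frames):
            values[t] = ar_coeff * values[t - 1] + scale * innov[t]
    return RoiTimeSeries(values=values, tr=tr, roi_ids=roi_ids or [])


def simulate_motion_trace(
    n_frames: int,
    spike_prob: float = 0.05,
    spike_scale: float = 0.6,
    seed: int | np.random.SeedSequence = 0,
    walk_sd: float = 0.02,
    rot_walk_sd: float = 4e-4,
) -> MotionTrace:
    """Smooth random-walk motion parameters with sparse step spikes.

    Six columns: three translations (mm) and three rotations (rad) as
    Gaussian random walks starting at zero.  With probability
    ``spike_prob`` per frame (frames 1..T-1) a persistent translation step
    is applied whose per-axis magnitude is uniform in
    ``[0.5, 1.5] * spike_scale`` with random sign, so each spike produces
    one frame whose framewise displacement clearly exceeds the 0.5 mm
    scrubbing threshold at the default scale.
    """
    if not 0 <= spike_prob <= 1:
        raise ValueError("spike_prob must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    steps = np.zeros((n_frames, 6))
    if n_frames > 1:
        steps[1:, :3] = rng.normal(0.0, walk_sd, size=(n_frames - 1, 3))
        steps[1:, 3:] = rng.normal(0.0, rot_walk_sd, size=(n_frames - 1, 3))
    spikes = np.zeros(n_frames, dtype=bool)
    if n_frames > 1:
        spikes[1:] = rng.random(n_frames - 1) < spike_prob
    for t in np.flatnonzero(spikes):
        mag = rng.uniform(0.5, 1.5, size=3) * spike_scale
        sign = rng.choice([-1.0, 1.0], size=3)
        steps[t, :3] += mag * sign
    return MotionTrace(params=np.cumsum(steps, axis=0))


def assign_clinical_covariates(
    records: list[SubjectRecord],
    realized_dmn_z: dict[str, float],
    link: ClinicalLink | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[list[SubjectRecord], dict]:
    """Attach seizure frequencies tied to realised intra-DMN strength.

    For each patient, ``freq = max(0, a + b*z + noise)`` with the link's
    intercept a, slope b (negative by default) and Gaussian noise.
    Controls are left untouched.  Returns the updated records and metadata
    documenting the planted (pre-truncation) correlation.
    """
    link = link or ClinicalLink()
    patients = [r for r in records if r.group == "patient"]
    if not patients:
        raise ValueError("no patients in the cohort")
    missing = [r.subject_id for r in patients
               if r.subject_id not in realized_dmn_z]
    if missing:
        raise ValueError(f"no realised DMN strength for: {missing[:5]}")
    rng = np.random.default_rng(seed)
    z = np.array([realized_dmn_z[r.subject_id] for r in patients])
    noise = rng.normal(0.0, link.noise_sd, size=len(patients))
    raw = link.intercept + link.slope * z + noise
    freq = np.maximum(0.0, raw)
    out: list[SubjectRecord] = []
    i = 0
    for r in records:
        if r.group == "patient":
            out.append(
                SubjectRecord(
                    subject_id=r.subject_id,
                    group=r.group,
                    age_months=r.age_months,
                    sex=r.sex,
                    seizure_freq_per_day=float(freq[i]),
                    duration_months=r.duration_months,
                )
            )
            i += 1
        else:
            out.append(r)
    if len(patients) > 1 and np.std(z) > 0 and np.std(raw) > 0:
        planted_r = float(np.corrcoef(z, raw)[0, 1])
    else:
        planted_r = np.nan
    info = {
        "planted_correlation_pre_truncation": planted_r,
        "link_intercept": link.intercept,
        "link_slope": link.slope,
        "link_noise_sd": link.noise_sd,
    }
    return out, info


def benchmark_graph(
    kind: str,
    n: int,
    k_or_p: float | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Binary adjacency of a named analytic graph family.

    ``kind`` is one of ``ring_lattice`` (k nearest neighbours, k even),
    ``watts_strogatz`` (requires (k, p) as a tuple in ``k_or_p``),
    ``erdos_renyi`` (p), ``complete``, ``path``, ``star``.  Deterministic
    given the seed.
    """
    if n < 2:
        raise ValueError("need at least 2 nodes")
    if kind == "ring_lattice":
        k = int(k_or_p)
        if k % 2 != 0 or k >= n or k < 2:
            raise ValueError("lattice degree must be even, >= 2 and < n")
        g = nx.watts_strogatz_graph(n, k, p=0.0, seed=seed)
    elif kind == "watts_strogatz":
        k, p = k_or_p
        k = int(k)
        if k % 2 != 0 or k >= n or k < 2:
            raise ValueError("lattice degree must be even, >= 2 and < n")
        if not 0 <= p <= 1:
            raise ValueError("rewiring probability must lie in [0, 1]")
        g = nx.watts_strogatz_graph(n, k, p=float(p), seed=seed)
    elif kind == "erdos_renyi":
        p = float(k_or_p)
        if not 0 <= p <= 1:
            raise ValueError("edge probability must lie in [0, 1]")
        g = nx.gnp_random_graph(n, p, seed=seed)
    elif kind == "complete":
        g = nx.complete_graph(n)
    elif kind == "path":
        g = nx.path_graph(n)
    elif kind == "star":
        g = nx.star_graph(n - 1)
    else:
        raise ValueError(f"unknown benchmark graph kind: {kind!r}")
    return nx.to_numpy_array(g, nodelist=range(n), dtype=np.uint8)


def _module_index(spec: CohortSpec, label: str) -> int:
    try:
        return spec.module_labels.index(label)
    except ValueError as err:
        raise ValueError(f"unknown module label {label!r}") from err


def group_covariance(spec: CohortSpec, group: str) -> tuple[np.ndarray, bool]:
    """Block covariance for one group, applying patient offsets if any."""
    overrides: dict[tuple[int, int], float] = {}
    if group == "patient":
        r_within = spec.r_within_list()
        for (la, lb), delta in spec.patient_deltas.items():
            i, j = _module_index(spec, la), _module_index(spec, lb)
            base = r_within[i] if i == j else spec.r_between_control
            overrides[(min(i, j), max(i, j))] = base + delta
    return make_block_covariance(
        spec.module_sizes, spec.r_within_list(), spec.r_between_control,
        overrides or None,
    )


def intra_module_mean_z(
    ts: RoiTimeSeries, partition: ModulePartition, label: str = "default"
) -> float:
    """Mean Fisher z over unordered ROI pairs inside one module."""
    cm = pearson_matrix(ts)
    idx = partition.indices(label, cm.roi_ids)
    ii, jj = np.triu_indices(idx.size, k=1)
    return float(cm.z[idx[ii], idx[jj]].mean())


def generate_cohort(
    spec: CohortSpec | None = None,
    master_seed: int | None = None,
) -> Cohort:
    """Generate a full synthetic cohort from a specification.

    Produces per-subject ROI time series (block-modular covariance, AR(1)
    smoothing), motion traces, surrogate nuisance columns, demographics
    (ages and sexes drawn from a common distribution for both groups), and
    patient clinical covariates whose seizure frequency is negatively
    linked to the realised intra-DMN mean Fisher z.
    """
    spec = spec or CohortSpec()
    if master_seed is not None:
        spec = CohortSpec(**{**spec.__dict__, "master_seed": int(master_seed)})
    roi_ids = [f"roi{i:03d}" for i in range(spec.n_rois)]
    partition = ModulePartition.from_sizes(
        roi_ids, spec.module_sizes, spec.module_labels
    )
    cohort_rng = np.random.default_rng(
        np.random.SeedSequence([spec.master_seed, 0xC0F0])
    )
    coords = cohort_rng.uniform(-70, 70, size=(spec.n_rois, 3))

    subject_ids = [f"sub-P{i + 1:02d}" for i in range(spec.n_patients)] + [
        f"sub-C{i + 1:02d}" for i in range(spec.n_controls)
    ]
    groups = ["patient"] * spec.n_patients + ["control"] * spec.n_controls

    covs = {g: group_covariance(spec, g)[0] for g in ("patient", "control")}

    subjects: list[SubjectData] = []
    records: list[SubjectRecord] = []
    realized: dict[str, float] = {}
    for sid, group in zip(subject_ids, groups):
        ss = subject_seed_sequence(spec.master_seed, sid)
        ts_seed, motion_seed, nuis_seed, demo_seed = ss.spawn(4)
        ts = simulate_subject_timeseries(
            covs[group], spec.n_frames, spec.ar_coeff, ts_seed,
            tr=spec.tr, roi_ids=roi_ids,
        )
        motion = simulate_motion_trace(
            spec.n_frames, spec.spike_prob, spec.spike_scale, motion_seed,
            walk_sd=spec.walk_sd, rot_walk_sd=spec.rot_walk_sd,
        )
        nuis_rng = np.random.default_rng(nuis_seed)
        wm_csf = nuis_rng.standard_normal((spec.n_frames, 2))
        nuisance = np.column_stack([ts.values.mean(axis=1), wm_csf])
        demo_rng = np.random.default_rng(demo_seed)
        record = SubjectRecord(
            subject_id=sid,
            group=group,
            age_months=float(demo_rng.uniform(4, 40)),
            sex="F" if demo_rng.random() < 0.35 else "M",
            duration_months=(
                float(demo_rng.uniform(1, 24)) if group == "patient" else None
            ),
        )
        if group == "patient":
            realized[sid] = intra_module_mean_z(ts, partition, "default")
        subjects.append(SubjectData(record, ts, motion, nuisance))
        records.append(record)

    records, clin_info = assign_clinical_covariates(
        records,
        realized,
        spec.clinical_link,
        np.random.SeedSequence([spec.master_seed, 0xC11]),
    )
    for subj, rec in zip(subjects, records):
        subj.record = rec
    return Cohort(
        spec=spec,
        subjects=subjects,
        partition=partition,
        roi_ids=roi_ids,
        roi_coords=coords,
        info=clin_info,
    )
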