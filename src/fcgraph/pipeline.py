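"""End-to-end orchestration: configuration, file formats, and the full
cohort analysis.

The pipeline sequences the stages: signal cleaning -> connectivity matrix
construction -> sparsity binarisation -> graph metrics with random-null
normalisation and AUC -> six-module block strengths and data-driven
modularity -> covariate-adjusted group statistics with FDR, effect sizes
and clinical partial correlations.  Every run is deterministic given the
master seed and emits a manifest sufficient to reproduce it.

All on-disk formats are plain text: delimited time-series (frames x ROIs
with ROI-id header), motion files (frames x 6), a partition CSV
(roi_id, roi_name, module_label, x, y, z), a cohort metadata CSV, and
headered square matrices.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .graph_metrics import (
    NORMALIZED_METRICS,
    compute_metric_curves,
)
from .group_inference import (
    adjusted_group_ttest,
    chi_square_2x2,
    fdr_bh,
    hedges_g,
    partial_correlation,
)
from .modular_analysis import (
    ModulePartition,
    all_block_strengths,
    spectral_modularity,
)
from .network_construction import (
    SparsityGrid,
    pearson_matrix,
    sparsity_binarize,
)
from .signal_cleaning import MotionTrace, RoiTimeSeries, clean_subject
from .synthetic_cohort import Cohort, SubjectData, SubjectRecord

logger = logging.getLogger("fcgraph")

#: Metrics entered into the group comparison when nulls are available.
GROUP_METRICS = ("lambda", "gamma", "sigma", "Eglob", "Eloc")
#: Fallback family when small-world normalisation is skipped (n_null = 0).
GROUP_METRICS_RAW = ("Cp", "Lp", "Eglob", "Eloc")


@dataclass
class AnalysisConfig:
    """Everything needed to run (and re-run) one analysis."""

    timeseries_dir: str = ""
    motion_dir: str = ""
    partition_file: str = ""
    cohort_file: str = ""
    output_dir: str = "results"
    grid_start: float = 0.05
    grid_stop: float = 0.40
    grid_levels: int = 18
    low_hz: float = 0.01
    high_hz: float = 0.08
    fd_threshold: float = 0.5
    do_detrend: bool = True
    do_bandpass: bool = True
    do_regress: bool = True
    do_scrub: bool = True
    n_null: int = 100
    n_swap_factor: float = 10.0
    master_seed: int = 0
    fdr_level: float = 0.05
    block_denominator: str = "all_pairs"
    covariates: tuple[str, ...] = ("age", "sex")

    def grid(self) -> SparsityGrid:
        return SparsityGrid(
            np.linspace(self.grid_start, self.grid_stop, self.grid_levels)
        )

    def validate(self, check_paths: bool = True) -> None:
        self.grid()  # raises if invalid
        if not 0 < self.fdr_level < 1:
            raise ValueError("fdr_level must lie in (0, 1)")
        if self.n_null < 0:
            raise ValueError("n_null must be nonnegative")
        if check_paths:
            for name in ("timeseries_dir", "motion_dir", "partition_file",
                         "cohort_file"):
                p = getattr(self, name)
                if not p or not Path(p).exists():
                    raise FileNotFoundError(f"{name} does not exist: {p!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "covariates" in data:
            data["covariates"] = tuple(data["covariates"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["covariates"] = list(d["covariates"])
        return d


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def write_timeseries(path: str | Path, ts: RoiTimeSeries) -> None:
    pd.DataFrame(ts.values, columns=ts.roi_ids).to_csv(
        path, sep="\t", index=False, float_format="%.8g"
    )


def read_timeseries(path: str | Path, tr: float) -> RoiTimeSeries:
    df = pd.read_csv(path, sep="\t")
    return RoiTimeSeries(
        values=df.to_numpy(float), tr=tr, roi_ids=[str(c) for c in df.columns]
    )


MOTION_COLUMNS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]


def write_motion(path: str | Path, motion: MotionTrace) -> None:
    pd.DataFrame(motion.params, columns=MOTION_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.8g"
    )


def read_motion(path: str | Path) -> MotionTrace:
    return MotionTrace(pd.read_csv(path, sep="\t").to_numpy(float))


def write_partition(
    path: str | Path,
    partition: ModulePartition,
    roi_ids: list[str],
    coords: np.ndarray | None = None,
) -> None:
    if coords is None:
        coords = np.zeros((len(roi_ids), 3))
    pd.DataFrame(
        {
            "roi_id": roi_ids,
            "roi_name": roi_ids,
            "module_label": [partition.assignments[r] for r in roi_ids],
            "x": coords[:, 0],
            "y": coords[:, 1],
            "z": coords[:, 2],
        }
    ).to_csv(path, index=False, float_format="%.2f")


def read_partition(
    path: str | Path,
) -> tuple[ModulePartition, list[str], np.ndarray]:
    df = pd.read_csv(path)
    roi_ids = [str(r) for r in df["roi_id"]]
    labels = tuple(dict.fromkeys(str(m) for m in df["module_label"]))
    partition = ModulePartition(
        dict(zip(roi_ids, (str(m) for m in df["module_label"]))), labels
    )
    coords = df[["x", "y", "z"]].to_numpy(float)
    return partition, roi_ids, coords


def write_matrix(path: str | Path, mat: np.ndarray, roi_ids: list[str]) -> None:
    pd.DataFrame(mat, index=roi_ids, columns=roi_ids).to_csv(
        path, sep="\t", float_format="%.8g"
    )


def read_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(float), [str(c) for c in df.columns]


def write_cohort(cohort: Cohort, outdir: str | Path) -> dict[str, Path]:
    """Write a generated cohort in the pipeline's on-disk layout."""
    outdir = Path(outdir)
    ts_dir = outdir / "timeseries"
    mot_dir = outdir / "motion"
    ts_dir.mkdir(parents=True, exist_ok=True)
    mot_dir.mkdir(parents=True, exist_ok=True)
    for subj in cohort.subjects:
        sid = subj.record.subject_id
        write_timeseries(ts_dir / f"{sid}_timeseries.tsv", subj.timeseries)
        write_motion(mot_dir / f"{sid}_motion.tsv", subj.motion)
        pd.DataFrame(
            subj.nuisance, columns=["global", "wm", "csf"]
        ).to_csv(ts_dir / f"{sid}_nuisance.tsv", sep="\t", index=False,
                 float_format="%.8g")
    cohort.metadata().to_csv(outdir / "cohort.csv", index=False)
    write_partition(
        outdir / "partition.csv", cohort.partition, cohort.roi_ids,
        cohort.roi_coords,
    )
    (outdir / "generation_info.json").write_text(
        json.dumps(cohort.info, indent=2, default=float)
    )
    return {
        "timeseries_dir": ts_dir,
        "motion_dir": mot_dir,
        "partition_file": outdir / "partition.csv",
        "cohort_file": outdir / "cohort.csv",
    }


def config_for_cohort_dir(outdir: str | Path, **overrides) -> AnalysisConfig:
    """AnalysisConfig pointing at a directory written by write_cohort."""
    outdir = Path(outdir)
    return AnalysisConfig(
        timeseries_dir=str(outdir / "timeseries"),
        motion_dir=str(outdir / "motion"),
        partition_file=str(outdir / "partition.csv"),
        cohort_file=str(outdir / "cohort.csv"),
        output_dir=str(outdir / "results"),
        **overrides,
    )


@dataclass
class LoadedCohort:
    subjects: list[SubjectData]
    partition: ModulePartition
    roi_ids: list[str]


def load_cohort(config: AnalysisConfig, tr: float = 2.0) -> LoadedCohort:
    """Load and validate a cohort from disk.

    Every subject in the metadata table must have matching time-series and
    motion files; ROI columns are harmonised to the partition file's order.
    Missing files, duplicate subject ids, and ROI-id mismatches are
    reported with the offending subject named.
    """
    config.validate(check_paths=True)
    partition, roi_order, _ = read_partition(config.partition_file)
    meta = pd.read_csv(config.cohort_file)
    if meta["subject_id"].duplicated().any():
        dupes = meta.loc[meta["subject_id"].duplicated(), "subject_id"]
        raise ValueError(f"duplicate subject ids: {sorted(set(dupes))}")
    subjects: list[SubjectData] = []
    for row in meta.itertuples(index=False):
        sid = str(row.subject_id)
        ts_path = Path(config.timeseries_dir) / f"{sid}_timeseries.tsv"
        mot_path = Path(config.motion_dir) / f"{sid}_motion.tsv"
        if not ts_path.exists():
            raise FileNotFoundError(f"missing time series for {sid}: {ts_path}")
        if not mot_path.exists():
            raise FileNotFoundError(f"missing motion file for {sid}: {mot_path}")
        ts = read_timeseries(ts_path, tr=tr)
        if set(ts.roi_ids) != set(roi_order):
            raise ValueError(
                f"ROI ids of {sid} do not match the partition file"
            )
        if ts.roi_ids != roi_order:  # harmonise column order
            idx = [ts.roi_ids.index(r) for r in roi_order]
            ts = RoiTimeSeries(ts.values[:, idx], ts.tr, list(roi_order))
        motion = read_motion(mot_path)
        if motion.n_frames != ts.n_frames:
            raise ValueError(f"motion/time-series frame mismatch for {sid}")
        nuis_path = Path(config.timeseries_dir) / f"{sid}_nuisance.tsv"
        nuisance = (
            pd.read_csv(nuis_path, sep="\t").to_numpy(float)
            if nuis_path.exists()
            else np.zeros((ts.n_frames, 0))
        )
        freq = getattr(row, "seizure_freq_per_day", None)
        dur = getattr(row, "duration_months", None)
        record = SubjectRecord(
            subject_id=sid,
            group=str(row.group),
            age_months=float(row.age_months),
            sex=str(row.sex),
            seizure_freq_per_day=None if pd.isna(freq) else float(freq),
            duration_months=None if pd.isna(dur) else float(dur),
        )
        subjects.append(SubjectData(record, ts, motion, nuisance))
    return LoadedCohort(subjects, partition, roi_order)


# ---------------------------------------------------------------------------
# Analysis
# ---------------------------------------------------------------------------

@dataclass
class AnalysisResults:
    """All tabular outputs of one pipeline run."""

    metric_values: pd.DataFrame   # subject_id, metric, sparsity, value
    metric_auc: pd.DataFrame      # subject_id, metric, auc
    block_strength: pd.DataFrame  # subject_id, block, sparsity, strength
    block_auc: pd.DataFrame       # subject_id, block, auc
    modularity: pd.DataFrame      # subject_id, sparsity, Q, n_modules
    group_stats: pd.DataFrame     # analysis_id, metric_or_block, t, p, q, ...
    correlations: pd.DataFrame    # variable_pair, r_partial, p, df, n
    demographics: pd.DataFrame    # statistic, value, p
    flags: pd.DataFrame           # subject_id, stage, message
    manifest: dict = field(default_factory=dict)


def _subject_metric_seed(master_seed: int, subject_id: str) -> int:
    ss = np.random.SeedSequence(
        [int(master_seed), zlib.crc32(subject_id.encode("utf8")), 0x3E7]
    )
    return int(ss.generate_state(1)[0] % (2**31))


def analyze_cohort(
    cohort: Cohort | LoadedCohort, config: AnalysisConfig
) -> AnalysisResults:
    """Run the full analysis on an in-memory cohort.

    Deterministic given ``config.master_seed``; no stage mutates its
    inputs.
    """
    grid = config.grid()
    partition = cohort.partition
    flags: list[dict] = []

    metric_rows, auc_rows = [], []
    block_rows, block_auc_rows = [], []
    mod_rows = []
    subj_auc: dict[str, dict[str, float]] = {}
    block_auc_by_subj: dict[str, dict[tuple[str, str], float]] = {}

    for subj in cohort.subjects:
        sid = subj.record.subject_id
        cleaned, report = clean_subject(
            subj.timeseries,
            subj.motion,
            subj.nuisance if subj.nuisance.size else None,
            low_hz=config.low_hz,
            high_hz=config.high_hz,
            fd_threshold=config.fd_threshold,
            do_detrend=config.do_detrend,
            do_bandpass=config.do_bandpass,
            do_regress=config.do_regress,
            do_scrub=config.do_scrub,
        )
        if report is not None and report.replaced_indices:
            flags.append({
                "subject_id": sid, "stage": "scrub",
                "message": f"replaced {len(report.replaced_indices)} frames "
                           f"({report.fraction_replaced:.3f})",
            })
        try:
            cm = pearson_matrix(cleaned)
        except ValueError as err:
            raise ValueError(f"connectivity failed for {sid}: {err}") from err
        if cm.clamped_pairs:
            flags.append({
                "subject_id": sid, "stage": "connectivity",
                "message": f"{len(cm.clamped_pairs)} correlation(s) clamped",
            })
        stack = sparsity_binarize(cm, grid)
        for w in stack.warnings:
            flags.append({"subject_id": sid, "stage": "binarize",
                          "message": w})
        seed = _subject_metric_seed(config.master_seed, sid)
        curves = compute_metric_curves(
            stack, n_null=config.n_null, seed=seed,
            n_swap_factor=config.n_swap_factor,
        )
        subj_auc[sid] = {}
        for name, curve in curves.items():
            subj_auc[sid][name] = curve.auc
            auc_rows.append({"subject_id": sid, "metric": name,
                             "auc": curve.auc})
            for s, v in zip(curve.sparsities, curve.values):
                metric_rows.append({"subject_id": sid, "metric": name,
                                    "sparsity": s, "value": v})
        blocks = all_block_strengths(cm, stack, partition,
                                     config.block_denominator)
        block_auc_by_subj[sid] = {}
        for blk, bs in blocks.items():
            label = f"{blk[0]}|{blk[1]}"
            block_auc_by_subj[sid][blk] = bs.auc
            block_auc_rows.append({"subject_id": sid, "block": label,
                                   "auc": bs.auc})
            for s, v in zip(bs.sparsities, bs.strength):
                block_rows.append({"subject_id": sid, "block": label,
                                   "sparsity": s, "strength": v})
        for s, adj in stack:
            mr = spectral_modularity(adj)
            mod_rows.append({"subject_id": sid, "sparsity": s,
                             "Q": mr.q, "n_modules": mr.n_modules})

    meta = pd.DataFrame([
        {
            "subject_id": s.record.subject_id,
            "group": s.record.group,
            "age_months": s.record.age_months,
            "sex": s.record.sex,
            "seizure_freq_per_day": s.record.seizure_freq_per_day,
            "duration_months": s.record.duration_months,
        }
        for s in cohort.subjects
    ])
    group_stats = _group_statistics(
        meta, subj_auc, block_auc_by_subj, config
    )
    correlations = _clinical_correlations(
        meta, subj_auc, block_auc_by_subj, group_stats
    )
    demographics = _demographics(meta)

    return AnalysisResults(
        metric_values=pd.DataFrame(metric_rows),
        metric_auc=pd.DataFrame(auc_rows),
        block_strength=pd.DataFrame(block_rows),
        block_auc=pd.DataFrame(block_auc_rows),
        modularity=pd.DataFrame(mod_rows),
        group_stats=group_stats,
        correlations=correlations,
        demographics=demographics,
        flags=pd.DataFrame(flags,
                           columns=["subject_id", "stage", "message"]),
        manifest=_manifest(config),
    )


def _group_statistics(meta, subj_auc, block_auc_by_subj, config):
    """Covariate-adjusted group comparisons with FDR per analysis family."""
    sids = list(meta["subject_id"])
    group = meta["group"].to_numpy()
    age = meta["age_months"].to_numpy(float) if "age" in config.covariates \
        else None
    sex = meta["sex"].to_numpy() if "sex" in config.covariates else None
    is_patient = group == "patient"

    available = set(next(iter(subj_auc.values()), {}))
    metric_family = (
        GROUP_METRICS
        if set(NORMALIZED_METRICS) <= available
        else GROUP_METRICS_RAW
    )
    rows = []
    for family_id, names in (
        ("global_metrics", list(metric_family)),
        ("module_blocks", None),
    ):
        if names is None:
            blocks = sorted({b for d in block_auc_by_subj.values()
                             for b in d})
            names = [f"{a}|{b}" for a, b in blocks]
            values = {
                n: np.array([block_auc_by_subj[s][blk] for s in sids])
                for n, blk in zip(names, blocks)
            }
        else:
            values = {
                n: np.array([subj_auc[s][n] for s in sids]) for n in names
            }
        family_rows = []
        for name in names:
            v = values[name]
            comp = adjusted_group_ttest(v, group, age, sex, metric=name)
            es = hedges_g(v[is_patient], v[~is_patient])
            family_rows.append({
                "analysis_id": family_id,
                "metric_or_block": name,
                "t": comp.t, "p": comp.p, "df": comp.df,
                "g": es.g, "ci_low": es.ci95[0], "ci_high": es.ci95[1],
                "label": es.label, "direction": comp.direction,
            })
        q, reject = fdr_bh([r["p"] for r in family_rows], config.fdr_level)
        for r, qi, rej in zip(family_rows, q, reject):
            r["q"] = float(qi)
            r["significant_fdr"] = bool(rej)
        rows.extend(family_rows)
    cols = ["analysis_id", "metric_or_block", "t", "p", "q", "df", "g",
            "ci_low", "ci_high", "label", "direction", "significant_fdr"]
    return pd.DataFrame(rows)[cols]


def _clinical_correlations(meta, subj_auc, block_auc_by_subj, group_stats):
    """Partial correlations (age, sex controlled) of every AUC measure with
    the patients' clinical variables; uncorrected p-values."""
    from .group_inference import _encode_sex

    pat = meta[meta["group"] == "patient"]
    rows = []
    if len(pat) < 6:
        return pd.DataFrame(
            rows, columns=["variable_pair", "measure", "clinical",
                           "r_partial", "p", "df", "n", "source_significant"]
        )
    covs = np.column_stack([
        pat["age_months"].to_numpy(float),
        _encode_sex(pat["sex"].to_numpy()),
    ])
    sig = dict(zip(group_stats["metric_or_block"],
                   group_stats["significant_fdr"]))
    measures: dict[str, np.ndarray] = {}
    for name in group_stats["metric_or_block"]:
        if "|" in name:
            blk = tuple(name.split("|"))
            measures[name] = np.array(
                [block_auc_by_subj[s][blk] for s in pat["subject_id"]]
            )
        else:
            measures[name] = np.array(
                [subj_auc[s][name] for s in pat["subject_id"]]
            )
    for clinical in ("seizure_freq_per_day", "duration_months"):
        y = pat[clinical].to_numpy(float)
        if np.any(~np.isfinite(y)):
            continue
        for name, x in measures.items():
            res = partial_correlation(x, y, covs)
            rows.append({
                "variable_pair": f"{name}~{clinical}",
                "measure": name,
                "clinical": clinical,
                "r_partial": res.r,
                "p": res.p,
                "df": res.df,
                "n": len(pat),
                "source_significant": bool(sig.get(name, False)),
            })
    return pd.DataFrame(rows)


def _demographics(meta) -> pd.DataFrame:
    """Sex chi-square and age two-sample t between the groups."""
    from scipy import stats as sstats

    rows = []
    tab = pd.crosstab(meta["group"], meta["sex"])
    if tab.shape == (2, 2):
        chi2, p = chi_square_2x2(tab.to_numpy())
        rows.append({"statistic": "sex_chi2", "value": chi2, "p": p})
    age_p = meta.loc[meta["group"] == "patient", "age_months"]
    age_c = meta.loc[meta["group"] == "control", "age_months"]
    t, p = sstats.ttest_ind(age_p, age_c)
    rows.append({"statistic": "age_t", "value": float(t), "p": float(p)})
    return pd.DataFrame(rows)


def _manifest(config: AnalysisConfig) -> dict:
    cfg = config.to_dict()
    blob = json.dumps(cfg, sort_keys=True).encode()
    return {
        "config": cfg,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "master_seed": config.master_seed,
        "package_version": _pkg_version,
        "numpy_version": np.__version__,
    }


def write_results(results: AnalysisResults, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results.metric_values.to_csv(outdir / "metric_values.csv", index=False)
    results.metric_auc.to_csv(outdir / "metric_auc.csv", index=False)
    results.block_strength.to_csv(outdir / "block_strength.csv", index=False)
    results.block_auc.to_csv(outdir / "block_auc.csv", index=False)
    results.modularity.to_csv(outdir / "modularity.csv", index=False)
    results.group_stats.to_csv(outdir / "group_stats.csv", index=False)
    results.correlations.to_csv(outdir / "correlations.csv", index=False)
    results.demographics.to_csv(outdir / "demographics.csv", index=False)
    results.flags.to_csv(outdir / "flags.csv", index=False)
    (outdir / "manifest.json").write_text(
        json.dumps(results.manifest, indent=2)
    )
    return outdir


def run_analysis(config: AnalysisConfig) -> AnalysisResults:
    """Load a cohort from disk, analyse it, and write the results bundle."""
    cohort = load_cohort(config)
    results = analyze_cohort(cohort, config)
    write_results(results, config.output_dir)
    return results
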