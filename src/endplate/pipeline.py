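"""End-to-end cohort pipeline: generate/load -> measure -> classify -> statistics.

The pipeline produces, per run: a per-endplate metrics table, a
classification table, per-segment shape-distribution tables for both
planes, sex-comparison tables (exact p and Cramér's V for morphology;
t, CI and Cohen's d for depth) and a reliability section, bundled into a
:class:`CohortReport` and optionally written as CSVs plus one JSON.
Deterministic for a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import ClassifierConfig, SEGMENTS, classify, classify_cohort
from .errors import EndplateError, InputError, ParameterError, \
    UndefinedEffectError
from .mesh_io import AnatomicalFrame, read_stl
from .morphometry import DEFAULT_MARGIN_FRACTION, NOISY_SMOOTH_WINDOW, \
    measure_profile
from .profiles import extract_profile
from .stats import GroupSummary, exact_test, icc_absolute_agreement, \
    pooled_t_test
from .synthetic import CohortRecord, generate_cohort

log = logging.getLogger("endplate")

RELIABILITY_PARAMS = ("SCD", "CCD", "SD", "CD")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.  Exactly one input mode applies:
    synthetic generation (``n_patients``) or an STL directory with a
    manifest (``stl_dir``)."""

    n_patients: int | None = 33
    stl_dir: str | None = None
    frame: AnatomicalFrame = field(default_factory=AnatomicalFrame)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    margin_fraction: float = DEFAULT_MARGIN_FRACTION
    smooth_window: int = NOISY_SMOOTH_WINDOW
    noise_sd: float = 0.05
    resolution: int = 64
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self):
        if (self.n_patients is None) == (self.stl_dir is None):
            raise ParameterError(
                "exactly one of n_patients (synthetic) or stl_dir must be set"
            )

    def digest(self) -> str:
        raw = json.dumps({
            "n_patients": self.n_patients, "stl_dir": self.stl_dir,
            "frame": (self.frame.lateral, self.frame.ap, self.frame.si),
            "classifier": (self.classifier.depth_threshold,
                           self.classifier.ratio_threshold,
                           self.classifier.plateau_threshold),
            "margin_fraction": self.margin_fraction,
            "smooth_window": self.smooth_window,
            "noise_sd": self.noise_sd, "resolution": self.resolution,
            "seed": self.seed,
        }, sort_keys=True)
        return hashlib.sha256(raw.encode()).hexdigest()[:16]


@dataclass
class CohortReport:
    metrics: pd.DataFrame
    classes: pd.DataFrame
    distribution_sagittal: pd.DataFrame
    distribution_coronal: pd.DataFrame
    sex_morphology: pd.DataFrame
    sex_depth: pd.DataFrame
    reliability: pd.DataFrame | None
    failures: list[dict]
    meta: dict

    def to_json_dict(self) -> dict:
        def df(d):
            return None if d is None else json.loads(
                d.reset_index().to_json(orient="records")
            )
        return {
            "meta": self.meta,
            "distribution_sagittal": df(self.distribution_sagittal),
            "distribution_coronal": df(self.distribution_coronal),
            "sex_morphology": df(self.sex_morphology),
            "sex_depth": df(self.sex_depth),
            "reliability": df(self.reliability),
            "failures": self.failures,
            "n_endplates": int(len(self.metrics) // 2),
        }


def _load_stl_cohort(config: RunConfig) -> list[dict]:
    stl_dir = Path(config.stl_dir)
    manifest_path = stl_dir / "manifest.csv"
    if not manifest_path.exists():
        raise InputError(f"no manifest.csv in {stl_dir}")
    manifest = pd.read_csv(manifest_path)
    need = {"patient", "sex", "segment", "file"}
    if need - set(manifest.columns):
        raise InputError(f"manifest must have columns {sorted(need)}")
    items = []
    for _, row in manifest.iterrows():
        items.append({"patient": row["patient"], "sex": row["sex"],
                      "segment": row["segment"],
                      "path": stl_dir / row["file"]})
    return items


def measure_endplate(mesh, margin_fraction: float,
                     classifier: ClassifierConfig,
                     smooth_window: int = NOISY_SMOOTH_WINDOW) -> list[dict]:
    """Both-plane metrics + class for one endplate mesh."""
    rows = []
    for plane in ("sagittal", "coronal"):
        prof = extract_profile(mesh, plane)
        m = measure_profile(prof, margin_fraction, smooth_window)
        row = m.as_dict()
        row["shape_class"] = classify(m, classifier).value
        rows.append(row)
    return rows


def run_pipeline(config: RunConfig) -> CohortReport:
    """Run the full cohort pipeline; see the module docstring."""
    records: list[CohortRecord] | None = None
    if config.stl_dir is not None:
        items = _load_stl_cohort(config)
        log.info("loaded manifest with %d endplates from %s",
                 len(items), config.stl_dir)
    else:
        records = generate_cohort(config.n_patients, seed=config.seed,
                                  noise_sd=config.noise_sd,
                                  resolution=config.resolution)
        items = [{"patient": r.patient_id, "sex": r.sex,
                  "segment": r.segment, "mesh": r.mesh} for r in records]
        log.info("generated synthetic cohort: %d patients, %d endplates",
                 config.n_patients, len(items))

    metric_rows, failures = [], []
    for item in items:
        try:
            mesh = item.get("mesh")
            if mesh is None:
                mesh = read_stl(item["path"], frame=config.frame)
            for row in measure_endplate(mesh, config.margin_fraction,
                                        config.classifier,
                                        config.smooth_window):
                row.update(patient=item["patient"], sex=item["sex"],
                           segment=item["segment"])
                metric_rows.append(row)
        except EndplateError as exc:
            failures.append({"patient": str(item["patient"]),
                             "segment": str(item["segment"]),
                             "error": str(exc)})
    if not metric_rows:
        raise EndplateError("all endplates failed to measure")
    if failures:
        log.warning("%d endplates failed measurement", len(failures))

    metrics = pd.DataFrame(metric_rows)
    log.info("measured %d profiles from %d endplates",
             len(metrics), len(metrics) // 2)
    classes = metrics[["patient", "sex", "segment", "plane", "shape_class"]]

    dist = {p: classify_cohort(classes[classes["plane"] == p])
            for p in ("sagittal", "coronal")}

    sex_morph = _sex_morphology_tables(classes)
    sex_depth = _sex_depth_tables(metrics)

    reliability = None
    if records is not None:
        n_pat = len({r.patient_id for r in records})
        if n_pat >= 10:
            reliability = reliability_protocol(records, seed=config.seed)

    meta = {"seed": config.seed, "config_hash": config.digest(),
            "package_version": __version__,
            "n_input_endplates": len(items), "n_failed": len(failures)}
    report = CohortReport(metrics, classes, dist["sagittal"],
                          dist["coronal"], sex_morph, sex_depth,
                          reliability, failures, meta)
    if config.out_dir:
        write_report(report, config.out_dir)
    return report


def _sex_morphology_tables(classes: pd.DataFrame) -> pd.DataFrame:
    """Per segment x plane: 2 x 4 sex-by-class table -> exact p + Cramér's V."""
    from .classify import CLASS_ORDER

    rows = []
    for plane in ("sagittal", "coronal"):
        sub = classes[classes["plane"] == plane]
        for seg in SEGMENTS:
            seg_df = sub[sub["segment"] == seg]
            if seg_df.empty or seg_df["sex"].nunique() < 2:
                continue
            tab = np.zeros((2, 4), dtype=np.int64)
            for i, sex in enumerate(("male", "female")):
                vc = seg_df[seg_df["sex"] == sex]["shape_class"].value_counts()
                for j, cls in enumerate(CLASS_ORDER):
                    tab[i, j] = int(vc.get(cls.value, 0))
            row = {"plane": plane, "segment": seg,
                   "counts_male": tab[0].tolist(),
                   "counts_female": tab[1].tolist()}
            try:
                res = exact_test(tab)
                row.update(p_exact=res.p_exact, chi2=res.chi2,
                           cramers_v=res.cramers_v)
            except UndefinedEffectError as exc:
                row.update(p_exact=np.nan, chi2=np.nan, cramers_v=np.nan,
                           note=str(exc))
            rows.append(row)
    return pd.DataFrame(rows)


def _sex_depth_tables(metrics: pd.DataFrame) -> pd.DataFrame:
    """Per segment x plane: male vs female concavity depth (pooled t)."""
    rows = []
    for plane in ("sagittal", "coronal"):
        sub = metrics[metrics["plane"] == plane]
        for seg in SEGMENTS:
            seg_df = sub[sub["segment"] == seg]
            groups = {}
            for sex in ("male", "female"):
                vals = seg_df[seg_df["sex"] == sex]["concavity_depth"]
                if len(vals) >= 2:
                    groups[sex] = GroupSummary.from_data(vals)
            if len(groups) < 2:
                continue
            g1, g2 = groups["male"], groups["female"]
            res = pooled_t_test(g1, g2)
            rows.append({
                "plane": plane, "segment": seg,
                "n_male": g1.n, "mean_male": g1.mean, "sd_male": g1.sd,
                "n_female": g2.n, "mean_female": g2.mean, "sd_female": g2.sd,
                "t": res.t, "df": res.df, "p": res.p,
                "ci_low": res.ci_low, "ci_high": res.ci_high,
                "cohens_d": res.cohens_d,
            })
    return pd.DataFrame(rows)


def summary_table_stats(depth_csv=None, morphology_csv=None) -> dict:
    """Stats-only mode: recompute the comparison tables from summary CSVs.

    ``depth_csv`` columns: segment, sex, n, mean, sd.
    ``morphology_csv`` columns: segment, sex, + the four class counts.
    Either may be a path or a DataFrame.  Returns DataFrames keyed
    'depth' and 'morphology'.
    """
    from .classify import CLASS_ORDER

    out: dict[str, pd.DataFrame] = {}
    if depth_csv is not None:
        df = depth_csv if isinstance(depth_csv, pd.DataFrame) \
            else pd.read_csv(depth_csv)
        rows = []
        for seg, sub in df.groupby("segment", sort=False):
            sub = sub.set_index("sex")
            g = {s: GroupSummary(int(sub.loc[s, "n"]),
                                 float(sub.loc[s, "mean"]),
                                 float(sub.loc[s, "sd"]))
                 for s in ("male", "female")}
            res = pooled_t_test(g["male"], g["female"])
            rows.append({"segment": seg, "t": res.t, "df": res.df,
                         "p": res.p, "ci_low": res.ci_low,
                         "ci_high": res.ci_high, "cohens_d": res.cohens_d})
        out["depth"] = pd.DataFrame(rows)
    if morphology_csv is not None:
        df = morphology_csv if isinstance(morphology_csv, pd.DataFrame) \
            else pd.read_csv(morphology_csv)
        cols = [c.value for c in CLASS_ORDER]
        rows = []
        for seg, sub in df.groupby("segment", sort=False):
            tab = sub.set_index("sex").loc[["male", "female"], cols] \
                     .to_numpy(dtype=np.int64)
            row = {"segment": seg}
            try:
                res = exact_test(tab)
                row.update(p_exact=res.p_exact, chi2=res.chi2,
                           cramers_v=res.cramers_v)
            except UndefinedEffectError as exc:
                row.update(p_exact=np.nan, chi2=np.nan, cramers_v=np.nan,
                           note=str(exc))
            rows.append(row)
        out["morphology"] = pd.DataFrame(rows)
    return out


def reliability_protocol(records: list[CohortRecord],
                         n_patients_sampled: int = 10,
                         margin_jitter: float = 0.015,
                         landmark_noise: float = 0.05,
                         seed: int = 0) -> pd.DataFrame:
    """Simulated rater-reliability study on a synthetic cohort.

    Samples ``n_patients_sampled`` patients (five endplates each) and
    emulates human raters as perturbed measurement passes: each pass
    draws its own margin-window fraction (Gaussian jitter around the
    default, SD ``margin_jitter``) and adds Gaussian landmark noise
    (SD ``landmark_noise`` mm) to each measured parameter.  Three passes
    are taken — rater 1, rater 2, and rater 1 repeated after an interval —
    and ICC(A,1) is computed per parameter (SCD, CCD, SD, CD) for
    inter-observer (rater 1 vs rater 2) and intra-observer
    (rater 1 vs repeat) agreement.
    """
    patients = sorted({r.patient_id for r in records})
    if len(patients) < n_patients_sampled:
        raise ParameterError(
            f"cohort has {len(patients)} patients, need >= {n_patients_sampled}"
        )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7321]))
    chosen = set(rng.choice(patients, size=n_patients_sampled, replace=False))
    sample = [r for r in records if r.patient_id in chosen]

    profiles = [(extract_profile(r.mesh, "sagittal"),
                 extract_profile(r.mesh, "coronal")) for r in sample]

    def one_pass() -> np.ndarray:
        mf = float(np.clip(rng.normal(DEFAULT_MARGIN_FRACTION, margin_jitter),
                           0.05, 0.45))
        vals = np.empty((len(sample), 4))
        for i, (sag, cor) in enumerate(profiles):
            ms = measure_profile(sag, mf, NOISY_SMOOTH_WINDOW)
            mc = measure_profile(cor, mf, NOISY_SMOOTH_WINDOW)
            vals[i] = [ms.concavity_depth, mc.concavity_depth,
                       ms.chord_length, mc.chord_length]
        if landmark_noise > 0:
            vals = vals + rng.normal(0.0, landmark_noise, size=vals.shape)
        return vals

    rater1, rater2, rater1_repeat = one_pass(), one_pass(), one_pass()

    rows = []
    for j, name in enumerate(RELIABILITY_PARAMS):
        inter = icc_absolute_agreement(
            np.column_stack([rater1[:, j], rater2[:, j]]))
        intra = icc_absolute_agreement(
            np.column_stack([rater1[:, j], rater1_repeat[:, j]]))
        rows.append({"parameter": name, "icc_inter": inter.icc,
                     "icc_intra": intra.icc,
                     "n_endplates": len(sample)})
    return pd.DataFrame(rows)


def write_report(report: CohortReport, out_dir) -> None:
    """Write metrics.csv, classes.csv, tables/*.csv and report.json."""
    out = Path(out_dir)
    (out / "tables").mkdir(parents=True, exist_ok=True)
    report.metrics.to_csv(out / "metrics.csv", index=False)
    report.classes.to_csv(out / "classes.csv", index=False)
    report.distribution_sagittal.to_csv(out / "tables" / "distribution_sagittal.csv")
    report.distribution_coronal.to_csv(out / "tables" / "distribution_coronal.csv")
    report.sex_morphology.to_csv(out / "tables" / "sex_morphology.csv", index=False)
    report.sex_depth.to_csv(out / "tables" / "sex_depth.csv", index=False)
    if report.reliability is not None:
        report.reliability.to_csv(out / "tables" / "reliability.csv", index=False)
    with open(out / "report.json", "w") as fh:
        json.dump(report.to_json_dict(), fh, indent=2, default=float)
    log.info("report written to %s", out)
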