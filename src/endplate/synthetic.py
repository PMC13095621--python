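"""Parametric synthetic endplate profiles, surfaces and cohorts.

Real endplates come from CT reconstructions that are not redistributable,
so the package generates stand-ins with known ground truth.  Each of the
four concavity archetypes has a closed-form profile basis ``B`` over the
chord ``[-L/2, L/2]`` with ``B = 0`` at the endpoints and maximum 1:

* uniform / asymmetric — a raised-cosine bump whose apex sits at a
  configurable offset (fraction of chord) from the centre;
* flat-bottom — a raised cosine clipped to a central plateau covering a
  configurable fraction of the chord;
* flat — the same bump at sub-millimetre depth (or identically zero).

A surface is the height field
``h(x, y) = -(D_sag * B_sag(y) + D_cor * B_cor(x))`` over an elliptical
plate.  The cross-plane term is constant along each mid-line, so the
mid-sagittal profile realizes depth ``D_sag`` exactly and the mid-coronal
profile ``D_cor`` (chord-relative depth is unaffected by a uniform
offset).  The regular (resolution x resolution) grid is carried onto the
ellipse by the area mapping
``(x, y) = (a*p*sqrt(1 - q^2/2), b*q*sqrt(1 - p^2/2))`` so the
triangulation keeps exactly ``2*(resolution-1)^2`` faces while the
boundary is the exact ellipse.

Default plate semi-axes are 25 mm (anterior-posterior) by 17 mm
(lateral), a typical lower-lumbar endplate footprint; surface noise
defaults to zero and is configurable as an additive Gaussian on vertex
heights.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .classify import ShapeClass
from .errors import ParameterError
from .mesh_io import AnatomicalFrame, TriangleMesh, write_stl
from .profiles import END_LABELS, Profile

#: default plate semi-axes, mm
DEFAULT_SEMI_AXIS_AP = 25.0
DEFAULT_SEMI_AXIS_LAT = 17.0

SEGMENTS = ("L4_sup", "L4_inf", "L5_sup", "L5_inf", "S1_sup")

_CONCAVE = (ShapeClass.UNIFORM_CONCAVE, ShapeClass.ASYMMETRIC_CONCAVE,
            ShapeClass.FLAT_BOTTOM)


def offset_length_ratio(apex_offset: float) -> float:
    """Margin-to-apex length ratio induced by an apex offset (fraction of
    chord), ignoring the small vertical contribution."""
    o = abs(apex_offset)
    if o >= 0.5:
        raise ParameterError("apex offset must lie in (-0.5, 0.5)")
    return (0.5 + o) / (0.5 - o)


@dataclass(frozen=True)
class SyntheticEndplateSpec:
    """Ground-truth description of one synthetic endplate surface."""

    shape_class_sagittal: ShapeClass = ShapeClass.UNIFORM_CONCAVE
    shape_class_coronal: ShapeClass = ShapeClass.UNIFORM_CONCAVE
    depth_sagittal: float = 2.0          # mm
    depth_coronal: float = 2.0           # mm
    apex_offset_sagittal: float = 0.0    # fraction of chord, (-0.5, 0.5)
    apex_offset_coronal: float = 0.0
    plateau_fraction: float = 0.4        # chord fraction of the flat floor
    semi_axis_ap: float = DEFAULT_SEMI_AXIS_AP
    semi_axis_lat: float = DEFAULT_SEMI_AXIS_LAT
    noise_sd: float = 0.0                # mm
    resolution: int = 64                 # grid points per axis
    seed: int = 0

    def __post_init__(self):
        # accept plain strings for the class fields
        object.__setattr__(self, "shape_class_sagittal",
                           ShapeClass(self.shape_class_sagittal))
        object.__setattr__(self, "shape_class_coronal",
                           ShapeClass(self.shape_class_coronal))
        if self.resolution < 16:
            raise ParameterError("resolution must be >= 16")
        if self.semi_axis_ap <= 0 or self.semi_axis_lat <= 0:
            raise ParameterError("semi-axes must be positive")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if not 0 <= self.plateau_fraction < 1:
            raise ParameterError("plateau_fraction must lie in [0, 1)")
        for cls, depth, off, plane in (
            (self.shape_class_sagittal, self.depth_sagittal,
             self.apex_offset_sagittal, "sagittal"),
            (self.shape_class_coronal, self.depth_coronal,
             self.apex_offset_coronal, "coronal"),
        ):
            if depth < 0:
                raise ParameterError(f"{plane} depth must be >= 0")
            if cls is ShapeClass.FLAT and depth >= 1.0:
                raise ParameterError(
                    f"{plane}: flat class requires depth < 1 mm, got {depth}"
                )
            if cls in _CONCAVE and depth < 1.0:
                raise ParameterError(
                    f"{plane}: concave class requires depth >= 1 mm, got {depth}"
                )
            ratio = offset_length_ratio(off)
            if cls is ShapeClass.ASYMMETRIC_CONCAVE and ratio < 1.3:
                raise ParameterError(
                    f"{plane}: asymmetric class needs offset-induced ratio "
                    f">= 1.3, got {ratio:.3f}"
                )
            if cls is ShapeClass.UNIFORM_CONCAVE and ratio >= 1.3:
                raise ParameterError(
                    f"{plane}: uniform class needs offset-induced ratio "
                    f"< 1.3, got {ratio:.3f}"
                )


def _bump(s: np.ndarray, half: float, offset_frac: float) -> np.ndarray:
    """Raised-cosine bump on [-half, half], apex at offset_frac*2*half."""
    c = offset_frac * 2.0 * half
    out = np.zeros_like(s, dtype=float)
    left = s <= c
    out[left] = 0.5 * (1 - np.cos(np.pi * (s[left] + half) / (c + half)))
    out[~left] = 0.5 * (1 - np.cos(np.pi * (half - s[~left]) / (half - c)))
    return np.clip(out, 0.0, 1.0)


def _plateau_bump(s: np.ndarray, half: float, plateau_frac: float) -> np.ndarray:
    """Symmetric raised cosine clipped to a central plateau of the given
    chord fraction."""
    b0 = 0.5 * (1 + np.cos(np.pi * s / half))
    sp = plateau_frac * half
    denom = 0.5 * (1 + np.cos(np.pi * sp / half))
    if denom <= 0:
        return b0
    return np.minimum(1.0, b0 / denom)


def _basis(s: np.ndarray, half: float, cls: ShapeClass, offset: float,
           plateau_frac: float) -> np.ndarray:
    if cls is ShapeClass.FLAT_BOTTOM:
        return _plateau_bump(s, half, plateau_frac)
    # flat uses the same bump shape; its sub-mm depth makes it flat by rule
    return _bump(s, half, offset)


def generate_profile(spec: SyntheticEndplateSpec, plane: str) -> Profile:
    """Generate the mid-plane profile of a spec directly in 2D."""
    if plane not in END_LABELS:
        raise ParameterError(f"plane must be 'sagittal' or 'coronal', got {plane!r}")
    if plane == "sagittal":
        half = spec.semi_axis_ap
        cls, depth, off = (spec.shape_class_sagittal, spec.depth_sagittal,
                           spec.apex_offset_sagittal)
    else:
        half = spec.semi_axis_lat
        cls, depth, off = (spec.shape_class_coronal, spec.depth_coronal,
                           spec.apex_offset_coronal)
    s = np.linspace(-half, half, spec.resolution)
    h = -depth * _basis(s, half, cls, off, spec.plateau_fraction)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(
            np.random.SeedSequence([spec.seed, 0 if plane == "sagittal" else 1])
        )
        h = h + rng.normal(0.0, spec.noise_sd, size=h.shape)
    return Profile(s, h, plane=plane, end_labels=END_LABELS[plane])


def analytic_height(spec: SyntheticEndplateSpec, x: np.ndarray,
                    y: np.ndarray) -> np.ndarray:
    """Noise-free height field h(x, y) of a spec (x lateral, y AP, mm)."""
    b_sag = _basis(np.asarray(y, float), spec.semi_axis_ap,
                   spec.shape_class_sagittal, spec.apex_offset_sagittal,
                   spec.plateau_fraction)
    b_cor = _basis(np.asarray(x, float), spec.semi_axis_lat,
                   spec.shape_class_coronal, spec.apex_offset_coronal,
                   spec.plateau_fraction)
    return -(spec.depth_sagittal * b_sag + spec.depth_coronal * b_cor)


def generate_surface(spec: SyntheticEndplateSpec,
                     frame: AnatomicalFrame | None = None) -> TriangleMesh:
    """Generate a triangulated endplate surface for a spec.

    The mesh is a (resolution x resolution) grid carried onto an ellipse
    (semi-axes ``semi_axis_lat`` x ``semi_axis_ap``), triangulated into
    exactly ``2*(resolution-1)^2`` faces, with the archetype height field
    plus optional Gaussian vertex noise.  Deterministic for a fixed seed.
    """
    frame = frame or AnatomicalFrame()
    n = spec.resolution
    p = np.linspace(-1.0, 1.0, n)
    P, Q = np.meshgrid(p, p, indexing="ij")
    x = spec.semi_axis_lat * P * np.sqrt(1 - Q**2 / 2)
    y = spec.semi_axis_ap * Q * np.sqrt(1 - P**2 / 2)
    h = analytic_height(spec, x, y)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
        h = h + rng.normal(0.0, spec.noise_sd, size=h.shape)

    coords = np.zeros((n * n, 3))
    coords[:, frame.axis_index("lateral")] = frame.axis_sign("lateral") * x.ravel()
    coords[:, frame.axis_index("ap")] = frame.axis_sign("ap") * y.ravel()
    coords[:, frame.axis_index("si")] = frame.axis_sign("si") * h.ravel()

    idx = np.arange(n * n).reshape(n, n)
    a = idx[:-1, :-1].ravel()
    b = idx[1:, :-1].ravel()
    c = idx[:-1, 1:].ravel()
    d = idx[1:, 1:].ravel()
    faces = np.concatenate([np.column_stack([a, b, d]),
                            np.column_stack([a, d, c])])
    return TriangleMesh(coords, faces, frame)


@dataclass
class CohortRecord:
    """One synthetic endplate with its ground truth."""

    patient_id: str
    sex: str                     # 'male' or 'female'
    segment: str
    spec: SyntheticEndplateSpec
    mesh: TriangleMesh = field(repr=False)

    @property
    def true_sagittal_class(self) -> ShapeClass:
        return self.spec.shape_class_sagittal

    @property
    def true_coronal_class(self) -> ShapeClass:
        return self.spec.shape_class_coronal


def _default_class_mix() -> dict:
    """Per-segment class mixes matching the observed form distributions of
    the reference cohort (see :mod:`endplate.reference`)."""
    from .reference import load_form_distribution

    mixes: dict[str, dict[str, np.ndarray]] = {}
    for plane in ("sagittal", "coronal"):
        tab = load_form_distribution(plane)
        for seg in SEGMENTS:
            row = tab.loc[seg].to_numpy(dtype=float)
            mixes.setdefault(seg, {})[plane] = row / row.sum()
    return mixes


def _sample_plane_params(rng: np.random.Generator, cls: ShapeClass):
    """Depth and apex offset for a sampled class, kept >= 10% clear of the
    1 mm depth and 1.3 ratio decision boundaries."""
    if cls is ShapeClass.FLAT:
        depth = rng.uniform(0.10, 0.85)
    else:
        depth = rng.uniform(1.15, 3.2)
    if cls is ShapeClass.ASYMMETRIC_CONCAVE:
        offset = rng.choice([-1.0, 1.0]) * rng.uniform(0.12, 0.22)
    else:
        offset = rng.uniform(-0.03, 0.03)
    return float(depth), float(offset)


def make_endplate_spec(rng: np.random.Generator,
                       sag_class: ShapeClass, cor_class: ShapeClass,
                       noise_sd: float, resolution: int,
                       seed: int) -> SyntheticEndplateSpec:
    d_sag, o_sag = _sample_plane_params(rng, sag_class)
    d_cor, o_cor = _sample_plane_params(rng, cor_class)
    return SyntheticEndplateSpec(
        shape_class_sagittal=sag_class, shape_class_coronal=cor_class,
        depth_sagittal=d_sag, depth_coronal=d_cor,
        apex_offset_sagittal=o_sag, apex_offset_coronal=o_cor,
        plateau_fraction=float(rng.uniform(0.35, 0.5)),
        semi_axis_ap=float(DEFAULT_SEMI_AXIS_AP * rng.uniform(0.9, 1.1)),
        semi_axis_lat=float(DEFAULT_SEMI_AXIS_LAT * rng.uniform(0.9, 1.1)),
        noise_sd=noise_sd, resolution=resolution, seed=seed,
    )


def generate_cohort(n_patients: int, class_mix: dict | None = None,
                    seed: int = 0, noise_sd: float = 0.05,
                    resolution: int = 64,
                    male_fraction: float = 19 / 33) -> list[CohortRecord]:
    """Generate a synthetic cohort: five endplates per patient
    (L4 sup/inf, L5 sup/inf, S1 sup).

    ``class_mix`` maps segment -> {'sagittal': probs, 'coronal': probs}
    over the four classes in canonical order; the default reproduces the
    reference cohort's observed per-segment distributions.  Each endplate
    draws from a stream derived from (seed, patient, segment), so cohorts
    are reproducible and order independent.
    """
    if n_patients < 1:
        raise ParameterError("n_patients must be >= 1")
    from .classify import CLASS_ORDER

    mixes = class_mix if class_mix is not None else _default_class_mix()
    for seg in SEGMENTS:
        if seg not in mixes:
            raise ParameterError(f"class_mix lacks segment {seg}")
        for plane in ("sagittal", "coronal"):
            probs = np.asarray(mixes[seg][plane], dtype=float)
            if probs.shape != (4,) or probs.min() < 0 or \
                    abs(probs.sum() - 1.0) > 1e-9:
                raise ParameterError(
                    f"class_mix[{seg}][{plane}] must be 4 probabilities summing to 1"
                )

    records: list[CohortRecord] = []
    for pi in range(n_patients):
        sex_rng = np.random.default_rng(np.random.SeedSequence([seed, pi, 999]))
        sex = "male" if sex_rng.random() < male_fraction else "female"
        for si, seg in enumerate(SEGMENTS):
            rng = np.random.default_rng(np.random.SeedSequence([seed, pi, si]))
            sub_seed = int(rng.integers(0, 2**31 - 1))
            sag_cls = CLASS_ORDER[rng.choice(4, p=mixes[seg]["sagittal"])]
            cor_cls = CLASS_ORDER[rng.choice(4, p=mixes[seg]["coronal"])]
            spec = make_endplate_spec(rng, sag_cls, cor_cls, noise_sd,
                                      resolution, sub_seed)
            mesh = generate_surface(spec)
            records.append(CohortRecord(f"P{pi:03d}", sex, seg, spec, mesh))
    return records


def write_cohort(records: list[CohortRecord], outdir,
                 dialect: str = "binary") -> pd.DataFrame:
    """Write a cohort as STL files plus a manifest CSV; returns the manifest."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        fname = f"{rec.patient_id}_{rec.segment}.stl"
        write_stl(rec.mesh, outdir / fname, dialect=dialect)
        rows.append({
            "patient": rec.patient_id, "sex": rec.sex, "segment": rec.segment,
            "file": fname,
            "true_sagittal_class": rec.spec.shape_class_sagittal.value,
            "true_coronal_class": rec.spec.shape_class_coronal.value,
            "true_depth_sagittal": rec.spec.depth_sagittal,
            "true_depth_coronal": rec.spec.depth_coronal,
            "seed": rec.spec.seed,
        })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest


def perturbed(spec: SyntheticEndplateSpec, **changes) -> SyntheticEndplateSpec:
    """Convenience: a copy of a spec with fields replaced."""
    return replace(spec, **changes)
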