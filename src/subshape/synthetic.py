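"""Synthetic corresponded-surface cohorts with implanted group effects.

Real subcortical surface cohorts require MRI segmentation, which this
package does not do.  This module generates a stand-in: parametric
genus-0 templates (ellipsoids; bent tubes for the caudate and
hippocampus), per-subject surfaces in exact vertex correspondence with
the template, a covariate table whose marginals default to an elderly
HIV case-control cohort (63 cases / 31 controls), and a ground-truth
record of every implanted effect so that recovery can be tested.

Subject surfaces are built from the template by (1) a global isotropic
scale (ICV / ICV_ref)^(1/3), (2) a smooth random normal-direction
displacement field, and (3) each applicable effect: a patch displacement
of amplitude * RD_template * window, or a global volume rescaling.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh as _trimesh
from scipy import sparse
from scipy.sparse.csgraph import dijkstra
from scipy.stats import truncnorm

from .mesh import (
    CorrespondedSurface,
    TriangleMesh,
    enclosed_volume,
    save_mesh,
    vertex_normals,
)

__all__ = [
    "STRUCTURES",
    "SHAPE_STRUCTURES",
    "VOLUME_ONLY_STRUCTURES",
    "EffectSpec",
    "GroundTruth",
    "default_effect_menu",
    "suggest_patch_center",
    "CohortConfig",
    "CohortBundle",
    "make_template",
    "template_centerline",
    "simulate_covariates",
    "simulate_subject",
    "simulate_cohort",
    "geodesic_distances",
]

# ---------------------------------------------------------------------------
# Templates
# ---------------------------------------------------------------------------

# (axis ratios a:b:c, target volume mm^3, bend radius in multiples of the
# half-length a, or None for a plain ellipsoid).  Target volumes follow
# typical adult unilateral values for the grey structures; the midline
# volumes follow the control means implied by elderly case-control cohorts.
_BASE_SPECS: dict[str, tuple[tuple[float, float, float], float, float | None]] = {
    "thalamus": ((1.7, 1.0, 0.9), 6600.0, None),
    "caudate": ((4.0, 0.85, 0.85), 3600.0, 2.2),
    "putamen": ((2.2, 1.0, 0.8), 4900.0, None),
    "pallidum": ((1.9, 1.0, 0.8), 1700.0, None),
    "hippocampus": ((3.2, 1.0, 0.8), 3700.0, 2.6),
    "amygdala": ((1.3, 1.0, 0.9), 1600.0, None),
    "accumbens": ((1.5, 1.0, 0.8), 550.0, None),
}
_MIDLINE_SPECS: dict[str, tuple[tuple[float, float, float], float, float | None]] = {
    "callosum": ((3.2, 1.0, 0.35), 2710.0, 2.5),
    "left_lateral_ventricle": ((3.0, 1.0, 0.55), 40000.0, 2.8),
    "right_lateral_ventricle": ((3.0, 1.0, 0.55), 48000.0, 2.8),
    "third_ventricle": ((2.4, 0.7, 1.0), 2700.0, None),
}

SHAPE_STRUCTURES = tuple(
    f"{side}_{name}" for name in _BASE_SPECS for side in ("left", "right")
)
VOLUME_ONLY_STRUCTURES = tuple(_MIDLINE_SPECS)
STRUCTURES = SHAPE_STRUCTURES + VOLUME_ONLY_STRUCTURES


def _spec_for(structure_id: str):
    if structure_id in _MIDLINE_SPECS:
        return _MIDLINE_SPECS[structure_id], None
    for side in ("left", "right"):
        prefix = side + "_"
        if structure_id.startswith(prefix) and structure_id[len(prefix):] in _BASE_SPECS:
            return _BASE_SPECS[structure_id[len(prefix):]], side
    raise ValueError(
        f"unknown structure {structure_id!r}; supported: {sorted(STRUCTURES)}"
    )


def _semi_axes(ratios, volume):
    a, b, c = ratios
    s = (volume * 3.0 / (4.0 * np.pi * a * b * c)) ** (1.0 / 3.0)
    return a * s, b * s, c * s


def _bend(points: np.ndarray, half_length: float, bend_mult: float) -> np.ndarray:
    """Bend along x around a circular arc of radius R = bend_mult * half_length."""
    R = bend_mult * half_length
    x, y, z = points.T
    theta = x / R
    out = np.empty_like(points)
    out[:, 0] = (R - z) * np.sin(theta)
    out[:, 1] = y
    out[:, 2] = R - (R - z) * np.cos(theta)
    return out


def make_template(structure_id: str, resolution: int = 3) -> TriangleMesh:
    """Deterministic genus-0 template mesh for one subcortical structure.

    ``resolution`` is the icosphere subdivision level (level 3 -> 642
    vertices, level 4 -> 2562).  Elongated structures (caudate,
    hippocampus, callosum, lateral ventricles) are bent tubes; the rest
    are ellipsoids.  Left/right templates are mirror-symmetric.
    """
    (ratios, volume, bend_mult), side = _spec_for(structure_id)
    ico = _trimesh.creation.icosphere(subdivisions=resolution, radius=1.0)
    v = np.asarray(ico.vertices, float)
    f = np.asarray(ico.faces, np.int64)
    a, b, c = _semi_axes(ratios, volume)
    v = v * np.array([a, b, c])
    if bend_mult is not None:
        v = _bend(v, a, bend_mult)
        v -= v.mean(axis=0)
    if side == "right":
        v = v * np.array([1.0, -1.0, 1.0])  # mirror across midline plane
        f = f[:, ::-1]  # restore outward orientation
    mesh = TriangleMesh(structure_id, v, f)
    return mesh.validate()


def template_centerline(structure_id: str, n_points: int = 200) -> np.ndarray:
    """True generating centerline of a bent-tube template (for validation).

    For ellipsoid templates this is the major-axis segment.
    """
    (ratios, volume, bend_mult), side = _spec_for(structure_id)
    a, b, c = _semi_axes(ratios, volume)
    x = np.linspace(-a, a, n_points)
    pts = np.column_stack([x, np.zeros(n_points), np.zeros(n_points)])
    if bend_mult is not None:
        pts = _bend(pts, a, bend_mult)
        # same recentring as make_template: subtract bent ellipsoid centroid
        ico = _trimesh.creation.icosphere(subdivisions=3, radius=1.0)
        ref = _bend(np.asarray(ico.vertices) * np.array([a, b, c]), a, bend_mult)
        pts -= ref.mean(axis=0)
    if side == "right":
        pts = pts * np.array([1.0, -1.0, 1.0])
    return pts


# ---------------------------------------------------------------------------
# Covariates
# ---------------------------------------------------------------------------

#: Default covariate marginals for an elderly HIV case-control cohort.
COVARIATE_DEFAULTS = {
    "n_cases": 63,
    "n_controls": 31,
    "age_case": (64.68, 4.57),
    "age_control": (65.35, 2.21),
    "female_frac_case": 2 / 63,
    "female_frac_control": 4 / 31,
    "icv": (1.45e6, 1.3e5),  # mm^3
    "ncd4": (204.96, 154.85),  # cells/mm^3, truncated > 0
    "tsd": (20.39, 6.31),  # years, truncated > 0
    "viral_detectable_frac": 24 / 63,
    "hand_frac_case": 30 / 63,
    "drug_frac_case": 15 / 63,
    "wais_case": (48.77, 10.73),
    "wais_control": (57.27, 7.48),
    "wais_missing_case": 6 / 63,
    "wais_missing_control": 9 / 31,
    "wrat_case": (64.05, 4.26),
    "wrat_control": (66.50, 1.93),
    "wrat_missing_case": 6 / 63,
    "wrat_missing_control": 11 / 31,
    "education_case": (16.09, 2.25),
    "education_control": (17.53, 2.09),
    "apoe_frac_case": 12 / 63,
    "apoe_frac_control": 6 / 31,
}

CLINICAL_CASE_ONLY = ("nCD4", "TSD", "ViralDetectable")


def _trunc_normal(rng, mean, sd, size, lower=0.0):
    a = (lower - mean) / sd
    return truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def _exact_binary(rng, mask: np.ndarray, frac: float) -> np.ndarray:
    """Binary indicator with an exact count round(frac * n) within ``mask``.

    Mirrors cohort tables that report counts (e.g. 2/63 female) rather
    than rates, and keeps small designs estimable.
    """
    out = np.zeros(len(mask))
    idx = np.flatnonzero(mask)
    k = int(round(frac * len(idx)))
    out[rng.permutation(idx)[:k]] = 1.0
    return out


def simulate_covariates(n_cases: int, n_controls: int, seed: int = 0,
                        **overrides) -> pd.DataFrame:
    """Simulate a subject covariate table.

    Marginals default to :data:`COVARIATE_DEFAULTS` (elderly HIV cohort);
    any key can be overridden.  Clinical fields undefined for controls
    (nCD4, TSD, ViralDetectable) are NaN, never silently zero.
    """
    if n_cases < 1 or n_controls < 1:
        raise ValueError("n_cases and n_controls must be >= 1")
    p = dict(COVARIATE_DEFAULTS)
    p.update(overrides)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC0]))
    n = n_cases + n_controls
    case = np.concatenate([np.ones(n_cases, bool), np.zeros(n_controls, bool)])

    age = np.where(
        case,
        rng.normal(*p["age_case"], size=n),
        rng.normal(*p["age_control"], size=n),
    )
    female = _exact_binary(rng, case, p["female_frac_case"]) + _exact_binary(
        rng, ~case, p["female_frac_control"]
    )
    icv = _trunc_normal(rng, *p["icv"], size=n, lower=0.5 * p["icv"][0])
    ncd4 = np.where(case, _trunc_normal(rng, *p["ncd4"], size=n), np.nan)
    tsd = np.where(case, _trunc_normal(rng, *p["tsd"], size=n), np.nan)
    viral = np.where(case, _exact_binary(rng, case, p["viral_detectable_frac"]), np.nan)
    hand = np.where(case, _exact_binary(rng, case, p["hand_frac_case"]), 0.0)
    drug = np.where(case, _exact_binary(rng, case, p["drug_frac_case"]), 0.0)

    def _score(case_params, control_params, miss_case, miss_control):
        vals = np.where(
            case,
            rng.normal(*case_params, size=n),
            rng.normal(*control_params, size=n),
        )
        miss = _exact_binary(rng, case, miss_case) + _exact_binary(rng, ~case, miss_control)
        return np.where(miss > 0, np.nan, vals)

    wais = _score(p["wais_case"], p["wais_control"],
                  p["wais_missing_case"], p["wais_missing_control"])
    wrat = _score(p["wrat_case"], p["wrat_control"],
                  p["wrat_missing_case"], p["wrat_missing_control"])
    edu = np.where(
        case,
        rng.normal(*p["education_case"], size=n),
        rng.normal(*p["education_control"], size=n),
    )
    apoe = _exact_binary(rng, case, p["apoe_frac_case"]) + _exact_binary(
        rng, ~case, p["apoe_frac_control"]
    )

    df = pd.DataFrame(
        {
            "subject_id": [f"sub-{i:04d}" for i in range(n)],
            "HIVStatus": case.astype(int),
            "Age": age,
            "Sex": female.astype(int),
            "ICV": icv,
            "nCD4": ncd4,
            "TSD": tsd,
            "ViralDetectable": viral,
            "HAND": hand,
            "DrugHistory": drug,
            "WAIS": wais,
            "WRAT": wrat,
            "AdjEducation": edu,
            "APOE": apoe,
        }
    )
    return df


# ---------------------------------------------------------------------------
# Effects and ground truth
# ---------------------------------------------------------------------------

@dataclass
class EffectSpec:
    """One implanted morphometric effect.

    ``effect_type='thickness'`` displaces patch vertices along template
    normals by amplitude * RD_template * window(geodesic distance);
    negative amplitude is inward atrophy.  ``effect_type='volume'``
    rescales the whole structure so its volume changes by ``amplitude``
    (fraction, e.g. -0.107 for a 10.7% deficit).  Binary predictors
    activate the effect for subjects with predictor value 1; continuous
    predictors scale it by the standardized predictor value.
    """

    structure_id: str
    amplitude: float
    predictor: str = "HIVStatus"
    effect_type: str = "thickness"
    patch_center: int = 0
    patch_radius: float = 10.0  # geodesic mm

    def __post_init__(self) -> None:
        if not abs(self.amplitude) < 0.5:
            raise ValueError("|amplitude| must be < 0.5")
        if self.effect_type not in ("thickness", "volume"):
            raise ValueError("effect_type must be 'thickness' or 'volume'")


@dataclass
class GroundTruthEntry:
    structure_id: str
    predictor: str
    effect_type: str
    mask: np.ndarray  # bool, per template vertex (empty for volume effects)
    true_displacement: np.ndarray  # mm at unit activation, per vertex
    volume_change_pct: float

    def to_jsonable(self):
        return {
            "structure_id": self.structure_id,
            "predictor": self.predictor,
            "effect_type": self.effect_type,
            "mask": np.flatnonzero(self.mask).tolist(),
            "n_vertices": int(len(self.mask)),
            "volume_change_pct": self.volume_change_pct,
        }


@dataclass
class GroundTruth:
    entries: list[GroundTruthEntry] = field(default_factory=list)

    def masks_for(self, structure_id: str):
        return [e for e in self.entries if e.structure_id == structure_id]


def geodesic_distances(mesh: TriangleMesh, source: int) -> np.ndarray:
    """Graph-geodesic distance (edge-length Dijkstra) from one vertex."""
    e = mesh.undirected_edges()
    w = np.linalg.norm(mesh.vertices[e[:, 0]] - mesh.vertices[e[:, 1]], axis=1)
    n = mesh.n_vertices
    g = sparse.coo_matrix((w, (e[:, 0], e[:, 1])), shape=(n, n))
    return dijkstra(g.tocsr(), directed=False, indices=source)


def suggest_patch_center(template: TriangleMesh, n_sections: int = 12) -> int:
    """Canonical thickness-patch placement: the template's thickest vertex.

    A focal atrophy patch modelled as "percent thickness" loss belongs
    where there is tissue to lose; vertices near the medial curve carry
    sub-mm absolute effects that no realistic cohort size can detect.
    Returns the index of the vertex with maximal template radial
    distance.
    """
    from .features import medial_curve, radial_distance

    curve = medial_curve(template, n_sections=n_sections)
    return int(np.argmax(radial_distance(template, curve).values))


def default_effect_menu() -> tuple:
    """Volume-effect menu matching the study's reported group differences.

    Signs and magnitudes follow the reported case-control percent volume
    differences: grey-matter deficits (callosum -10.7%, left pallidum
    -7.6%, left putamen -5.7%, left thalamus -5.9%, right thalamus
    -6.3%) and ventricular enlargement (left lateral +12.7%, right
    lateral +8%, third +15.5%).
    """
    menu = [
        ("callosum", -0.107),
        ("left_pallidum", -0.076),
        ("left_putamen", -0.057),
        ("left_thalamus", -0.059),
        ("right_thalamus", -0.063),
        ("left_lateral_ventricle", 0.127),
        ("right_lateral_ventricle", 0.08),
        ("third_ventricle", 0.155),
    ]
    return tuple(
        EffectSpec(s, a, predictor="HIVStatus", effect_type="volume")
        for s, a in menu
    )


PATCH_PLATEAU = 0.6  # fraction of the radius at full amplitude


def _patch_window(mesh: TriangleMesh, center: int, radius: float) -> np.ndarray:
    """Focal-patch weight: 1 on the inner plateau, cosine taper to 0 at the rim."""
    d = geodesic_distances(mesh, center)
    w = np.zeros(mesh.n_vertices)
    r0 = PATCH_PLATEAU * radius
    w[d <= r0] = 1.0
    rim = (d > r0) & (d < radius)
    w[rim] = 0.5 * (1.0 + np.cos(np.pi * (d[rim] - r0) / (radius - r0)))
    return w


# ---------------------------------------------------------------------------
# Subject simulation
# ---------------------------------------------------------------------------

ICV_REF = COVARIATE_DEFAULTS["icv"][0]


class _TemplateCache:
    """Per-template precomputations reused across subjects."""

    def __init__(self, template: TriangleMesh):
        from .features import medial_curve, radial_distance  # local import: no cycle at module load

        self.template = template
        self.normals = vertex_normals(template)
        curve = medial_curve(template, n_sections=12)
        self.rd = radial_distance(template, curve).values
        e = template.undirected_edges()
        n = template.n_vertices
        adj = sparse.coo_matrix(
            (np.ones(2 * len(e)), (np.r_[e[:, 0], e[:, 1]], np.r_[e[:, 1], e[:, 0]])),
            shape=(n, n),
        ).tocsr()
        deg = np.asarray(adj.sum(axis=1)).ravel()
        self.smooth = sparse.diags(1.0 / deg) @ adj  # row-normalized adjacency
        self._windows: dict[tuple[int, float], np.ndarray] = {}

    def window(self, center: int, radius: float) -> np.ndarray:
        key = (center, radius)
        if key not in self._windows:
            self._windows[key] = _patch_window(self.template, center, radius)
        return self._windows[key]


def _smooth_noise(cache: _TemplateCache, rng: np.random.Generator,
                  sd: float, n_iter: int) -> np.ndarray:
    if sd <= 0:
        return np.zeros(cache.template.n_vertices)
    d = rng.standard_normal(cache.template.n_vertices)
    for _ in range(n_iter):
        d = 0.5 * d + 0.5 * (cache.smooth @ d)
    s = d.std()
    return d / (s if s > 0 else 1.0) * sd


def _activation(effect: EffectSpec, row: pd.Series, standardizers: dict) -> float:
    val = row.get(effect.predictor, np.nan)
    if val is None or (isinstance(val, float) and np.isnan(val)):
        return 0.0
    mu, sigma = standardizers.get(effect.predictor, (0.0, 1.0))
    if sigma > 0 and effect.predictor in CONTINUOUS_PREDICTORS:
        return float((val - mu) / sigma)
    return float(val)


CONTINUOUS_PREDICTORS = ("Age", "ICV", "nCD4", "TSD", "WAIS", "WRAT", "AdjEducation")

#: standardizers used when an effect is driven by a continuous predictor
_DEFAULT_STANDARDIZERS = {
    "TSD": COVARIATE_DEFAULTS["tsd"],
    "nCD4": COVARIATE_DEFAULTS["ncd4"],
    "WAIS": COVARIATE_DEFAULTS["wais_case"],
    "WRAT": COVARIATE_DEFAULTS["wrat_case"],
    "Age": COVARIATE_DEFAULTS["age_case"],
}


def simulate_subject(
    template: TriangleMesh,
    covariate_row: pd.Series,
    effects=(),
    noise_sd: float = 0.5,
    seed: int = 0,
    *,
    cache: _TemplateCache | None = None,
    noise_smooth_iters: int = 10,
    icv_ref: float = ICV_REF,
) -> CorrespondedSurface:
    """Simulate one subject surface in correspondence with its template.

    The subject inherits the template's face list; vertices are displaced
    along template normals by smooth noise plus any active effects, then
    scaled globally by (ICV / icv_ref)^(1/3) and any volume effects.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    for eff in effects:
        if eff.structure_id != template.structure_id:
            raise ValueError(
                f"effect targets {eff.structure_id!r}, template is {template.structure_id!r}"
            )
    if cache is None:
        cache = _TemplateCache(template)
    rng = np.random.default_rng(seed)
    disp = _smooth_noise(cache, rng, noise_sd, noise_smooth_iters)
    vol_scale = 1.0
    for eff in effects:
        act = _activation(eff, covariate_row, _DEFAULT_STANDARDIZERS)
        if act == 0.0:
            continue
        if eff.effect_type == "thickness":
            w = cache.window(eff.patch_center, eff.patch_radius)
            disp = disp + eff.amplitude * act * cache.rd * w
        else:
            vol_scale *= max(1.0 + eff.amplitude * act, 0.05)
    icv = covariate_row.get("ICV", icv_ref)
    scale = (float(icv) / icv_ref) ** (1.0 / 3.0) * vol_scale ** (1.0 / 3.0)
    center = template.vertices.mean(axis=0)
    verts = template.vertices + disp[:, None] * cache.normals
    verts = center + (verts - center) * scale
    mesh = TriangleMesh(template.structure_id, verts, template.faces.copy())
    return CorrespondedSurface(mesh, template.structure_id)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Study-condition parameters for a simulated cohort."""

    n_cases: int = 63
    n_controls: int = 31
    structures: tuple = ("left_thalamus",)
    resolution: int = 3
    effects: tuple = ()
    noise_sd: float = 0.5  # mm, per-vertex displacement SD
    noise_smooth_iters: int = 10
    covariate_overrides: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        effects = tuple(
            e if isinstance(e, EffectSpec) else EffectSpec(**e)
            for e in d.pop("effects", ())
        )
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown cohort config field(s): {sorted(unknown)}")
        cfg = cls(effects=effects, **d)
        cfg.structures = tuple(cfg.structures)
        if len(cfg.structures) < 1:
            raise ValueError("cohort config must name at least one structure")
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["effects"] = [asdict(e) for e in self.effects]
        d["structures"] = list(self.structures)
        return d


@dataclass
class CohortBundle:
    """In-memory cohort: templates, per-subject surfaces, covariates, truth."""

    config: CohortConfig
    seed: int
    covariates: pd.DataFrame
    templates: dict[str, TriangleMesh]
    surfaces: dict[str, dict[str, CorrespondedSurface]]  # subject -> structure
    ground_truth: GroundTruth

    @property
    def subject_ids(self):
        return list(self.covariates["subject_id"])

    def write(self, outdir) -> dict:
        """Persist to a run directory; returns the manifest dict."""
        out = Path(outdir)
        (out / "meshes").mkdir(parents=True, exist_ok=True)
        files = {}
        cov_path = out / "covariates.csv"
        self.covariates.to_csv(cov_path, index=False)
        files["covariates.csv"] = _sha256(cov_path)
        for sid, struct in self.templates.items():
            p = out / "meshes" / f"template_{sid}.ply"
            save_mesh(struct, p)
            files[str(p.relative_to(out))] = _sha256(p)
        for sub, structs in self.surfaces.items():
            d = out / "meshes" / sub
            d.mkdir(exist_ok=True)
            for sid, surf in structs.items():
                p = d / f"{sid}.ply"
                save_mesh(surf.mesh, p)
                files[str(p.relative_to(out))] = _sha256(p)
        gt_path = out / "ground_truth.json"
        gt_path.write_text(
            json.dumps([e.to_jsonable() for e in self.ground_truth.entries], indent=1)
        )
        files["ground_truth.json"] = _sha256(gt_path)
        manifest = {
            "seed": self.seed,
            "config": self.config.to_dict(),
            "files": files,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        return manifest


    @classmethod
    def load(cls, rundir) -> "CohortBundle":
        """Reload a cohort persisted by :meth:`write`."""
        from .mesh import load_mesh

        rundir = Path(rundir)
        manifest = json.loads((rundir / "manifest.json").read_text())
        config = CohortConfig.from_dict(manifest["config"])
        cov = pd.read_csv(rundir / "covariates.csv")
        templates = {
            sid: load_mesh(rundir / "meshes" / f"template_{sid}.ply", structure_id=sid)
            for sid in config.structures
        }
        surfaces: dict[str, dict[str, CorrespondedSurface]] = {}
        for sub in cov["subject_id"]:
            surfaces[sub] = {
                sid: CorrespondedSurface(
                    load_mesh(rundir / "meshes" / sub / f"{sid}.ply",
                              structure_id=sid, validate=False),
                    sid,
                ).check_against(templates[sid])
                for sid in config.structures
            }
        truth = GroundTruth()
        for e in json.loads((rundir / "ground_truth.json").read_text()):
            mask = np.zeros(e["n_vertices"], bool)
            mask[np.asarray(e["mask"], int)] = True
            truth.entries.append(
                GroundTruthEntry(e["structure_id"], e["predictor"], e["effect_type"],
                                 mask, np.zeros(e["n_vertices"]), e["volume_change_pct"])
            )
        return cls(config, int(manifest["seed"]), cov, templates, surfaces, truth)


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def simulate_cohort(config: CohortConfig | dict, seed: int = 0,
                    outdir=None) -> CohortBundle:
    """Simulate a full cohort: covariates, templates, corresponded subjects.

    Deterministic given (config, seed).  If ``outdir`` is given the bundle
    is persisted as ``meshes/<subject>/<structure>.ply`` plus
    ``covariates.csv``, ``ground_truth.json`` and ``manifest.json``.
    """
    if not isinstance(config, CohortConfig):
        config = CohortConfig.from_dict(dict(config))
    cov = simulate_covariates(
        config.n_cases, config.n_controls, seed=seed, **config.covariate_overrides
    )
    templates = {sid: make_template(sid, config.resolution) for sid in config.structures}
    caches = {sid: _TemplateCache(m) for sid, m in templates.items()}
    effects_by_struct: dict[str, list[EffectSpec]] = {sid: [] for sid in config.structures}
    for eff in config.effects:
        if eff.structure_id not in templates:
            raise ValueError(
                f"effect references structure {eff.structure_id!r} not in cohort config"
            )
        effects_by_struct[eff.structure_id].append(eff)

    truth = GroundTruth()
    for eff in config.effects:
        cache = caches[eff.structure_id]
        if eff.effect_type == "thickness":
            w = cache.window(eff.patch_center, eff.patch_radius)
            mask = w > 0
            disp = eff.amplitude * cache.rd * w
        else:
            mask = np.zeros(cache.template.n_vertices, bool)
            disp = np.zeros(cache.template.n_vertices)
        truth.entries.append(
            GroundTruthEntry(
                eff.structure_id, eff.predictor, eff.effect_type,
                mask, disp, 100.0 * eff.amplitude if eff.effect_type == "volume" else 0.0,
            )
        )

    surfaces: dict[str, dict[str, CorrespondedSurface]] = {}
    for i, row in cov.iterrows():
        sub = row["subject_id"]
        surfaces[sub] = {}
        for j, sid in enumerate(config.structures):
            sub_seed = np.random.SeedSequence([int(seed), 1, int(i), j])
            surfaces[sub][sid] = simulate_subject(
                templates[sid],
                row,
                effects_by_struct[sid],
                noise_sd=config.noise_sd,
                seed=sub_seed,
                cache=caches[sid],
                noise_smooth_iters=config.noise_smooth_iters,
            )
    bundle = CohortBundle(config, int(seed), cov, templates, surfaces, truth)
    if outdir is not None:
        bundle.write(outdir)
    return bundle
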