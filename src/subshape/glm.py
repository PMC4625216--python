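"""Mass-univariate general linear models over vertices and volumes.

Two model families are supported, one regression per vertex (RD or
logJD) or per structure (volume), both fit by ordinary least squares:

* group/clinical model:
  ``Y = b0 + b1*MainEffect + b2*Age + b3*Sex + b4*ICV + e``
  where MainEffect is HIV status, nadir CD4, viral detectability, time
  since diagnosis, HAND or drug-abuse history;
* cognition model (MainEffect = WAIS or WRAT):
  ``Y = b0 + b1*MainEffect + b2*HIVStatus + b3*Age + b4*Sex + b5*ICV
  + b6*MainEffect*HIVStatus + e``.

HIV status, viral detectability, HAND and drug history are coded
dichotomously; nadir CD4, TSD, WAIS and WRAT continuously.  Rows with
missing values are dropped listwise (and counted); predictors defined
only for cases (nCD4, TSD, ViralDetectable) are fitted on cases only.

Multiple testing is controlled by Benjamini-Hochberg FDR at q = 0.05,
with one correction family per surface per measure for shape maps and a
single family across structures for volumes.

The public surface follows the model/results idiom:
``MassUnivariateGLM(features, covariates).fit()`` returns a
:class:`MassUnivariateGLMResults` holding every fitted map, the
corrected q-values, the volume effect table and a text summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .mesh import VertexScalarMap, save_mesh_with_scalars

__all__ = [
    "ModelSpec",
    "GLMMap",
    "fit_glm",
    "fit_vertex_maps",
    "fdr_bh",
    "apply_family_correction",
    "volume_effect_report",
    "MassUnivariateGLM",
    "MassUnivariateGLMResults",
]

DICHOTOMOUS = ("HIVStatus", "ViralDetectable", "HAND", "DrugHistory", "Sex", "APOE")
CONTINUOUS = ("nCD4", "TSD", "WAIS", "WRAT", "Age", "ICV", "AdjEducation")
COGNITIVE = ("WAIS", "WRAT")
CASE_ONLY = ("nCD4", "TSD", "ViralDetectable")


@dataclass(frozen=True)
class ModelSpec:
    """Which regression to run: outcome, tested predictor, covariate set."""

    outcome: str  # "volume" | "RD" | "JD"
    main_effect: str = "HIVStatus"
    test: str = "main"  # "main" or "interaction" (cognition model only)

    def __post_init__(self):
        if self.outcome not in ("volume", "RD", "JD"):
            raise ValueError("outcome must be 'volume', 'RD' or 'JD'")
        if self.test not in ("main", "interaction"):
            raise ValueError("test must be 'main' or 'interaction'")
        if self.test == "interaction" and not self.is_cognition_model:
            raise ValueError("interaction test requires a WAIS/WRAT main effect")

    @property
    def is_cognition_model(self) -> bool:
        return self.main_effect in COGNITIVE

    @property
    def coding(self) -> str:
        return "dichotomous" if self.main_effect in DICHOTOMOUS else "continuous"

    @property
    def case_only(self) -> bool:
        return self.main_effect in CASE_ONLY

    def design(self, covariates: pd.DataFrame):
        """Build the design matrix (with listwise deletion).

        Returns (X, coef_names, tested_index, row_index, n_dropped).
        """
        df = covariates
        if self.case_only:
            df = df[df["HIVStatus"] == 1]
        cols = [self.main_effect]
        if self.is_cognition_model:
            cols.append("HIVStatus")
        cols += ["Age", "Sex", "ICV"]
        if self.main_effect not in df.columns:
            raise KeyError(f"main effect {self.main_effect!r} not in covariate table")
        sub = df[cols].astype(float)
        keep = ~sub.isna().any(axis=1)
        n_dropped = int((~keep).sum())
        sub = sub[keep]
        X = np.column_stack([np.ones(len(sub)), sub.to_numpy()])
        names = ["Intercept"] + cols
        if self.is_cognition_model:
            X = np.column_stack([X, sub[self.main_effect] * sub["HIVStatus"]])
            names.append(f"{self.main_effect}:HIVStatus")
        tested = names.index(
            self.main_effect if self.test == "main" else f"{self.main_effect}:HIVStatus"
        )
        return X, names, tested, sub.index, n_dropped


@dataclass
class GLMMap:
    """Fitted coefficients and inference for one structure x model.

    Arrays are per vertex for shape outcomes and length-1 for volumes.
    """

    family_id: str  # "<structure>:<RD|JD>" or "volumes"
    structure_id: str
    spec: ModelSpec
    coef_names: list
    tested_coef: str
    beta: np.ndarray  # (n_coef, n_targets)
    se: np.ndarray  # (n_targets,) SE of the tested coefficient
    t: np.ndarray
    p: np.ndarray
    df_resid: int
    sigma2: np.ndarray
    n_used: int
    n_dropped: int
    q: np.ndarray | None = None
    significant: np.ndarray | None = None
    q_threshold: float = 0.05

    @property
    def tested_beta(self) -> np.ndarray:
        return self.beta[self.coef_names.index(self.tested_coef)]

    def to_frame(self) -> pd.DataFrame:
        d = {
            "beta": self.tested_beta,
            "t": self.t,
            "p": self.p,
        }
        if self.q is not None:
            d["q"] = self.q
            d["significant"] = self.significant
        df = pd.DataFrame(d)
        df.index.name = "vertex"
        return df


def _check_full_rank(X: np.ndarray, names) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        from scipy.linalg import qr

        _, _, piv = qr(X, mode="economic", pivoting=True)
        bad = sorted(names[i] for i in piv[rank:])
        raise np.linalg.LinAlgError(
            f"design is rank deficient; collinear column(s): {bad}"
        )


def _ols_maps(X: np.ndarray, Y: np.ndarray, tested: int):
    """Vectorized OLS of many outcomes on one design.

    Y is (n, n_targets).  Returns beta (p, n_targets), se/t/p of the
    tested coefficient, df and sigma2 per target.
    """
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more complete rows ({n}) than regressors ({p})")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ (X.T @ Y)
    resid = Y - X @ beta
    df = n - p
    sigma2 = np.einsum("ij,ij->j", resid, resid) / df
    se = np.sqrt(xtx_inv[tested, tested] * sigma2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta[tested] / se, 0.0)
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    return beta, se, t, pvals, df, sigma2


def fit_glm(y: np.ndarray, covariates: pd.DataFrame, spec: ModelSpec,
            structure_id: str = "", family_id: str = "") -> GLMMap:
    """Fit one OLS regression of ``y`` (aligned with ``covariates`` rows).

    Two-sided p-value from the t distribution with ``n - p`` residual
    degrees of freedom; rows with missing covariates or outcome are
    dropped listwise.
    """
    y = np.asarray(y, float).ravel()
    if len(y) != len(covariates):
        raise ValueError("outcome length does not match covariate table")
    X, names, tested, rows, n_dropped = spec.design(covariates)
    pos = covariates.index.get_indexer(rows)
    ysub = y[pos]
    good = np.isfinite(ysub)
    n_dropped += int((~good).sum())
    X, ysub = X[good], ysub[good]
    _check_full_rank(X, names)
    beta, se, t, p, df, sigma2 = _ols_maps(X, ysub[:, None], tested)
    return GLMMap(
        family_id or "volumes", structure_id, spec, names, names[tested],
        beta, se, t, p, df, sigma2, len(ysub), n_dropped,
    )


def fit_vertex_maps(features, covariates: pd.DataFrame, spec: ModelSpec) -> list[GLMMap]:
    """Fit the model at every vertex (RD/JD) or per structure (volume).

    Returns one :class:`GLMMap` per surface for shape outcomes, or a
    single map with family_id 'volumes' whose targets are structures.
    """
    cov = covariates.set_index("subject_id").loc[features.subjects]
    if spec.outcome == "volume":
        maps = []
        for s in features.structures:
            maps.append(
                fit_glm(features.volumes[s].to_numpy(), cov, spec,
                        structure_id=s, family_id="volumes")
            )
        return maps
    store = features.rd if spec.outcome == "RD" else features.logjd
    X, names, tested, rows, n_dropped = spec.design(cov)
    pos = cov.index.get_indexer(rows)
    _check_full_rank(X, names)
    maps = []
    for s in features.shape_structures:
        Y = store[s][pos]
        beta, se, t, p, df, sigma2 = _ols_maps(X, Y, tested)
        maps.append(
            GLMMap(f"{s}:{spec.outcome}", s, spec, names, names[tested],
                   beta, se, t, p, df, sigma2, X.shape[0], n_dropped)
        )
    return maps


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------

def fdr_bh(pvals: np.ndarray, q_threshold: float = 0.05):
    """Benjamini-Hochberg step-up: returns (q_values, reject_mask).

    Rejects all hypotheses with rank <= max{i : p_(i) <= i*q/m};
    q-value_(i) = min_{j>=i} m*p_(j)/j, capped at 1.
    """
    p = np.asarray(pvals, float).ravel()
    if p.size == 0:
        return np.array([]), np.array([], bool)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    qraw = ranked * m / np.arange(1, m + 1)
    qmon = np.minimum.accumulate(qraw[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(qmon, 1.0)
    passed = ranked <= np.arange(1, m + 1) * q_threshold / m
    k = np.max(np.nonzero(passed)[0]) + 1 if passed.any() else 0
    reject = np.zeros(m, bool)
    reject[order[:k]] = True
    return q, reject


def apply_family_correction(maps: list[GLMMap], q_threshold: float = 0.05) -> list[GLMMap]:
    """BH-FDR within each map's declared family.

    Shape maps form one family per surface per measure (their own
    family_id); all maps tagged 'volumes' are pooled into a single
    family across structures.
    """
    vol_maps = [m for m in maps if m.family_id == "volumes"]
    if vol_maps:
        pooled = np.concatenate([m.p for m in vol_maps])
        q, rej = fdr_bh(pooled, q_threshold)
        at = 0
        for m in vol_maps:
            n = len(m.p)
            m.q, m.significant = q[at:at + n], rej[at:at + n]
            m.q_threshold = q_threshold
            at += n
    for m in maps:
        if m.family_id == "volumes":
            continue
        m.q, m.significant = fdr_bh(m.p, q_threshold)
        m.q_threshold = q_threshold
    return maps


# ---------------------------------------------------------------------------
# Volume effect table
# ---------------------------------------------------------------------------

def volume_effect_report(volume_maps: list[GLMMap], covariates: pd.DataFrame,
                         features) -> pd.DataFrame:
    """Per-structure effect table: beta, percent difference, t, p, q.

    The percent difference is 100 * beta_main / (covariate-adjusted
    control mean volume), the adjusted control mean being the model
    prediction at the fitted sample's covariate means with the main
    effect at its control level (0).
    """
    rows = []
    cov = covariates.set_index("subject_id").loc[features.subjects]
    for m in volume_maps:
        spec = m.spec
        X, names, tested, ridx, _ = spec.design(cov)
        xbar = X.mean(axis=0)
        xbar[tested] = 0.0
        if spec.is_cognition_model and f"{spec.main_effect}:HIVStatus" in names:
            xbar[names.index(f"{spec.main_effect}:HIVStatus")] = 0.0
        adj_control_mean = float(xbar @ m.beta[:, 0])
        if adj_control_mean == 0:
            raise ZeroDivisionError(f"{m.structure_id}: adjusted control mean volume is zero")
        b = float(m.tested_beta[0])
        rows.append(
            {
                "structure": m.structure_id,
                "main_effect": m.tested_coef,
                "beta": b,
                "percent": 100.0 * b / adj_control_mean,
                "t": float(m.t[0]),
                "p": float(m.p[0]),
                "q": float(m.q[0]) if m.q is not None else np.nan,
                "significant": bool(m.significant[0]) if m.significant is not None else False,
                "n": m.n_used,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Model / Results facade
# ---------------------------------------------------------------------------

class MassUnivariateGLM:
    """Vertex-wise and volumetric GLM analysis of a feature table.

    Parameters
    ----------
    features : ShapeFeatureTable
    covariates : DataFrame with a ``subject_id`` column
    specs : iterable of ModelSpec, optional
        Defaults to the group contrast (HIVStatus) on volume, RD and JD.
    """

    def __init__(self, features, covariates: pd.DataFrame, specs=None):
        self.features = features
        self.covariates = covariates
        if specs is None:
            specs = [ModelSpec(outcome, "HIVStatus") for outcome in ("volume", "RD", "JD")]
        self.specs = list(specs)

    @classmethod
    def from_cohort(cls, bundle, feature_table, specs=None) -> "MassUnivariateGLM":
        return cls(feature_table, bundle.covariates, specs)

    def fit(self, q_threshold: float = 0.05) -> "MassUnivariateGLMResults":
        maps: list[GLMMap] = []
        for spec in self.specs:
            maps.extend(fit_vertex_maps(self.features, self.covariates, spec))
        apply_family_correction(maps, q_threshold)
        return MassUnivariateGLMResults(self, maps, q_threshold)


@dataclass
class MassUnivariateGLMResults:
    """Fitted maps, FDR-corrected inference, and report builders."""

    model: MassUnivariateGLM
    maps: list[GLMMap] = field(repr=False)
    q_threshold: float = 0.05

    def get(self, outcome: str, structure: str, main_effect: str = "HIVStatus") -> GLMMap:
        for m in self.maps:
            if (m.spec.outcome == outcome and m.structure_id == structure
                    and m.spec.main_effect == main_effect):
                return m
        raise KeyError((outcome, structure, main_effect))

    def volume_table(self) -> pd.DataFrame:
        vol = [m for m in self.maps if m.family_id == "volumes"]
        if not vol:
            return pd.DataFrame()
        return volume_effect_report(vol, self.model.covariates, self.model.features)

    def significant_vertex_counts(self) -> pd.DataFrame:
        rows = [
            {
                "structure": m.structure_id,
                "outcome": m.spec.outcome,
                "main_effect": m.spec.main_effect,
                "n_vertices": len(m.p),
                "n_significant": int(m.significant.sum()) if m.significant is not None else 0,
            }
            for m in self.maps
            if m.family_id != "volumes"
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Mass-univariate GLM results",
            f"  subjects: {len(self.model.features.subjects)}   "
            f"q-threshold: {self.q_threshold}",
        ]
        vt = self.volume_table()
        if len(vt):
            lines.append("\nVolume effects (FDR across structures):")
            lines.append(vt.to_string(index=False, float_format=lambda x: f"{x:.4g}"))
        sc = self.significant_vertex_counts()
        if len(sc):
            lines.append("\nSignificant vertices (FDR per surface per measure):")
            lines.append(sc.to_string(index=False))
        return "\n".join(lines)

    def save(self, outdir, templates: dict | None = None) -> None:
        """Write per-structure CSVs, the volume table, and optional
        FDR-thresholded t-map overlays (VTK)."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        vt = self.volume_table()
        if len(vt):
            vt.to_csv(out / "volume_effects.csv", index=False)
        for m in self.maps:
            if m.family_id == "volumes":
                continue
            tag = f"{m.structure_id}_{m.spec.outcome}_{m.spec.main_effect}"
            m.to_frame().to_csv(out / f"glm_{tag}.csv")
            if templates and m.structure_id in templates:
                tmap = np.where(m.significant, m.t, 0.0) if m.significant is not None else m.t
                save_mesh_with_scalars(
                    templates[m.structure_id],
                    [
                        VertexScalarMap(m.structure_id, m.t, "t"),
                        VertexScalarMap(m.structure_id, m.q if m.q is not None else m.p, "q"),
                        VertexScalarMap(m.structure_id, tmap, "t_thresholded"),
                    ],
                    out / f"tmap_{tag}.vtk",
                )
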