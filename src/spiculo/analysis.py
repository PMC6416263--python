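"""End-to-end robustness experiments and their statistics.

The experiments mirror a phantom-based CT radiomics study: rasterize the
phantom suite, reconstruct surfaces with the different meshing strategies,
measure the nine shape features, and quantify

* monotone association of each feature with the spiculatedness index d
  (Spearman rank correlation, Fisher-z confidence intervals),
* agreement with the STL-reference feature values,
* sensitivity to slice thickness, to 1 mm isotropic grid resampling, and
  to pure volume rescaling (homothety).

Percent changes are always 100 * |value - reference| / |reference| with the
reference being the designated baseline arm of each comparison (the STL
value; the 2 mm-slice value; the original-grid value; the unscaled-volume
value; the most-spiculated model d = 11 for the spiculatedness span).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .features import (
    DIMENSIONLESS_FEATURES,
    FEATURE_NAMES,
    compute_features,
    mesh_volume,
)
from .geometry import as_mesh
from .masks import BinaryMask, equalize_volumes, resample_mask, voxelize
from .meshing import mesh_isosurface, reconstruct
from .phantoms import ModelSuite

__all__ = [
    "spearman",
    "spearman_with_ci",
    "percent_change",
    "rasterize_suite",
    "extract_suite_features",
    "run_correlation_experiment",
    "run_reference_comparison",
    "run_slice_thickness_comparison",
    "run_resampling_comparison",
    "run_volume_sensitivity",
    "feature_correlation_matrix",
    "flag_m4_outliers",
    "ExperimentReport",
]

#: the eight features analyzed against spiculatedness (volume is excluded:
#: it is fixed by the equalization step)
NON_VOLUME_FEATURES = tuple(f for f in FEATURE_NAMES if f != "volume")

DEFAULT_SPACING = (0.68, 0.68, 2.0)
THIN_SPACING = (0.68, 0.68, 0.6)
VOLUME_FRACTIONS = (0.25, 0.5, 0.75, 1.0, 1.25, 1.5)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks, t-approximation p-value)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length samples of size >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation for constant input")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def spearman_with_ci(x, y, confidence: float = 0.95):
    """Spearman rho with a Fisher-z confidence interval."""
    rho, p = spearman(x, y)
    n = len(x)
    z = np.arctanh(np.clip(rho, -1 + 1e-15, 1 - 1e-15))
    half = stats.norm.ppf(0.5 + confidence / 2) / np.sqrt(n - 3)
    lo, hi = float(np.tanh(z - half)), float(np.tanh(z + half))
    # guard against float round-off at |rho| ~ 1
    return rho, min(lo, rho), max(hi, rho), p


def percent_change(value: float, reference: float) -> float:
    """100 * |value - reference| / |reference|."""
    if reference == 0:
        raise ValueError("zero reference in percent change")
    return 100.0 * abs(value - reference) / abs(reference)


def rasterize_suite(suite: ModelSuite, spacing=DEFAULT_SPACING) -> list[BinaryMask]:
    """Voxelize every model of the suite at the given spacing."""
    return [voxelize(mesh, spacing) for _, mesh in suite]


def _scaled_mesh(mesh, factor: float):
    return as_mesh(np.asarray(mesh.vertices) * factor, mesh.faces)


def extract_suite_features(
    suite: ModelSuite,
    spacing=DEFAULT_SPACING,
    methods=("M1", "M2", "M3"),
    equalize: bool = True,
    resample: bool = False,
    masks: list[BinaryMask] | None = None,
    **mesh_kwargs,
) -> pd.DataFrame:
    """Long feature table of the full pipeline.

    voxelize -> (optional 1 mm resampling) -> (optional volume equalization
    to the suite-mean M1 volume) -> per-method surface reconstruction ->
    features.  One row per (model, method).
    """
    if masks is None:
        masks = rasterize_suite(suite, spacing)
    if resample:
        masks = [resample_mask(m) for m in masks]
    if equalize:
        m1_vols = [mesh_volume(mesh_isosurface(m)) for m in masks]
        reference = float(np.mean(m1_vols))
        masks = equalize_volumes(masks, reference, m1_vols)
    rows = []
    for (spec, _), mask in zip(suite, masks):
        for method in methods:
            mesh = reconstruct(mask, method, **mesh_kwargs)
            fv = compute_features(mesh)
            rows.append(
                {
                    "d": spec.spiculation_d,
                    "method": method,
                    "spacing": "x".join(f"{s:g}" for s in spacing),
                    "resampled": resample,
                    "equalized": equalize,
                    "fraction": 1.0,
                    **fv.as_dict(),
                }
            )
    return pd.DataFrame(rows)


def run_correlation_experiment(
    suite: ModelSuite,
    spacing=DEFAULT_SPACING,
    methods=("M1", "M2", "M3"),
    features_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Spearman correlation of each non-volume feature with d, per method.

    The pipeline arm is the volume-equalized one, so volume itself carries
    no rank information and is excluded.
    """
    if features_table is None:
        features_table = extract_suite_features(suite, spacing, methods)
    rows = []
    for method in methods:
        sub = features_table[features_table["method"] == method].sort_values("d")
        for feat in NON_VOLUME_FEATURES:
            rho, lo, hi, p = spearman_with_ci(sub["d"], sub[feat])
            rows.append(
                {
                    "feature": feat,
                    "method": method,
                    "rho": rho,
                    "ci_low": lo,
                    "ci_high": hi,
                    "p": p,
                }
            )
    return pd.DataFrame(rows)


def _percent_change_table(
    pipeline: pd.DataFrame, reference: pd.DataFrame, comparison: str
) -> pd.DataFrame:
    """Mean/min/max percent change per (feature, method), paired on d."""
    rows = []
    for method in pipeline["method"].unique():
        sub = pipeline[pipeline["method"] == method].set_index("d").sort_index()
        if "method" in reference.columns and (reference["method"] == method).any():
            ref = reference[reference["method"] == method]
        else:
            ref = reference
        ref = ref.set_index("d").sort_index()
        common = sub.index.intersection(ref.index)
        for feat in FEATURE_NAMES:
            pc = [
                percent_change(sub.loc[d, feat], ref.loc[d, feat]) for d in common
            ]
            rows.append(
                {
                    "comparison": comparison,
                    "feature": feat,
                    "method": method,
                    "mean": float(np.mean(pc)),
                    "min": float(np.min(pc)),
                    "max": float(np.max(pc)),
                }
            )
    return pd.DataFrame(rows)


def stl_reference_features(suite: ModelSuite) -> pd.DataFrame:
    """Features computed directly on the suite's surface models."""
    rows = []
    for spec, mesh in suite:
        rows.append({"d": spec.spiculation_d, **compute_features(mesh).as_dict()})
    return pd.DataFrame(rows)


def run_reference_comparison(
    suite: ModelSuite,
    spacing=DEFAULT_SPACING,
    methods=("M1", "M3"),
    pipeline_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Percent change of pipeline features against the STL reference.

    Native (non-equalized) masks: volume differences are part of what the
    rasterization chain distorts.
    """
    if pipeline_table is None:
        pipeline_table = extract_suite_features(
            suite, spacing, methods, equalize=False
        )
    return _percent_change_table(
        pipeline_table, stl_reference_features(suite), "stl_vs_pipeline"
    )


def run_slice_thickness_comparison(
    suite: ModelSuite,
    thin=THIN_SPACING,
    thick=DEFAULT_SPACING,
    methods=("M1", "M3"),
    thin_table: pd.DataFrame | None = None,
    thick_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Percent change between slice thicknesses; the thick (2 mm) arm is
    the reference."""
    if thin_table is None:
        thin_table = extract_suite_features(suite, thin, methods, equalize=False)
    if thick_table is None:
        thick_table = extract_suite_features(suite, thick, methods, equalize=False)
    return _percent_change_table(thin_table, thick_table, "thin_vs_thick_slices")


def run_resampling_comparison(
    suite: ModelSuite,
    spacing=DEFAULT_SPACING,
    methods=("M1", "M3"),
    original_table: pd.DataFrame | None = None,
    resampled_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Percent change after 1 mm isotropic grid resampling of native masks."""
    if original_table is None:
        original_table = extract_suite_features(suite, spacing, methods, equalize=False)
    if resampled_table is None:
        resampled_table = extract_suite_features(
            suite, spacing, methods, equalize=False, resample=True
        )
    return _percent_change_table(
        resampled_table, original_table, "resampled_vs_original"
    )


def run_volume_sensitivity(
    suite: ModelSuite,
    d_select=(11.0, 47.0, 92.0),
    fractions=VOLUME_FRACTIONS,
    spacing=DEFAULT_SPACING,
    method: str = "M3",
    features_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Volume-rescaling sensitivity versus the spiculatedness span.

    Each selected model's reconstructed surface is homothetically rescaled
    to each volume fraction (spacing recomputation scales the mesh; the
    topology is fixed, so dimensionless features are exactly invariant).
    The volume spread of a feature is the full span of its values across
    the fraction sweep, as a percentage of the unscaled value,
    100 * (max_f - min_f) / value(f=1); the spiculatedness span is the
    percent change between the least (d = 92) and most (d = 11) spiculated
    models, with d = 11 as reference.  A feature is classified
    volume-robust when its volume spread is below its spiculatedness span.
    """
    if features_table is None:
        features_table = extract_suite_features(suite, spacing, (method,))
    sub = features_table[features_table["method"] == method].set_index("d")
    d_min, d_max = min(sub.index), max(sub.index)
    rows = []
    meshes = {}
    masks = rasterize_suite(suite, spacing)
    m1_vols = [mesh_volume(mesh_isosurface(m)) for m in masks]
    reference = float(np.mean(m1_vols))
    eq_masks = equalize_volumes(masks, reference, m1_vols)
    for (spec, _), mask in zip(suite, eq_masks):
        if spec.spiculation_d in d_select:
            meshes[spec.spiculation_d] = reconstruct(mask, method)
    for feat in FEATURE_NAMES:
        spic_span = percent_change(sub.loc[d_max, feat], sub.loc[d_min, feat])
        vol_spread = 0.0
        per_model = {}
        for d, mesh in meshes.items():
            base = getattr(compute_features(mesh), feat)
            values = [
                getattr(compute_features(_scaled_mesh(mesh, f ** (1.0 / 3.0))), feat)
                if f != 1.0
                else base
                for f in fractions
            ]
            span = 100.0 * (max(values) - min(values)) / abs(base)
            per_model[d] = span
            vol_spread = max(vol_spread, span)
        rows.append(
            {
                "feature": feat,
                "spiculatedness_span": spic_span,
                "volume_spread": vol_spread,
                **{f"volume_spread_d{int(d)}": v for d, v in sorted(per_model.items())},
                "volume_robust": bool(vol_spread < spic_span),
            }
        )
    return pd.DataFrame(rows)


def feature_correlation_matrix(
    features_table: pd.DataFrame, method: str = "M1"
) -> pd.DataFrame:
    """Pairwise Spearman correlations among the eight non-volume features."""
    sub = features_table[features_table["method"] == method].sort_values("d")
    if len(sub) < 3:
        raise ValueError("need at least 3 models")
    n = len(NON_VOLUME_FEATURES)
    mat = np.full((n, n), np.nan)
    for i, fi in enumerate(NON_VOLUME_FEATURES):
        for j, fj in enumerate(NON_VOLUME_FEATURES):
            if i == j:
                mat[i, j] = 1.0
            elif i < j:
                try:
                    mat[i, j], _ = spearman(sub[fi], sub[fj])
                except ValueError:
                    pass  # constant column: entry stays marked as NaN
                mat[j, i] = mat[i, j]
    return pd.DataFrame(mat, index=NON_VOLUME_FEATURES, columns=NON_VOLUME_FEATURES)


def flag_m4_outliers(features_table: pd.DataFrame, threshold: float = 3.0):
    """Flag (d, feature) cells where M4 deviates from the M1-M3 consensus.

    Deviation is measured in median-absolute-deviations of the M1-M3
    values; the concave-hull method is known to behave erratically on
    spiculated masks.
    """
    flags = []
    consensus_methods = [m for m in ("M1", "M2", "M3") if m in set(features_table["method"])]
    if "M4" not in set(features_table["method"]) or not consensus_methods:
        return pd.DataFrame(columns=["d", "feature", "m4_value", "consensus_median"])
    for d, grp in features_table.groupby("d"):
        m4 = grp[grp["method"] == "M4"]
        cons = grp[grp["method"].isin(consensus_methods)]
        if m4.empty or cons.empty:
            continue
        for feat in FEATURE_NAMES:
            vals = cons[feat].to_numpy()
            med = np.median(vals)
            mad = np.median(np.abs(vals - med))
            scale = mad if mad > 0 else max(abs(med) * 1e-6, 1e-12)
            value = float(m4[feat].iloc[0])
            if abs(value - med) > threshold * scale:
                flags.append(
                    {"d": d, "feature": feat, "m4_value": value, "consensus_median": med}
                )
    return pd.DataFrame(flags, columns=["d", "feature", "m4_value", "consensus_median"])


@dataclass
class ExperimentReport:
    """Container for the tables a full reproduction run emits."""

    features: pd.DataFrame
    correlations: pd.DataFrame
    percent_changes: pd.DataFrame
    volume_sensitivity: pd.DataFrame
    m4_outliers: pd.DataFrame = field(default_factory=pd.DataFrame)
    provenance: dict = field(default_factory=dict)
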