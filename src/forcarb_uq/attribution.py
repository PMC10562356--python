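"""Variance attribution and risk post-processing of simulation ensembles.

Attribution uses the Stewart-Love redundancy index: the share of an output
variable's variance explained by a feature block through canonical variates,

    Rd = sum_k rho_k^2 * mean_j loading_jk^2,

where rho_k are the canonical correlations and the loadings are the
correlations of the output variables with their own canonical variates.  For
a single feature column and a single output this reduces to the squared
Pearson correlation.  The index lies in [0, 1] and is only interpreted
relative to other index values.

Risk analysis is empirical: eCDF-based exceedance probabilities and central
interquantile range widths of the simulated output distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .engine import EnsembleResult

__all__ = [
    "FeatureMatrix", "RedundancyResult", "RiskCurves",
    "encode_features", "redundancy_index", "attribute_sources",
    "ecdf_probability", "interquantile_range", "risk_curves",
]

#: feature-name prefix -> named uncertainty-source set (per-set maxima are
#: reported for these, matching how multi-parameter sources are summarized)
FEATURE_SETS = {"pPrel": "pPrel", "pCrob": "pCrob", "pYas": "pYas",
                "pECorg": "pECorg", "pHarv": "pHarv"}
CATEGORICAL = ("RCP", "Harv", "GCM")


@dataclass
class FeatureMatrix:
    """Numeric per-simulation feature matrix with set membership retained."""

    matrix: pd.DataFrame
    groups: dict[str, str]           # column -> set name (itself if ungrouped)
    dropped_constant: list[str] = field(default_factory=list)

    @property
    def n_rows(self) -> int:
        return len(self.matrix)


def _feature_group(column: str) -> str:
    for prefix, name in FEATURE_SETS.items():
        if column.startswith(prefix + "_"):
            return name
    for cat in CATEGORICAL:
        if column.startswith(cat + "="):
            return cat
    return column


def _pooled_frames(ensembles: Iterable[EnsembleResult], year: int,
                   output_variable: str, region: str | None,
                   include_noharv: bool) -> tuple[pd.DataFrame, np.ndarray]:
    frames, outputs = [], []
    for ens in ensembles:
        if not include_noharv and ens.harvest == "NoHarv":
            continue
        feats = ens.features.copy()
        if region is None:
            y = ens.country_mean(output_variable).sel(year=year).to_numpy()
        else:
            y = ens.data[output_variable].sel(region=region, year=year).to_numpy()
            # region-level analysis uses region-level initial means
            feats["vol0"] = ens.data["vol0"].sel(region=region).to_numpy()
            feats["age0"] = ens.data["age0"].sel(region=region).to_numpy()
        ok = ~np.isnan(y)
        frames.append(feats.loc[ok])
        outputs.append(y[ok])
    if not frames:
        raise ValueError("no ensembles to pool (is everything NoHarv?)")
    return pd.concat(frames, ignore_index=True), np.concatenate(outputs)


def encode_features(ensembles: EnsembleResult | Iterable[EnsembleResult],
                    year: int, output_variable: str,
                    region: str | None = None,
                    include_noharv: bool = False,
                    ) -> tuple[FeatureMatrix, np.ndarray]:
    """Build the (features, output) pair for one evaluation year.

    Categorical drivers (RCP, Harv, GCM) are one-hot encoded with the first
    level dropped; parameter sets expand to scalar columns with their set
    membership retained so per-set maxima can be formed.  Constant columns
    are flagged and dropped.  NoHarv rows are excluded by default because
    they would dominate the harvest signal.
    """
    if isinstance(ensembles, EnsembleResult):
        ensembles = [ensembles]
    ensembles = list(ensembles)
    if year not in ensembles[0].data.year:
        raise ValueError(f"year {year} outside the simulated span")
    if output_variable not in ensembles[0].data:
        raise ValueError(f"unknown output variable {output_variable!r}")
    raw, y = _pooled_frames(ensembles, year, output_variable, region,
                            include_noharv)

    cols: dict[str, np.ndarray] = {}
    for cat in CATEGORICAL:
        levels = sorted(raw[cat].unique())
        for level in levels[1:]:  # k-1 indicator columns
            cols[f"{cat}={level}"] = (raw[cat] == level).to_numpy(dtype=float)
    for c in raw.columns:
        if c in CATEGORICAL:
            continue
        cols[c] = raw[c].to_numpy(dtype=float)

    matrix = pd.DataFrame(cols)
    constant = [c for c in matrix.columns if matrix[c].nunique() <= 1]
    matrix = matrix.drop(columns=constant)
    groups = {c: _feature_group(c) for c in matrix.columns}
    return FeatureMatrix(matrix=matrix, groups=groups,
                         dropped_constant=constant), y


def redundancy_index(feature_columns, output_vector) -> float:
    """Stewart-Love redundancy of the output(s) given the feature block.

    Canonical correlations are computed from QR decompositions of the
    centred blocks; the index is clamped to [0, 1] against numerical noise.
    """
    X = np.asarray(feature_columns, dtype=float)
    Y = np.asarray(output_vector, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if Y.ndim == 1:
        Y = Y[:, None]
    n = X.shape[0]
    if n < 3:
        raise ValueError("at least 3 rows are required")
    if np.allclose(Y.var(axis=0), 0.0):
        raise ValueError("output variance is zero; redundancy undefined")

    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    Qx, Rx, px = _thin_qr(Xc)
    Qy, Ry, py = _thin_qr(Yc)
    U, s, Vt = np.linalg.svd(Qx.T @ Qy, full_matrices=False)
    k = min(px, py)
    rho = np.clip(s[:k], 0.0, 1.0)

    # output canonical variates and loadings (correlations with Y columns)
    V = Qy @ Vt.T[:, :k]
    sd_v = V.std(axis=0, ddof=0)
    sd_y = Yc.std(axis=0, ddof=0)
    keep = sd_v > 0
    loadings = np.zeros((Y.shape[1], k))
    if keep.any():
        cov = (Yc.T @ V[:, keep]) / n
        loadings[:, keep] = cov / (sd_y[:, None] * sd_v[keep][None, :])
    rd = float(np.sum(rho ** 2 * np.mean(loadings ** 2, axis=0)))
    return float(np.clip(rd, 0.0, 1.0))


def _thin_qr(M: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Rank-revealing thin QR keeping only independent columns."""
    q, r = np.linalg.qr(M)
    diag = np.abs(np.diag(r))
    tol = max(M.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    rank = int((diag > tol).sum())
    return q[:, :rank], r[:rank, :rank], rank


@dataclass
class RedundancyResult:
    """Tidy per-feature(-set) redundancy indices."""

    table: pd.DataFrame  # columns: region, year, output, feature, rd_ind

    def top_feature(self, year: int, output: str,
                    region: str = "country") -> str:
        sub = self.table.query("year == @year and output == @output"
                               " and region == @region")
        return str(sub.loc[sub["rd_ind"].idxmax(), "feature"])


def attribute_sources(ensembles: EnsembleResult | Iterable[EnsembleResult],
                      years: Sequence[int] = (2015, 2035, 2050),
                      outputs: Sequence[str] = ("nbe", "nee", "total_c"),
                      regions: Sequence[str] | None = None,
                      include_noharv: bool = False,
                      joint_sets: bool = False) -> RedundancyResult:
    """Per-feature redundancy indices with per-set maxima for parameter sets.

    Default mode scores each feature column against the scalar output (the
    squared-correlation special case); ``joint_sets`` instead runs a joint
    CCA per feature set.  Rows where every feature is constant are skipped.
    """
    if isinstance(ensembles, EnsembleResult):
        ensembles = [ensembles]
    ensembles = list(ensembles)
    region_list: list[str | None] = [None]
    if regions is None:
        region_list += [str(r) for r in ensembles[0].data.region.values]
    else:
        region_list = list(regions)

    rows = []
    for region in region_list:
        rname = "country" if region is None else region
        for year in years:
            for output in outputs:
                fm, y = encode_features(ensembles, year, output, region=region,
                                        include_noharv=include_noharv)
                if fm.matrix.empty or y.size < 3 or np.var(y) == 0:
                    continue
                per_set: dict[str, float] = {}
                if joint_sets:
                    for set_name in sorted(set(fm.groups.values())):
                        cols = [c for c, g in fm.groups.items() if g == set_name]
                        per_set[set_name] = redundancy_index(
                            fm.matrix[cols].to_numpy(), y)
                else:
                    for col in fm.matrix.columns:
                        rd = redundancy_index(fm.matrix[col].to_numpy(), y)
                        g = fm.groups[col]
                        per_set[g] = max(per_set.get(g, 0.0), rd)
                for feature, rd in sorted(per_set.items()):
                    rows.append({"region": rname, "year": year, "output": output,
                                 "feature": feature, "rd_ind": rd})
    return RedundancyResult(table=pd.DataFrame(rows))


def ecdf_probability(samples, threshold: float) -> float:
    """Empirical P(X <= threshold)."""
    x = np.asarray(samples, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        raise ValueError("samples must be non-empty")
    return float(np.mean(x <= threshold))


def interquantile_range(samples, level: float = 0.95) -> float:
    """Central interquantile width, linear interpolation of order statistics."""
    x = np.asarray(samples, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        raise ValueError("samples must be non-empty")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    lo, hi = (1.0 - level) / 2.0, (1.0 + level) / 2.0
    qs = np.quantile(x, [lo, hi], method="linear")
    return float(qs[1] - qs[0])


@dataclass
class RiskCurves:
    """Per region/scenario/year eCDF summaries of an output variable."""

    table: pd.DataFrame  # region, rcp, harvest, year, threshold, probability
    widths: pd.DataFrame  # region, rcp, harvest, year, width_95


def risk_curves(ensembles: EnsembleResult | Iterable[EnsembleResult],
                variable: str = "nbe", years: Sequence[int] = (2035,),
                thresholds: Sequence[float] = (-1000.0,),
                level: float = 0.95,
                include_country: bool = True) -> RiskCurves:
    """eCDF threshold probabilities and central range widths per region."""
    if isinstance(ensembles, EnsembleResult):
        ensembles = [ensembles]
    prob_rows, width_rows = [], []
    for ens in ensembles:
        units = [(str(r), ens.data[variable].sel(region=r))
                 for r in ens.data.region.values]
        if include_country:
            units.append(("country", ens.country_mean(variable)))
        for rname, da in units:
            for year in years:
                samples = da.sel(year=year).to_numpy()
                samples = samples[~np.isnan(samples)]
                if samples.size == 0:
                    continue
                for t in thresholds:
                    prob_rows.append({
                        "region": rname, "rcp": ens.rcp, "harvest": ens.harvest,
                        "year": year, "threshold": t,
                        "probability": ecdf_probability(samples, t)})
                width_rows.append({
                    "region": rname, "rcp": ens.rcp, "harvest": ens.harvest,
                    "year": year, "width": interquantile_range(samples, level)})
    return RiskCurves(table=pd.DataFrame(prob_rows),
                      widths=pd.DataFrame(width_rows))
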