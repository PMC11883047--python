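"""Morphospace ordination and group comparison.

The 40 grain-level features are ordinated by PCA — on the correlation matrix
by default, since log-scaled sizes and integer component counts mix units —
and groups are compared by 50% confidence ellipses in the PC1 x PC2 plane
and by Euclidean distances between group centroids, either in the (possibly
standardized) 40-D feature space or in PC-score space.

The interface follows the model/results pattern: build a
:class:`Morphospace` from a feature table, call :meth:`~Morphospace.fit`,
and read estimates off the returned :class:`MorphospaceResults`.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .io import FEATURE_COLUMNS

logger = logging.getLogger(__name__)

DISTANCE_SPACES = ("feature_40d", "standardized_40d", "pc_scores")


@dataclass
class EllipseSummary:
    """A group's 50% (by default) confidence ellipse in the PC1 x PC2 plane.

    The boundary is the set of points at Mahalanobis radius
    sqrt(chi2_2(level)) from the group mean under the group's 2 x 2 score
    covariance; ``semi_axes`` are in descending order.
    """

    group: str
    center: tuple[float, float]
    semi_axes: tuple[float, float]
    angle_rad: float
    level: float
    n: int
    degenerate: bool = False

    @property
    def area(self) -> float:
        return float(np.pi * self.semi_axes[0] * self.semi_axes[1])

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "center": list(self.center),
            "semi_axes": list(self.semi_axes),
            "angle_rad": self.angle_rad,
            "level": self.level,
            "n": self.n,
            "degenerate": self.degenerate,
            "area": self.area,
        }


def confidence_ellipse(
    scores: np.ndarray, level: float = 0.5, group: str = "", min_n: int = 3
) -> EllipseSummary:
    """Fit a confidence ellipse to n x 2 scores from mean and covariance."""
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[1] != 2:
        raise ValueError(f"scores must be n x 2, got {scores.shape}")
    n = scores.shape[0]
    if n < min_n:
        raise ValueError(f"need at least {min_n} points per group, got {n}")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    center = scores.mean(axis=0)
    cov = np.cov(scores, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(cov)
    radius2 = stats.chi2.ppf(level, df=2)
    degenerate = bool(eigvals[0] <= 1e-12 * max(eigvals[1], 1.0))
    semi = np.sqrt(np.clip(eigvals, 0.0, None) * radius2)
    # principal axis first
    angle = float(np.arctan2(eigvecs[1, 1], eigvecs[0, 1]))
    if degenerate:
        logger.warning("group %r: singular score covariance, degenerate ellipse", group)
    return EllipseSummary(
        group=group,
        center=(float(center[0]), float(center[1])),
        semi_axes=(float(semi[1]), float(semi[0])),
        angle_rad=angle,
        level=level,
        n=n,
        degenerate=degenerate,
    )


@dataclass
class DistanceMatrix:
    """Pairwise Euclidean distances between group centroids."""

    groups: list[str]
    distances: np.ndarray
    space: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.distances, index=self.groups, columns=self.groups)

    def between(self, a: str, b: str) -> float:
        return float(self.distances[self.groups.index(a), self.groups.index(b)])


class Morphospace:
    """PCA morphospace model of a grain feature table.

    Parameters
    ----------
    table
        Feature table with the 40 canonical feature columns plus metadata.
    group_col
        Column holding group labels (spatio-temporal group by default;
        pass ``"subfamily"`` for subfamily-level comparison).
    scaling
        ``"correlation"`` (default; features standardized to unit variance)
        or ``"covariance"`` (centering only).
    drop_constant
        In correlation mode a zero-variance feature cannot be standardized;
        by default this is an error naming the column (matching R's
        ``prcomp(scale = TRUE)``).  With ``drop_constant=True`` such
        columns are removed from the ordination with a warning instead —
        the usual remedy when e.g. a saturated count feature is constant
        across a small cohort.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        group_col: str = "group",
        scaling: str = "correlation",
        feature_cols: Sequence[str] = FEATURE_COLUMNS,
        drop_constant: bool = False,
    ):
        if scaling not in ("correlation", "covariance"):
            raise ValueError(f"unknown scaling mode {scaling!r}")
        missing = [c for c in feature_cols if c not in table.columns]
        if missing:
            raise ValueError(f"table missing feature columns {missing}")
        if len(table) < 3:
            raise ValueError("need at least 3 grains to fit a morphospace")
        self.table = table.reset_index(drop=True)
        self.group_col = group_col
        self.scaling = scaling
        self.feature_cols = list(feature_cols)
        self.X = self.table[self.feature_cols].to_numpy(dtype=float)
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature matrix contains non-finite values")
        if scaling == "correlation" and drop_constant:
            std = self.X.std(axis=0, ddof=1)
            constant = [c for c, s in zip(self.feature_cols, std) if s <= 0]
            if constant:
                warnings.warn(
                    f"dropping constant feature columns from the ordination: "
                    f"{constant}",
                    stacklevel=2,
                )
                keep = std > 0
                self.feature_cols = [
                    c for c, k in zip(self.feature_cols, keep) if k
                ]
                self.X = self.X[:, keep]

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "Morphospace":
        from .io import read_feature_table

        return cls(read_feature_table(path), **kwargs)

    def fit(self, n_components: int | None = None) -> "MorphospaceResults":
        """Fit the PCA and return the results object."""
        center = self.X.mean(axis=0)
        if self.scaling == "correlation":
            scale = self.X.std(axis=0, ddof=1)
            constant = [
                c for c, s in zip(self.feature_cols, scale) if s <= 0
            ]
            if constant:
                raise ValueError(
                    f"constant feature columns in correlation mode: {constant}"
                )
        else:
            scale = np.ones(self.X.shape[1])
        Z = (self.X - center) / scale
        m = n_components or min(Z.shape)
        pca = PCA(n_components=m, svd_solver="full")
        scores = pca.fit_transform(Z)
        loadings = pca.components_.T.copy()  # p x m, orthonormal columns
        # deterministic sign: largest-|loading| entry positive per axis
        for j in range(loadings.shape[1]):
            pivot = np.argmax(np.abs(loadings[:, j]))
            if loadings[pivot, j] < 0:
                loadings[:, j] *= -1.0
                scores[:, j] *= -1.0
        explained = pca.explained_variance_ratio_.copy()
        return MorphospaceResults(
            model=self,
            center=center,
            scale=scale,
            loadings=loadings,
            scores=scores,
            explained_fraction=explained,
        )


class MorphospaceResults:
    """Fitted morphospace: loadings, scores, explained variance, and the
    group-level summaries (confidence ellipses, centroid distances)."""

    def __init__(self, model, center, scale, loadings, scores, explained_fraction):
        self.model = model
        self.center = center
        self.scale = scale
        self.loadings = loadings
        self.scores = scores
        self.explained_fraction = explained_fraction

    # -- basic accessors ---------------------------------------------------

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    @property
    def pc_names(self) -> list[str]:
        return [f"PC{j + 1}" for j in range(self.n_components)]

    def loadings_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.loadings, index=self.model.feature_cols, columns=self.pc_names
        )

    def scores_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.scores, columns=self.pc_names)
        for col in ("grain_id", self.model.group_col):
            if col in self.model.table.columns:
                df.insert(0, col, self.model.table[col].to_numpy())
        return df

    def explained_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "component": self.pc_names,
                "explained_fraction": self.explained_fraction,
                "explained_pct": 100.0 * self.explained_fraction,
            }
        )

    # -- projection --------------------------------------------------------

    def project(self, table: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Project new rows into the fitted morphospace."""
        if isinstance(table, pd.DataFrame):
            missing = [c for c in self.model.feature_cols if c not in table.columns]
            if missing:
                raise ValueError(f"projection table missing columns {missing}")
            X = table[self.model.feature_cols].to_numpy(dtype=float)
        else:
            X = np.asarray(table, dtype=float)
            if X.ndim == 1:
                X = X[None, :]
            if X.shape[1] != len(self.model.feature_cols):
                raise ValueError(
                    f"expected {len(self.model.feature_cols)} columns, got {X.shape[1]}"
                )
        return (X - self.center) / self.scale @ self.loadings

    # -- group summaries ---------------------------------------------------

    def _groups(self) -> pd.Series:
        col = self.model.group_col
        if col not in self.model.table.columns:
            raise ValueError(f"no group column {col!r} in the table")
        return self.model.table[col]

    def group_ellipses(self, level: float = 0.5) -> dict[str, EllipseSummary]:
        """50% confidence ellipses per group in the PC1 x PC2 plane."""
        groups = self._groups()
        out = {}
        for g in pd.unique(groups.dropna()):
            pts = self.scores[(groups == g).to_numpy(), :2]
            out[str(g)] = confidence_ellipse(pts, level=level, group=str(g))
        return out

    def centroid_distances(self, space: str = "feature_40d") -> DistanceMatrix:
        """Euclidean distances between group centroids.

        ``space`` is ``feature_40d`` (raw features), ``standardized_40d``
        (centered/scaled as fitted) or ``pc_scores`` (all components kept;
        identical to ``standardized_40d`` up to rotation).
        """
        if space not in DISTANCE_SPACES:
            raise ValueError(f"unknown space {space!r}; pick from {DISTANCE_SPACES}")
        groups = self._groups()
        labels = [str(g) for g in pd.unique(groups.dropna())]
        if len(labels) < 2:
            raise ValueError("need at least 2 groups for centroid distances")
        if space == "feature_40d":
            data = self.model.X
        elif space == "standardized_40d":
            data = (self.model.X - self.center) / self.scale
        else:
            data = self.scores
        centroids = np.vstack(
            [data[(groups == g).to_numpy()].mean(axis=0) for g in labels]
        )
        diff = centroids[:, None, :] - centroids[None, :, :]
        dist = np.sqrt((diff**2).sum(-1))
        return DistanceMatrix(groups=labels, distances=dist, space=space)

    def loadings_report(self, top_n: int = 10, n_axes: int = 2) -> pd.DataFrame:
        """Features ranked by absolute loading, per axis."""
        rows = []
        for j in range(min(n_axes, self.n_components)):
            order = np.argsort(-np.abs(self.loadings[:, j]))
            for rank, i in enumerate(order[:top_n], start=1):
                rows.append(
                    {
                        "component": f"PC{j + 1}",
                        "rank": rank,
                        "feature": self.model.feature_cols[i],
                        "loading": float(self.loadings[i, j]),
                        "abs_loading": float(abs(self.loadings[i, j])),
                    }
                )
        return pd.DataFrame(rows)

    def density_dominated_axis(self) -> int:
        """Index of the PC most correlated with log_density.

        Uses the feature-component correlation |loading| * sqrt(explained
        variance) rather than the raw loading: a near-noise late component
        can carry a large loading on a single feature while explaining
        almost none of its variance.
        """
        i = self.model.feature_cols.index("log_density")
        weight = np.abs(self.loadings[i, :]) * np.sqrt(self.explained_fraction)
        return int(np.argmax(weight))

    # -- reporting ---------------------------------------------------------

    def summary(self, ellipse_level: float = 0.5) -> str:
        """Human-readable fit summary."""
        lines = [
            "Morphospace PCA results",
            "=======================",
            f"grains: {len(self.model.table)}   features: {len(self.model.feature_cols)}"
            f"   scaling: {self.model.scaling}",
            "",
            "Explained variance:",
        ]
        for name, frac in zip(self.pc_names[:5], self.explained_fraction[:5]):
            lines.append(f"  {name}: {100 * frac:6.2f}%")
        try:
            groups = self._groups()
        except ValueError:
            groups = None
        if groups is not None and groups.nunique() >= 2:
            lines.append("")
            lines.append(f"Group centroid distances ({DISTANCE_SPACES[0]}):")
            dm = self.centroid_distances()
            for i, a in enumerate(dm.groups):
                for b in dm.groups[i + 1 :]:
                    lines.append(f"  {a} <-> {b}: {dm.between(a, b):.3f}")
            lines.append("")
            lines.append(f"{int(100 * ellipse_level)}% confidence ellipses (PC1 x PC2):")
            for g, ell in self.group_ellipses(level=ellipse_level).items():
                flag = "  [degenerate]" if ell.degenerate else ""
                lines.append(
                    f"  {g}: center=({ell.center[0]:.3f}, {ell.center[1]:.3f}) "
                    f"semi-axes=({ell.semi_axes[0]:.3f}, {ell.semi_axes[1]:.3f}) "
                    f"area={ell.area:.3f}{flag}"
                )
        return "\n".join(lines)

    def save(self, out_dir: str | Path, ellipse_level: float = 0.5) -> None:
        """Write scores/loadings/variance/distances/ellipses to ``out_dir``."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.scores_frame().to_csv(out / "scores.csv", index=False)
        self.loadings_frame().to_csv(out / "loadings.csv")
        self.explained_frame().to_csv(out / "explained_variance.csv", index=False)
        try:
            groups = self._groups()
        except ValueError:
            groups = None
        if groups is not None and groups.nunique() >= 2:
            self.centroid_distances().to_frame().to_csv(out / "distances.csv")
            ellipses = {
                g: e.to_dict() for g, e in self.group_ellipses(ellipse_level).items()
            }
            (out / "ellipses.json").write_text(json.dumps(ellipses, indent=2) + "\n")
        elif groups is not None:
            logger.warning("fewer than 2 groups: centroid distances skipped")

    def plot(self, ax=None, ellipse_level: float = 0.5):
        """Scatter of PC1 x PC2 scores with group confidence ellipses."""
        import matplotlib.pyplot as plt
        from matplotlib.patches import Ellipse as MplEllipse

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 5))
        try:
            groups = self._groups()
        except ValueError:
            groups = pd.Series(["all"] * len(self.scores))
        cmap = plt.get_cmap("tab10")
        for i, g in enumerate(pd.unique(groups.dropna())):
            sel = (groups == g).to_numpy()
            pts = self.scores[sel, :2]
            color = cmap(i % 10)
            ax.scatter(pts[:, 0], pts[:, 1], s=12, alpha=0.6, color=color, label=str(g))
            if sel.sum() >= 3:
                ell = confidence_ellipse(pts, level=ellipse_level, group=str(g))
                if not ell.degenerate:
                    ax.add_patch(
                        MplEllipse(
                            ell.center,
                            2 * ell.semi_axes[0],
                            2 * ell.semi_axes[1],
                            angle=np.degrees(ell.angle_rad),
                            fill=False,
                            color=color,
                            lw=1.5,
                        )
                    )
        ax.set_xlabel(f"PC1 ({100 * self.explained_fraction[0]:.1f}%)")
        if self.n_components > 1:
            ax.set_ylabel(f"PC2 ({100 * self.explained_fraction[1]:.1f}%)")
        ax.legend(fontsize=8)
        return ax


def reproduction_report(
    table: pd.DataFrame,
    reference: dict,
    group_col: str = "group",
    fossil_groups: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Grid-search analysis conventions against externally supplied
    reference statistics.

    Published variance percentages and centroid distances depend on
    conventions the written protocol leaves open: PCA scaling (covariance
    vs correlation), the base of the size/density log, and whether centroid
    distances are taken in feature space or score space.  This harness
    refits the morphospace under every combination and reports each one's
    deviation from the reference values, flagging the best match.

    ``reference`` may contain: ``pc1_pct``, ``pc2_pct`` (all-grain PCA),
    ``fossil_pc1_pct``, ``fossil_pc2_pct`` (fossil-only PCA, requires
    ``fossil_groups``), and ``distances`` (a list of expected centroid
    distances, compared as sorted multisets).

    The input table is expected to carry natural-log size/density; the
    base-10 variant is obtained by rescaling those two columns.
    """
    rows = []
    log10_table = table.copy()
    for col in ("log_size", "log_density"):
        log10_table[col] = table[col] / np.log(10.0)
    for scaling in ("correlation", "covariance"):
        for log_base, tbl in (("e", table), ("10", log10_table)):
            res = Morphospace(
                tbl, group_col=group_col, scaling=scaling, drop_constant=True
            ).fit()
            fossil_res = None
            if fossil_groups is not None:
                sub = tbl[tbl[group_col].isin(list(fossil_groups))]
                if sub[group_col].nunique() >= 1 and len(sub) >= 3:
                    fossil_res = Morphospace(
                        sub,
                        group_col=group_col,
                        scaling=scaling,
                        drop_constant=True,
                    ).fit()
            for space in ("feature_40d", "pc_scores"):
                row = {
                    "scaling": scaling,
                    "log_base": log_base,
                    "distance_space": space,
                    "pc1_pct": 100.0 * res.explained_fraction[0],
                    "pc2_pct": 100.0 * res.explained_fraction[1],
                }
                if fossil_res is not None:
                    row["fossil_pc1_pct"] = 100.0 * fossil_res.explained_fraction[0]
                    row["fossil_pc2_pct"] = 100.0 * fossil_res.explained_fraction[1]
                dm = res.centroid_distances(space=space)
                pairs = [
                    dm.distances[i, j]
                    for i in range(len(dm.groups))
                    for j in range(i + 1, len(dm.groups))
                ]
                row["distances"] = sorted(float(d) for d in pairs)
                dev = 0.0
                n_terms = 0
                for key in ("pc1_pct", "pc2_pct", "fossil_pc1_pct", "fossil_pc2_pct"):
                    if key in reference and key in row:
                        dev += abs(row[key] - reference[key]) / max(abs(reference[key]), 1e-9)
                        n_terms += 1
                if "distances" in reference:
                    # each reference distance matched to the closest computed
                    # centroid pair (the reference need not list every pair)
                    for r in reference["distances"]:
                        g = min(row["distances"], key=lambda d: abs(d - r))
                        dev += abs(g - r) / max(abs(r), 1e-9)
                        n_terms += 1
                row["mean_relative_deviation"] = dev / max(n_terms, 1)
                rows.append(row)
    report = pd.DataFrame(rows)
    report["best_match"] = (
        report["mean_relative_deviation"] == report["mean_relative_deviation"].min()
    )
    return report
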