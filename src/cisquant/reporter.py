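"""Embryo-level dual-reporter quantitation.

The assay co-delivers two constructs per embryo: a regulated enhancer
driving the reporter and a constitutive internal-control construct.
Dividing reporter by control signal cancels per-embryo delivery
(electroporation) efficiency; per-experiment normalization to the mean
wildtype ratio then puts constructs on a common scale where wildtype = 1.
Confocal stacks are flattened by sum projection (conserving total
intensity) and intensities are averaged inside manually drawn notochord
ROIs.  Construct comparisons use pairwise t-tests with a pooled standard
deviation and Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from matplotlib.path import Path as MplPath
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ImageStack",
    "ROISet",
    "EmbryoMeasurement",
    "TestResult",
    "sum_project",
    "roi_mean",
    "measure_embryo",
    "embryo_ratio",
    "normalize_experiment",
    "primary_secondary_ratio",
    "pairwise_tests",
    "bh_adjust",
    "stars",
]


@dataclass
class ImageStack:
    """Multi-channel confocal Z-stack: voxels shaped (C, Z, Y, X)."""

    voxels: np.ndarray
    channel_roles: dict[str, int]  # e.g. {"reporter": 0, "control": 1}

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 4:
            raise ValueError("voxels must be (channels, Z, Y, X)")
        if self.voxels.shape[0] < 2:
            raise ValueError("need at least reporter and control channels")
        if np.any(self.voxels < 0):
            raise ValueError("intensities must be non-negative")

    def channel(self, role: str) -> int:
        if role not in self.channel_roles:
            raise KeyError(f"no channel with role {role!r}")
        return self.channel_roles[role]


@dataclass
class ROISet:
    """Polygons in projected (x, y) pixel coordinates.

    ``whole`` outlines the full notochord; ``primary`` and ``secondary``
    optionally outline the anterior-32-cell and posterior-8-cell lineages.
    """

    whole: np.ndarray
    primary: np.ndarray | None = None
    secondary: np.ndarray | None = None


@dataclass
class EmbryoMeasurement:
    """Mean ROI intensities for one embryo, per channel and lineage."""

    embryo_id: str
    replicate_id: str
    construct_id: str
    reporter_mean: float
    control_mean: float
    reporter_primary: float | None = None
    control_primary: float | None = None
    reporter_secondary: float | None = None
    control_secondary: float | None = None


def sum_project(stack: ImageStack, channel: str | int) -> np.ndarray:
    """Flatten one channel along Z by summation; total intensity conserved."""
    idx = stack.channel(channel) if isinstance(channel, str) else channel
    if not (0 <= idx < stack.voxels.shape[0]):
        raise KeyError(f"channel index {idx} out of range")
    return stack.voxels[idx].sum(axis=0)


def polygon_mask(shape: tuple[int, int], polygon: np.ndarray) -> np.ndarray:
    """Pixels whose centers fall inside the polygon (even-odd rule).

    Pixel (row y, col x) has its center at coordinate (x, y).
    """
    poly = np.asarray(polygon, dtype=float)
    if poly.ndim != 2 or poly.shape[1] != 2 or len(poly) < 3:
        raise ValueError("polygon must be an N x 2 array of (x, y) vertices, N >= 3")
    ny, nx = shape
    ys, xs = np.mgrid[0:ny, 0:nx]
    centers = np.column_stack([xs.ravel(), ys.ravel()])
    inside = MplPath(poly).contains_points(centers)
    return inside.reshape(shape)


def roi_mean(image: np.ndarray, polygon: np.ndarray) -> float:
    """Mean intensity of pixels whose centers lie inside the polygon."""
    image = np.asarray(image, dtype=float)
    mask = polygon_mask(image.shape, polygon)
    if not mask.any():
        raise ValueError("polygon encloses no pixel centers")
    return float(image[mask].mean())


def measure_embryo(
    stack: ImageStack,
    rois: ROISet,
    embryo_id: str,
    replicate_id: str,
    construct_id: str,
) -> EmbryoMeasurement:
    """Project, apply ROIs, and return per-embryo channel means."""
    reporter = sum_project(stack, "reporter")
    control = sum_project(stack, "control")

    def lineage(poly):
        if poly is None:
            return None, None
        return roi_mean(reporter, poly), roi_mean(control, poly)

    rp, cp = lineage(rois.primary)
    rs, cs = lineage(rois.secondary)
    return EmbryoMeasurement(
        embryo_id=embryo_id,
        replicate_id=replicate_id,
        construct_id=construct_id,
        reporter_mean=roi_mean(reporter, rois.whole),
        control_mean=roi_mean(control, rois.whole),
        reporter_primary=rp,
        control_primary=cp,
        reporter_secondary=rs,
        control_secondary=cs,
    )


def embryo_ratio(m: EmbryoMeasurement) -> float:
    """Reporter / internal-control ratio; cancels electroporation efficiency."""
    if m.control_mean is None or m.control_mean <= 0:
        raise ValueError(
            f"embryo {m.embryo_id}: no internal-control signal (control_mean <= 0); "
            "such embryos are excluded upstream"
        )
    return m.reporter_mean / m.control_mean


def primary_secondary_ratio(m: EmbryoMeasurement) -> float:
    """(reporter/control in primary) / (reporter/control in secondary)."""
    values = (m.reporter_primary, m.control_primary, m.reporter_secondary, m.control_secondary)
    if any(v is None for v in values):
        raise ValueError(f"embryo {m.embryo_id}: missing lineage measurements")
    if m.control_primary <= 0 or m.control_secondary <= 0:
        raise ValueError(f"embryo {m.embryo_id}: non-positive lineage control signal")
    return (m.reporter_primary / m.control_primary) / (
        m.reporter_secondary / m.control_secondary
    )


_TABLE_COLUMNS = [
    "embryo_id", "replicate_id", "construct_id",
    "raw_ratio", "normalized_ratio",
    "primary_ratio", "secondary_ratio", "primary_secondary_ratio",
]


def _to_frame(measurements) -> pd.DataFrame:
    if isinstance(measurements, pd.DataFrame):
        return measurements.copy()
    return pd.DataFrame([vars(m) for m in measurements])


def normalize_experiment(
    measurements,
    wildtype_construct_id: str,
) -> pd.DataFrame:
    """Per-embryo ratios scaled so each replicate's wildtype mean is 1.

    ``measurements`` is a list of :class:`EmbryoMeasurement` or an
    equivalent DataFrame.  Every replicate (one electroporation-day
    experiment) must contain at least one wildtype embryo, because the
    normalization anchor is estimated within replicate.  Lineage columns,
    when present, are normalized the same way against the wildtype lineage
    means; the primary/secondary ratio is the plain per-embryo ratio of
    lineage reporter/control ratios.
    """
    df = _to_frame(measurements)
    if df.empty:
        raise ValueError("no measurements")
    if (df["control_mean"] <= 0).any():
        bad = df.loc[df["control_mean"] <= 0, "embryo_id"].tolist()
        raise ValueError(f"embryos without internal-control signal: {bad}")
    df["raw_ratio"] = df["reporter_mean"] / df["control_mean"]

    has_lineage = {"reporter_primary", "control_primary", "reporter_secondary", "control_secondary"} <= set(df.columns)
    if has_lineage and df["reporter_primary"].notna().all():
        df["raw_primary"] = df["reporter_primary"] / df["control_primary"]
        df["raw_secondary"] = df["reporter_secondary"] / df["control_secondary"]
        df["primary_secondary_ratio"] = df["raw_primary"] / df["raw_secondary"]
    else:
        df["raw_primary"] = np.nan
        df["raw_secondary"] = np.nan
        df["primary_secondary_ratio"] = np.nan

    out = []
    for rep, grp in df.groupby("replicate_id", sort=False):
        wt = grp[grp["construct_id"] == wildtype_construct_id]
        if wt.empty:
            raise ValueError(
                f"replicate {rep!r} has no wildtype ({wildtype_construct_id!r}) embryos"
            )
        grp = grp.copy()
        grp["normalized_ratio"] = grp["raw_ratio"] / wt["raw_ratio"].mean()
        grp["primary_ratio"] = grp["raw_primary"] / wt["raw_primary"].mean()
        grp["secondary_ratio"] = grp["raw_secondary"] / wt["raw_secondary"].mean()
        out.append(grp)
    result = pd.concat(out, ignore_index=True)
    return result[_TABLE_COLUMNS]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment over a set of raw p-values."""
    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]


def stars(p: float) -> str:
    """Significance label at the 0.05 / 0.01 / 0.001 conventions."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class TestResult:
    pair: tuple[str, str]
    raw_p: float
    adjusted_p: float
    t_statistic: float
    stars: str


def pairwise_tests(
    groups: dict[str, "np.ndarray | list[float]"],
    pool_sd: bool = True,
) -> list[TestResult]:
    """All unordered pairwise t-tests with Benjamini-Hochberg adjustment.

    By default a single standard deviation is pooled across *all* groups
    (df = N - k), matching R's ``pairwise.t.test`` default; ``pool_sd=False``
    switches to per-pair Welch tests.
    """
    names = list(groups)
    arrays = {g: np.asarray(groups[g], dtype=float) for g in names}
    for g, a in arrays.items():
        if len(a) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    if len(names) < 2:
        raise ValueError("need at least two groups")

    if pool_sd:
        n_total = sum(len(a) for a in arrays.values())
        df_pool = n_total - len(names)
        ss = sum((len(a) - 1) * a.var(ddof=1) for a in arrays.values())
        sp = np.sqrt(ss / df_pool)

    results = []
    raw_ps = []
    t_stats = []
    pairs = list(itertools.combinations(names, 2))
    for g1, g2 in pairs:
        a, b = arrays[g1], arrays[g2]
        if pool_sd:
            se = sp * np.sqrt(1 / len(a) + 1 / len(b))
            t = 0.0 if se == 0 else (a.mean() - b.mean()) / se
            p = 2 * stats.t.sf(abs(t), df_pool) if se > 0 else 1.0
        else:
            t, p = stats.ttest_ind(a, b, equal_var=False)
        raw_ps.append(float(p))
        t_stats.append(float(t))
    adjusted = multipletests(raw_ps, method="fdr_bh")[1]
    for (g1, g2), raw_p, adj_p, t in zip(pairs, raw_ps, adjusted, t_stats):
        results.append(
            TestResult(pair=(g1, g2), raw_p=raw_p, adjusted_p=float(adj_p),
                       t_statistic=t, stars=stars(float(adj_p)))
        )
    return results


def tests_to_frame(results: list[TestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "construct_a": r.pair[0], "construct_b": r.pair[1],
                "t": r.t_statistic, "raw_p": r.raw_p,
                "adjusted_p": r.adjusted_p, "stars": r.stars,
            }
            for r in results
        ]
    )
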