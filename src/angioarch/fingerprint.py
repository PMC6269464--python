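"""V/D fingerprints: cumulated caliber trees, volume/dispersion curves,
straight-line fits and group comparison.

Starting from the largest-caliber class, classes are added in descending
order of caliber to form 7 progressively reconstituted vascular trees.  Each
tree is summarized by its percent vascular volume V% and its normalized
dispersion index nHv95%; the 7 (V%, nHv) points form a near-linear curve
whose slope, endpoints and axial projections constitute the vasculature's
"fingerprint":

* left end (level 1): amount and dispersion of the largest vessels;
* right end (level 7): amount and dispersion of the whole (sub-75 µm²) tree;
* slope (negative): dispersion gained per unit V% of progressively smaller
  vessels — shallow means dense microvessels adjacent to larger ones,
  steep means fewer, more distant small vessels;
* X length: microvascular volume contributed by vessels below the second
  boundary; Y length: the dispersion gain they contribute.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .caliber import ClassifiedStack
from .dispersion import DilationScheme, HaloConfig, normalized_halo
from .errors import DomainError
from .grid import BinaryStack, volume_fraction


@dataclass(frozen=True)
class VDPoint:
    """One point of a V/D curve: cumulation level, V% and dispersion."""

    level: int
    v_percent: float
    nhv: int
    raw_cycles: int
    offset_cycles: int
    #: True when this level's class was empty, so the tree duplicates the
    #: previous level; duplicate points are excluded from line fits.
    duplicate: bool = False


@dataclass
class VDCurve:
    """Ordered (V%, nHv) points of one sample, one per cumulation level."""

    sample_id: str
    points: list[VDPoint]

    def __post_init__(self) -> None:
        levels = [p.level for p in self.points]
        if levels != sorted(set(levels)):
            raise ValueError("points must have strictly increasing, unique levels")

    @property
    def v_values(self) -> np.ndarray:
        return np.array([p.v_percent for p in self.points])

    @property
    def nhv_values(self) -> np.ndarray:
        return np.array([p.nhv for p in self.points], dtype=float)

    def fit_points(self) -> list[tuple[float, float]]:
        """(V%, nHv) pairs excluding duplicate (empty-class) levels."""
        return [(p.v_percent, float(p.nhv)) for p in self.points if not p.duplicate]

    @property
    def x_length(self) -> float:
        """V% span between the first and last level."""
        return self.points[-1].v_percent - self.points[0].v_percent

    @property
    def y_length(self) -> float:
        """Dispersion drop between the first and last level."""
        return float(self.points[0].nhv - self.points[-1].nhv)


@dataclass
class MedianCurve:
    """Per-level medians with 25–75% interquartile ranges across samples."""

    levels: list[int]
    v_median: np.ndarray
    v_iqr: np.ndarray  # shape (n_levels, 2): 25th, 75th percentile
    nhv_median: np.ndarray
    nhv_iqr: np.ndarray
    n_samples: int

    def fit_points(self) -> list[tuple[float, float]]:
        return [(float(v), float(d)) for v, d in zip(self.v_median, self.nhv_median)]


@dataclass(frozen=True)
class LineFit:
    """Ordinary least squares of nHv on V%."""

    slope: float
    intercept: float
    r_squared: float
    slope_ci95: tuple[float, float]


@dataclass(frozen=True)
class FingerprintParams:
    """Descriptive parameters of a (near-linear) V/D curve."""

    slope: float
    intercept: float
    r_squared: float
    slope_ci95: tuple[float, float]
    left_end: tuple[float, float]
    right_end: tuple[float, float]
    x_length: float
    y_length: float

    def as_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "slope_ci95": list(self.slope_ci95),
            "left_end": list(self.left_end),
            "right_end": list(self.right_end),
            "x_length": self.x_length,
            "y_length": self.y_length,
        }


#: FingerprintParams attributes compared across groups.
COMPARED_PARAMETERS = (
    "slope",
    "left_v",
    "left_nhv",
    "right_v",
    "right_nhv",
    "x_length",
    "y_length",
)


@dataclass
class ParameterComparison:
    """Statistics of one fingerprint parameter across groups."""

    parameter: str
    group_stats: dict[str, dict]  # per group: median, q25, q75, min, max, n
    test: str                     # "t-test" or "anova+bonferroni"
    anova_p: float | None
    pairwise: dict[tuple[str, str], dict]  # raw_p, adjusted_p, significant, stars


@dataclass
class GroupComparison:
    alpha: float
    parameters: dict[str, ParameterComparison]


def cumulate_classes(classified: ClassifiedStack) -> list[BinaryStack]:
    """Build the progressively reconstituted vascular trees.

    Tree ``k`` is the union of caliber classes 1..k; over-caliber voxels are
    never included.  Returns exactly ``n_classes`` trees (7 by default); the
    last tree is the whole classified vasculature.
    """
    n = classified.scheme.n_classes
    labels = classified.labels
    trees: list[BinaryStack] = []
    mask = np.zeros(labels.shape, dtype=bool)
    for k in range(1, n + 1):
        mask = mask | (labels == k)
        trees.append(BinaryStack(classified.meta, mask.copy()))
    return trees


def batch_reference_volume(tree_sets: list[list[BinaryStack]]) -> float:
    """Greatest initial V% among all stacks entering an analysis batch.

    The batch spans all cumulation levels of all samples of all groups, so
    nHv axes remain comparable across groups.
    """
    if not tree_sets:
        raise DomainError("empty batch")
    return max(volume_fraction(t) for trees in tree_sets for t in trees)


def compute_vd_curve(
    trees: list[BinaryStack],
    scheme: DilationScheme | None = None,
    config: HaloConfig | None = None,
    sample_id: str = "",
) -> VDCurve:
    """V/D curve of one sample from its cumulated trees.

    Per tree: V% from the voxel count ratio, nHv from the normalized halo.
    A level whose tree equals the previous one (empty class) reuses the
    previous halo result and is flagged as duplicate.
    """
    if not trees:
        raise DomainError("no trees supplied")
    metas = {t.meta for t in trees}
    if len(metas) > 1:
        raise DomainError("all trees of one sample must share one grid geometry")
    points: list[VDPoint] = []
    prev_count = -1
    prev = None
    for level, tree in enumerate(trees, start=1):
        count = tree.signal_count
        if count == 0:
            raise DomainError(
                f"tree at level {level} of sample {sample_id!r} is empty; "
                "the largest caliber classes contain no voxels"
            )
        duplicate = count == prev_count
        if duplicate:
            halo = prev
        else:
            halo = normalized_halo(tree, scheme=scheme, config=config)
        points.append(
            VDPoint(
                level=level,
                v_percent=volume_fraction(tree),
                nhv=halo.nhv,
                raw_cycles=halo.raw_cycles,
                offset_cycles=halo.offset_cycles,
                duplicate=duplicate,
            )
        )
        prev_count, prev = count, halo
    return VDCurve(sample_id=sample_id, points=points)


def median_curve(curves: list[VDCurve]) -> MedianCurve:
    """Pointwise medians and 25–75 IQRs of V% and nHv across samples.

    Percentiles use linear interpolation between order statistics.
    """
    if not curves:
        raise DomainError("median of an empty set of curves")
    levels = [p.level for p in curves[0].points]
    for c in curves:
        if [p.level for p in c.points] != levels:
            raise DomainError("all curves must share the same levels")
    v = np.array([c.v_values for c in curves])          # samples × levels
    d = np.array([c.nhv_values for c in curves])
    return MedianCurve(
        levels=levels,
        v_median=np.median(v, axis=0),
        v_iqr=np.percentile(v, [25, 75], axis=0).T,
        nhv_median=np.median(d, axis=0),
        nhv_iqr=np.percentile(d, [25, 75], axis=0).T,
        n_samples=len(curves),
    )


def fit_line(points: list[tuple[float, float]]) -> LineFit:
    """Ordinary least squares of nHv on V% with a t-based 95% CI on the slope.

    Raises
    ------
    DomainError
        With fewer than 2 points or all-identical abscissae.
    """
    if len(points) < 2:
        raise DomainError("need at least 2 points to fit a line")
    x = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    if np.ptp(x) == 0:
        raise DomainError("degenerate fit: all V% values identical")
    res = stats.linregress(x, y)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else float(res.rvalue) ** 2
    if len(x) > 2 and np.isfinite(res.stderr):
        tcrit = stats.t.ppf(0.975, len(x) - 2)
        ci = (res.slope - tcrit * res.stderr, res.slope + tcrit * res.stderr)
    else:
        ci = (float("nan"), float("nan"))
    return LineFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        slope_ci95=(float(ci[0]), float(ci[1])),
    )


def extract_parameters(
    curve: VDCurve | MedianCurve,
    per_sample_lengths: list[tuple[float, float]] | None = None,
) -> FingerprintParams:
    """Descriptive parameters of a V/D curve.

    Endpoints come from the first and last level; slope, intercept and R²
    from the OLS fit on all (non-duplicate) levels.  For group-level output
    the projected lengths are the medians of the per-sample (x_length,
    y_length) pairs when supplied, not the median curve's own projections.
    """
    if isinstance(curve, MedianCurve):
        v = curve.v_median
        d = curve.nhv_median
    else:
        v = curve.v_values
        d = curve.nhv_values
    fit = fit_line(curve.fit_points())
    left = (float(v[0]), float(d[0]))
    right = (float(v[-1]), float(d[-1]))
    if per_sample_lengths is not None:
        x_len = float(np.median([l[0] for l in per_sample_lengths]))
        y_len = float(np.median([l[1] for l in per_sample_lengths]))
    else:
        x_len = right[0] - left[0]
        y_len = left[1] - right[1]
    return FingerprintParams(
        slope=fit.slope,
        intercept=fit.intercept,
        r_squared=fit.r_squared,
        slope_ci95=fit.slope_ci95,
        left_end=left,
        right_end=right,
        x_length=x_len,
        y_length=y_len,
    )


def _parameter_value(params: FingerprintParams, name: str) -> float:
    if name == "left_v":
        return params.left_end[0]
    if name == "left_nhv":
        return params.left_end[1]
    if name == "right_v":
        return params.right_end[0]
    if name == "right_nhv":
        return params.right_end[1]
    return getattr(params, name)


def significance_stars(p: float, alpha: float = 0.05) -> str:
    """Three-tier star convention: * <0.05, ** <0.01, *** <0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < alpha:
        return "*"
    return ""


def compare_groups(
    param_tables: dict[str, list[FingerprintParams]], alpha: float = 0.05
) -> GroupComparison:
    """Compare fingerprint parameters across treatment groups.

    Two groups: two-tailed unpaired Student's t-test per parameter.  More
    groups: one-way ANOVA followed by Bonferroni-adjusted pairwise t-tests
    (adjusted p = min(1, raw p × number of pairwise comparisons)).  Box-plot
    summary statistics (median, quartiles, range) are emitted per group.
    """
    names = list(param_tables)
    if len(names) < 2:
        raise DomainError("need at least 2 groups to compare")
    for g, plist in param_tables.items():
        if len(plist) < 2:
            raise DomainError(f"group {g!r} has fewer than 2 samples")
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    n_pairs = len(pairs)
    comparisons: dict[str, ParameterComparison] = {}
    for pname in COMPARED_PARAMETERS:
        values = {g: np.array([_parameter_value(p, pname) for p in plist])
                  for g, plist in param_tables.items()}
        group_stats = {
            g: {
                "median": float(np.median(v)),
                "q25": float(np.percentile(v, 25)),
                "q75": float(np.percentile(v, 75)),
                "min": float(v.min()),
                "max": float(v.max()),
                "n": int(v.size),
            }
            for g, v in values.items()
        }
        if len(names) == 2:
            test = "t-test"
            anova_p = None
            adjust = 1
        else:
            test = "anova+bonferroni"
            anova_p = float(stats.f_oneway(*values.values()).pvalue)
            adjust = n_pairs
        pairwise = {}
        for a, b in pairs:
            if np.ptp(values[a]) == 0 and np.ptp(values[b]) == 0 and \
                    values[a][0] == values[b][0]:
                raw_p = 1.0  # identical constant groups: no evidence of difference
            else:
                raw_p = float(stats.ttest_ind(values[a], values[b]).pvalue)
            adj_p = min(1.0, raw_p * adjust)
            pairwise[(a, b)] = {
                "raw_p": raw_p,
                "adjusted_p": adj_p,
                "significant": adj_p < alpha,
                "stars": significance_stars(adj_p, alpha),
            }
        comparisons[pname] = ParameterComparison(
            parameter=pname,
            group_stats=group_stats,
            test=test,
            anova_p=anova_p,
            pairwise=pairwise,
        )
    return GroupComparison(alpha=alpha, parameters=comparisons)
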