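"""Validity assessment of sparse-sampling ICV estimates.

For a spacing ``n`` each subject has ``n`` possible estimates (one per
offset), so a cohort of ``m`` subjects admits ``n^m`` ways of picking one
estimate per subject.  That space is explored by Monte Carlo: a
*combination* draws one offset uniformly per subject, and 2000
combinations are scored per estimation setting.  Each combination is
compared with the true volumes by four metrics —

* ICC(A,1): single-measure, absolute-agreement intraclass correlation
  from a two-way ANOVA with subjects as targets and {truth, estimate} as
  the two raters.  Unlike Pearson it penalizes systematic bias.  For the
  single-measure absolute-agreement form, the two-way *random* and
  *mixed* models give the same point estimate.
* Pearson's linear correlation.
* Generalized Jaccard index Σ min(xᵢ,yᵢ) / Σ max(xᵢ,yᵢ).
* Signed percentage error per member estimate, pooled over all members
  of all combinations.

:func:`evaluate` sweeps (spacing × orientation × method) settings,
reusing the same combinations across methods within a setting pair so
method contrasts are not confounded by sampling noise, and emits
percentile curves (5/25/50/75/95) plus a paired t-test table contrasting
the constant and spline interpolators via per-subject mean absolute
percentage errors (MAPE) over all offsets.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .estimator import METHODS, offset_estimates
from .mask_model import ORIENTATIONS, AreaProfile

logger = logging.getLogger(__name__)

PERCENTILES = (5, 25, 50, 75, 95)
METRICS = ("icc", "pearson", "jaccard", "abs_pct_error")

DEFAULT_SPACINGS = tuple(range(2, 51))
DEFAULT_COMBINATIONS = 2000

#: decision threshold for the paired tests
ALPHA = 0.05


# ---------------------------------------------------------------------------
# Combination sampling


@dataclass
class CombinationSample:
    """One random choice of offset per subject for a fixed spacing."""

    offsets: np.ndarray
    spacing_n: int
    orientation: str = ""
    seed: int | None = None

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=np.int64)
        if ((self.offsets < 0) | (self.offsets >= self.spacing_n)).any():
            raise ValueError("offsets must lie in [0, spacing_n - 1]")


def sample_combinations(
    n_subjects: int,
    spacing_n: int,
    count: int = DEFAULT_COMBINATIONS,
    seed: int | np.random.Generator | None = None,
    orientation: str = "",
) -> list[CombinationSample]:
    """Draw ``count`` combinations of per-subject offsets, uniformly i.i.d.

    Collisions are allowed (sampling with replacement across the ``n^m``
    combination space).  Reproducible for a given integer seed.
    """
    if spacing_n < 1 or count < 1 or n_subjects < 1:
        raise ValueError("n_subjects, spacing_n and count must all be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    matrix = rng.integers(0, spacing_n, size=(count, n_subjects))
    seed_tag = seed if isinstance(seed, int) else None
    return [
        CombinationSample(row, spacing_n, orientation, seed_tag) for row in matrix
    ]


def _offsets_matrix(combos: Sequence[CombinationSample]) -> np.ndarray:
    return np.stack([c.offsets for c in combos])


# ---------------------------------------------------------------------------
# Agreement metrics


@dataclass
class AnovaDecomposition:
    """Mean squares of the two-way ANOVA underlying the ICC."""

    ms_rows: float
    ms_cols: float
    ms_err: float
    n_targets: int
    k_raters: int

    def __post_init__(self) -> None:
        if self.n_targets < 2 or self.k_raters < 2:
            raise ValueError("need at least 2 targets and 2 raters")
        if min(self.ms_rows, self.ms_cols, self.ms_err) < -1e-9:
            raise ValueError("mean squares must be nonnegative")


def two_way_anova(data: np.ndarray) -> AnovaDecomposition:
    """Two-way (targets × raters) ANOVA decomposition of an n×k table."""
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2 or data.shape[1] < 2:
        raise ValueError("need an n x k table with n >= 2 targets, k >= 2 raters")
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    resid = data - row_means[:, None] - col_means[None, :] + grand
    ss_err = (resid**2).sum()
    return AnovaDecomposition(
        ms_rows=ss_rows / (n - 1),
        ms_cols=ss_cols / (k - 1),
        ms_err=ss_err / ((n - 1) * (k - 1)),
        n_targets=n,
        k_raters=k,
    )


def icc_from_anova(anova: AnovaDecomposition) -> float:
    """ICC(A,1) from a two-way ANOVA decomposition."""
    n, k = anova.n_targets, anova.k_raters
    denom = (
        anova.ms_rows
        + (k - 1) * anova.ms_err
        + (k / n) * (anova.ms_cols - anova.ms_err)
    )
    if denom <= 0:
        raise ValueError("degenerate ICC: zero total variance")
    return float((anova.ms_rows - anova.ms_err) / denom)


def icc_single_absolute(
    x: np.ndarray, y: np.ndarray, model: str = "random"
) -> float:
    """Single-measure absolute-agreement ICC between truths and estimates.

    ``model`` may be ``"random"`` or ``"mixed"``; the point estimate is
    identical for the two (they differ only in inferential framing), so
    both flags are accepted.
    """
    if model not in ("random", "mixed"):
        raise ValueError("model must be 'random' or 'mixed'")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D arrays of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired measurements")
    if np.ptp(x) == 0 and np.ptp(y) == 0 and x[0] == y[0]:
        raise ValueError("degenerate ICC: all values identical")
    return icc_from_anova(two_way_anova(np.column_stack([x, y])))


def _icc_rows(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Vectorized ICC(A,1) of ``x`` against each row of ``Y`` (k = 2 raters)."""
    n = x.size
    mx = x.mean()
    my = Y.mean(axis=1)
    grand = (mx + my) / 2.0
    row_means = (x[None, :] + Y) / 2.0
    ms_rows = 2.0 * ((row_means - grand[:, None]) ** 2).sum(axis=1) / (n - 1)
    ms_cols = n * (mx - my) ** 2 / 2.0
    d = x[None, :] - Y
    ms_err = ((d - d.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) / (2.0 * (n - 1))
    denom = ms_rows + ms_err + (2.0 / n) * (ms_cols - ms_err)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (ms_rows - ms_err) / denom
    out[denom <= 0] = np.nan
    return out


def _pearson_rows(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    xc = x - x.mean()
    Yc = Y - Y.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc**2).sum() * (Yc**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (Yc @ xc) / denom
    out[denom == 0] = np.nan
    return out


def jaccard_volumes(x: np.ndarray, y: np.ndarray) -> float:
    """Generalized Jaccard index Σ min(xᵢ,yᵢ) / Σ max(xᵢ,yᵢ) for volumes."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if (x <= 0).any() or (y <= 0).any():
        raise ValueError("Jaccard index requires strictly positive volumes")
    return float(np.minimum(x, y).sum() / np.maximum(x, y).sum())


def _jaccard_rows(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    return np.minimum(x, Y).sum(axis=1) / np.maximum(x, Y).sum(axis=1)


def percentage_error(estimate: float | np.ndarray, truth: float | np.ndarray):
    """Signed percentage error 100·(estimate − truth)/truth."""
    truth = np.asarray(truth, dtype=float)
    if (truth <= 0).any():
        raise ValueError("truth must be > 0")
    out = 100.0 * (np.asarray(estimate, dtype=float) - truth) / truth
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Paired interpolator comparison


@dataclass
class PairedComparison:
    """Paired t-test of per-subject MAPE: constant minus spline.

    A positive ``mean_diff`` means the spline interpolator achieved the
    lower mean absolute percentage error.
    """

    spacing_n: int
    orientation: str
    n_subjects: int
    t: float
    p: float
    mean_diff: float
    ci_low: float
    ci_high: float
    significant: bool


def _paired_t(diff: np.ndarray) -> tuple[float, float, float, float]:
    """Mean difference, t, two-sided p, and the t-critical half-width."""
    n = diff.size
    mean = diff.mean()
    sd = diff.std(ddof=1)
    if sd == 0:
        t_stat = 0.0 if mean == 0 else np.inf * np.sign(mean)
        p = 1.0 if mean == 0 else 0.0
        return mean, t_stat, p, 0.0
    se = sd / np.sqrt(n)
    t_stat = mean / se
    p = 2.0 * stats.t.sf(abs(t_stat), n - 1)
    half = stats.t.ppf(0.975, n - 1) * se
    return mean, float(t_stat), float(p), float(half)


def mape_per_subject(profile: AreaProfile, spacing_n: int, method: str) -> float:
    """Mean |percentage error| over all offsets of one subject's profile."""
    est = offset_estimates(profile, spacing_n, method)
    return float(np.abs(percentage_error(est, profile.total_volume)).mean())


def compare_interpolators(
    cohort: Sequence, spacing_n: int, orientation: str = "sagittal"
) -> PairedComparison:
    """Paired t-test of constant vs spline MAPE across a cohort.

    For every subject, the mean absolute percentage error over all ``n``
    offsets is computed under each interpolator; the per-subject
    differences (constant − spline) enter a two-sided paired t-test.
    """
    profiles, truths = _profiles_and_truths(cohort, orientation)
    if len(profiles) < 3:
        raise ValueError("need a cohort of at least 3 subjects")
    mapes = {}
    for method in ("constant", "spline"):
        per_subject = []
        for prof, truth in zip(profiles, truths):
            est = offset_estimates(prof, spacing_n, method)
            per_subject.append(np.abs(percentage_error(est, truth)).mean())
        mapes[method] = np.array(per_subject)
    diff = mapes["constant"] - mapes["spline"]
    mean, t_stat, p, half = _paired_t(diff)
    return PairedComparison(
        spacing_n=spacing_n,
        orientation=orientation,
        n_subjects=diff.size,
        t=t_stat,
        p=p,
        mean_diff=float(mean),
        ci_low=float(mean - half),
        ci_high=float(mean + half),
        significant=p <= ALPHA,
    )


def _profiles_and_truths(cohort: Sequence, orientation: str):
    """Accept either AreaProfiles or subjects carrying profiles + truth."""
    profiles, truths = [], []
    for item in cohort:
        if isinstance(item, AreaProfile):
            profiles.append(item)
            truths.append(item.total_volume)
        else:
            prof = item.profiles[orientation]
            profiles.append(prof)
            truths.append(float(getattr(item, "true_volume", prof.total_volume)))
    return profiles, truths


# ---------------------------------------------------------------------------
# Full evaluation sweep


@dataclass
class ValidityReport:
    """Percentile curves and paired tests for a sweep of settings.

    ``percentiles``: long-format table with columns
    ``spacing, orientation, method, metric, percentile, value``;
    ``means``: per-setting metric means (over combinations; pooled for
    the absolute percentage error); ``paired_tests``: one row per
    (spacing, orientation) contrasting constant vs spline MAPE.
    """

    percentiles: pd.DataFrame
    means: pd.DataFrame
    paired_tests: pd.DataFrame
    manifest: dict = field(default_factory=dict)

    def percentile(
        self, spacing: int, orientation: str, method: str, metric: str, q: int
    ) -> float:
        t = self.percentiles
        sel = t[
            (t.spacing == spacing)
            & (t.orientation == orientation)
            & (t.method == method)
            & (t.metric == metric)
            & (t.percentile == q)
        ]
        if len(sel) != 1:
            raise KeyError((spacing, orientation, method, metric, q))
        return float(sel.value.iloc[0])

    def mean(self, spacing: int, orientation: str, method: str, metric: str) -> float:
        t = self.means
        sel = t[
            (t.spacing == spacing)
            & (t.orientation == orientation)
            & (t.method == method)
            & (t.metric == metric)
        ]
        if len(sel) != 1:
            raise KeyError((spacing, orientation, method, metric))
        return float(sel.value.iloc[0])

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.percentiles.to_csv(out / "percentiles.csv", index=False)
        self.means.to_csv(out / "means.csv", index=False)
        self.paired_tests.to_csv(out / "paired_tests.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=2) + "\n")


def evaluate(
    cohort: Sequence,
    spacings: Iterable[int] = DEFAULT_SPACINGS,
    orientations: Sequence[str] = ORIENTATIONS,
    methods: Sequence[str] = METHODS,
    count: int = DEFAULT_COMBINATIONS,
    seed: int = 0,
) -> ValidityReport:
    """Sweep estimation settings and score them against the true volumes.

    For each (spacing, orientation) the ``count`` random combinations are
    drawn once from a substream keyed by ``(seed, orientation, spacing)``
    and reused across methods, so per-method contrasts share sampling
    noise and each setting is independently reproducible.  Degenerate
    metric values are recorded as NaN with a logged warning, never
    silently dropped.
    """
    spacings = list(spacings)
    orientations = list(orientations)
    methods = list(methods)
    for m in methods:
        if m not in METHODS:
            raise ValueError(f"unknown method {m!r}")
    subjects = list(cohort)
    m_subj = len(subjects)
    pct_rows, mean_rows, paired_rows = [], [], []
    truths_by_orient: dict[str, np.ndarray] = {}
    for oi, orient in enumerate(orientations):
        profiles, truths = _profiles_and_truths(subjects, orient)
        x = np.asarray(truths)
        truths_by_orient[orient] = x
        for spacing in spacings:
            E = {
                method: np.array(
                    [offset_estimates(p, spacing, method) for p in profiles]
                )
                for method in methods
            }
            rng = np.random.default_rng(
                [int(seed), oi, int(spacing)]
            )  # independent substream per setting pair
            combos = sample_combinations(
                m_subj, spacing, count, rng, orientation=orient
            )
            O = _offsets_matrix(combos)
            cols = np.arange(m_subj)
            for method in methods:
                Y = E[method][cols[None, :], O]
                icc = _icc_rows(x, Y)
                pear = _pearson_rows(x, Y)
                jac = _jaccard_rows(x, Y)
                abs_err = np.abs(100.0 * (Y - x[None, :]) / x[None, :]).ravel()
                for metric, vals in (
                    ("icc", icc),
                    ("pearson", pear),
                    ("jaccard", jac),
                    ("abs_pct_error", abs_err),
                ):
                    n_bad = int(np.isnan(vals).sum())
                    if n_bad:
                        logger.warning(
                            "%d degenerate %s values at spacing %d, %s, %s",
                            n_bad, metric, spacing, orient, method,
                        )
                    qs = np.nanpercentile(vals, PERCENTILES)
                    for q, v in zip(PERCENTILES, qs):
                        pct_rows.append((spacing, orient, method, metric, q, v))
                    mean_rows.append(
                        (spacing, orient, method, metric, float(np.nanmean(vals)))
                    )
            if "constant" in methods and "spline" in methods:
                mape = {
                    method: np.abs(
                        100.0 * (E[method] - x[:, None]) / x[:, None]
                    ).mean(axis=1)
                    for method in ("constant", "spline")
                }
                mean, t_stat, p, half = _paired_t(mape["constant"] - mape["spline"])
                paired_rows.append(
                    (spacing, orient, m_subj, t_stat, p, mean,
                     mean - half, mean + half, p <= ALPHA)
                )
    report = ValidityReport(
        percentiles=pd.DataFrame(
            pct_rows,
            columns=["spacing", "orientation", "method", "metric", "percentile", "value"],
        ),
        means=pd.DataFrame(
            mean_rows, columns=["spacing", "orientation", "method", "metric", "value"]
        ),
        paired_tests=pd.DataFrame(
            paired_rows,
            columns=["spacing", "orientation", "n_subjects", "t", "p",
                     "mean_diff", "ci_low", "ci_high", "significant"],
        ),
        manifest={
            "seed": int(seed),
            "count": int(count),
            "spacings": [int(s) for s in spacings],
            "orientations": orientations,
            "methods": methods,
            "n_subjects": m_subj,
            "percentiles": list(PERCENTILES),
        },
    )
    return report
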