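"""Cohort statistics: rank correlation, all-pairs rank comparison, rater
agreement, and test-retest repeatability.

Everything an index-validation study needs, implemented directly from the
defining formulas:

* Spearman rank correlation with mid-rank tie handling and the Student-t
  approximation for the two-sided p-value;
* the Steel-Dwass (Dwass-Steel-Critchlow-Fligner) all-pairs nonparametric
  comparison, with tie-corrected variance and familywise adjustment through
  the studentized-range distribution ``Q(k, inf)``;
* Fleiss kappa for a fixed number of raters assigning categorical grades;
* the intraclass correlation ICC(A,1) — two-way model, absolute agreement,
  single measurement — from the two-way ANOVA decomposition.

scipy supplies distribution primitives only (Student t tail, mid-ranks);
the statistics themselves are computed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from scipy.stats import t as student_t

from .errors import DegeneratePairError, UndefinedStatisticError
from .indices import EyeRecord, Grade

__all__ = [
    "CorrelationResult",
    "PairwiseComparison",
    "KappaResult",
    "ICCResult",
    "GroupSummary",
    "StudyReport",
    "spearman",
    "steel_dwass",
    "fleiss_kappa",
    "icc_absolute_single",
    "group_summary",
    "pooled_mean",
    "run_study",
    "studentized_range_sf",
]

P_FLOOR = np.finfo(float).tiny  # reported instead of 0 for |rho| = 1

# ---------------------------------------------------------------------------
# studentized range, infinite degrees of freedom
# ---------------------------------------------------------------------------

from scipy.special import ndtr  # standard normal CDF, vectorized


@lru_cache(maxsize=1)
def _gauss_legendre(n: int = 256, lo: float = -9.5, hi: float = 9.5):
    x, w = np.polynomial.legendre.leggauss(n)
    mid, half = (hi + lo) / 2.0, (hi - lo) / 2.0
    return mid + half * x, half * w


def studentized_range_sf(q, k: int):
    """P(Q >= q) for the range of ``k`` iid standard normals (df = inf).

    Uses the classical single integral
    ``F(q) = k * ∫ phi(u) [Phi(u) - Phi(u - q)]^(k-1) du``
    evaluated on a fixed Gauss-Legendre grid; absolute error is far below
    1e-12, and the call is vectorized in ``q`` (scipy's implementation of
    the same distribution is orders of magnitude slower per call).
    """
    if k < 2:
        raise ValueError(f"need k >= 2 groups, got {k}")
    q = np.asarray(q, dtype=np.float64)
    u, w = _gauss_legendre()
    phi = np.exp(-0.5 * u * u) / np.sqrt(2.0 * np.pi)
    qq = np.atleast_1d(q)[:, None]
    inner = ndtr(u) - ndtr(u - qq)
    cdf = k * np.sum(w * phi * np.clip(inner, 0.0, 1.0) ** (k - 1), axis=1)
    sf = np.clip(1.0 - cdf, 0.0, 1.0)
    sf = np.where(np.atleast_1d(q) <= 0, 1.0, sf)
    return float(sf[0]) if q.ndim == 0 else sf.reshape(q.shape)


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman rank correlation with two-sided p-value."""

    rho: float
    p_value: float
    n: int


@dataclass(frozen=True)
class PairwiseComparison:
    """One Steel-Dwass pair: standardized rank statistic and adjusted p."""

    group_a: Grade
    group_b: Grade
    t_statistic: float
    p_value: float


@dataclass(frozen=True)
class KappaResult:
    """Fleiss kappa with its agreement components."""

    kappa: float
    observed_agreement: float
    expected_agreement: float
    n_items: int
    n_raters: int
    n_categories: int


@dataclass(frozen=True)
class ICCResult:
    """ICC(A,1): two-way model, absolute agreement, single measurement."""

    icc: float
    ms_rows: float
    ms_cols: float
    ms_error: float
    n_subjects: int
    k_sessions: int


@dataclass(frozen=True)
class GroupSummary:
    """Per-grade mean ± sample SD of each index, groups ordered NT, WT, ST."""

    grades: tuple[Grade, ...]
    sizes: tuple[int, ...]
    means: dict  # index name -> tuple of per-group means
    sds: dict  # index name -> tuple of per-group sample SDs (ddof=1)
    empty_grades: tuple[Grade, ...] = ()


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def spearman(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation: Pearson correlation of mid-ranks.

    Ties receive average ranks.  The two-sided p-value uses the Student-t
    approximation ``t = rho * sqrt((n-2) / (1-rho^2))`` with ``n-2``
    degrees of freedom; ``|rho| = 1`` is reported with a sub-machine-floor
    p rather than NaN.  A constant input vector has no rank ordering and
    raises :class:`UndefinedStatisticError`.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"need n >= 3 observations, got {n}")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values are not supported")
    rx = rankdata(x, method="average")
    ry = rankdata(y, method="average")
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        raise UndefinedStatisticError("constant vector: rank correlation undefined")
    rho = float(np.mean((rx - rx.mean()) * (ry - ry.mean())) / (sx * sy))
    rho = max(-1.0, min(1.0, rho))
    if 1.0 - abs(rho) < 1e-12:  # exact monotone ordering up to FP rounding
        rho = 1.0 if rho > 0 else -1.0
    if abs(rho) == 1.0:
        p = P_FLOOR
    else:
        tstat = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
        p = float(2.0 * student_t.sf(abs(tstat), df=n - 2))
    return CorrelationResult(rho=rho, p_value=p, n=n)


def steel_dwass_pair_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Standardized rank-sum statistic of group ``a`` against group ``b``.

    The two groups are pooled and mid-ranked; with ``R_a`` the rank sum of
    group ``a``, ``E = n_a (N+1)/2`` its null expectation and the
    tie-corrected variance
    ``V = n_a n_b / (N (N-1)) * (sum r^2 - N (N+1)^2 / 4)``,
    the statistic is ``(R_a - E) / sqrt(V)``.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    na, nb = a.size, b.size
    N = na + nb
    ranks = rankdata(np.concatenate([a, b]), method="average")
    ra = ranks[:na].sum()
    expect = na * (N + 1) / 2.0
    var = na * nb / (N * (N - 1.0)) * (np.sum(ranks**2) - N * (N + 1.0) ** 2 / 4.0)
    if var <= 0:
        raise DegeneratePairError("all pooled values identical: zero rank variance")
    return float((ra - expect) / np.sqrt(var))


def steel_dwass(
    values: Sequence[float], groups: Sequence
) -> list[PairwiseComparison]:
    """All-pairs Steel-Dwass comparison over ``k`` groups.

    Each unordered pair is compared with the pairwise standardized rank
    statistic (ties mid-ranked, tie-corrected variance); familywise control
    comes from referring ``|t| * sqrt(2)`` to the studentized range
    ``Q(k, inf)`` where ``k`` is the total number of groups in the call.
    Pairs are returned in sorted ``(group_a, group_b)`` order.
    """
    values = np.asarray(values, dtype=np.float64)
    groups = np.asarray(groups)
    if values.shape != groups.shape or values.ndim != 1:
        raise ValueError("values and groups must be 1-d vectors of equal length")
    labels = sorted(set(groups.tolist()))
    k = len(labels)
    if k < 2:
        raise ValueError(f"need >= 2 groups, got {k}")
    samples = {lab: values[groups == lab] for lab in labels}
    for lab, s in samples.items():
        if s.size < 2:
            raise ValueError(f"group {lab} has size {s.size} < 2")
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = labels[i], labels[j]
            t = steel_dwass_pair_statistic(samples[a], samples[b])
            p = studentized_range_sf(abs(t) * np.sqrt(2.0), k)
            out.append(
                PairwiseComparison(group_a=a, group_b=b, t_statistic=t, p_value=p)
            )
    return out


def fleiss_kappa(counts: np.ndarray) -> KappaResult:
    """Fleiss kappa from an items x categories matrix of rating counts.

    With ``r`` raters per item, per-item agreement is
    ``P_i = (sum_j n_ij^2 - r) / (r (r-1))``; ``P_bar`` is its mean, the
    chance agreement is ``P_e = sum_j p_j^2`` for marginal category
    shares ``p_j``, and ``kappa = (P_bar - P_e) / (1 - P_e)``.
    """
    counts = np.asarray(counts, dtype=np.float64)
    if counts.ndim != 2:
        raise ValueError("counts must be a 2-d items x categories matrix")
    if (counts < 0).any() or not np.allclose(counts, np.round(counts)):
        raise ValueError("counts must be non-negative integers")
    n_items, n_cats = counts.shape
    row_sums = counts.sum(axis=1)
    r = row_sums[0]
    if not np.all(row_sums == r):
        raise ValueError("every item must be rated by the same number of raters")
    r = int(r)
    if r < 2:
        raise ValueError(f"need >= 2 raters, got {r}")
    p_i = (np.sum(counts**2, axis=1) - r) / (r * (r - 1.0))
    p_bar = float(p_i.mean())
    p_j = counts.sum(axis=0) / (n_items * r)
    p_e = float(np.sum(p_j**2))
    if p_e >= 1.0:
        raise UndefinedStatisticError(
            "all ratings in a single category: chance agreement = 1, kappa undefined"
        )
    kappa = (p_bar - p_e) / (1.0 - p_e)
    return KappaResult(
        kappa=float(kappa),
        observed_agreement=p_bar,
        expected_agreement=p_e,
        n_items=n_items,
        n_raters=r,
        n_categories=n_cats,
    )


def icc_absolute_single(measurements: np.ndarray) -> ICCResult:
    """ICC(A,1) from a subjects x sessions matrix (no missing cells).

    The two-way ANOVA decomposition gives row (subject), column (session)
    and error mean squares; the absolute-agreement, single-measurement
    coefficient is

    ``ICC = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n) (MS_C - MS_E))``.
    """
    x = np.asarray(measurements, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("measurements must be a 2-d subjects x sessions matrix")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError(f"need >= 2 subjects and >= 2 sessions, got {n} x {k}")
    if np.isnan(x).any():
        raise ValueError("missing cells are not supported")
    grand = x.mean()
    ss_total = float(np.sum((x - grand) ** 2))
    if ss_total == 0:
        raise UndefinedStatisticError("zero total variance: ICC undefined")
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * float(np.sum((row_means - grand) ** 2))
    ss_cols = n * float(np.sum((col_means - grand) ** 2))
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    denom = ms_rows + (k - 1) * ms_err + (k / n) * (ms_cols - ms_err)
    if denom == 0:
        raise UndefinedStatisticError(
            "degenerate mean-square configuration: ICC denominator is zero"
        )
    icc = (ms_rows - ms_err) / denom
    return ICCResult(
        icc=float(icc),
        ms_rows=ms_rows,
        ms_cols=ms_cols,
        ms_error=ms_err,
        n_subjects=n,
        k_sessions=k,
    )


def pooled_mean(group_means: Sequence[float], group_sizes: Sequence[int]) -> float:
    """Size-weighted mean of group means: ``sum(n_i m_i) / sum(n_i)``."""
    m = np.asarray(group_means, dtype=np.float64)
    n = np.asarray(group_sizes, dtype=np.float64)
    if m.shape != n.shape or m.ndim != 1:
        raise ValueError("means and sizes must be 1-d vectors of equal length")
    if (n <= 0).any():
        raise ValueError("group sizes must be positive")
    return float(np.sum(n * m) / np.sum(n))


TFI_NAMES = ("tfi1", "tfi2", "tfi3")


def group_summary(records: Sequence[EyeRecord]) -> GroupSummary:
    """Mean ± sample SD (divisor n-1) of each index per consensus grade."""
    if not records:
        raise ValueError("no records")
    present = []
    empty = []
    for g in (Grade.NT, Grade.WT, Grade.ST):
        if any(r.consensus == g for r in records):
            present.append(g)
        else:
            empty.append(g)
    means: dict = {name: [] for name in TFI_NAMES}
    sds: dict = {name: [] for name in TFI_NAMES}
    sizes = []
    for g in present:
        vals = [r for r in records if r.consensus == g]
        sizes.append(len(vals))
        for name in TFI_NAMES:
            v = np.array([getattr(r.tfi, name) for r in vals])
            means[name].append(float(v.mean()))
            sds[name].append(float(v.std(ddof=1)) if v.size > 1 else 0.0)
    return GroupSummary(
        grades=tuple(present),
        sizes=tuple(sizes),
        means={k: tuple(v) for k, v in means.items()},
        sds={k: tuple(v) for k, v in sds.items()},
        empty_grades=tuple(empty),
    )


# ---------------------------------------------------------------------------
# the study report
# ---------------------------------------------------------------------------

ALPHA = 0.05  # significance label threshold; labeling only, never filtering

COVARIATE_NAMES = ("age", "axial_length", "spherical_equivalent", "sfct", "nct")


@dataclass
class StudyReport:
    """Full analysis of one cohort.

    Mirrors the layout of an index-validation study: cohort descriptives,
    per-grade index summaries, all-pairs Steel-Dwass results per index,
    Spearman correlations of each index with choroidal thickness and axial
    length, and the Fleiss kappa of the three rater gradings.
    """

    n_eyes: int
    descriptives: pd.DataFrame  # variable, mean, sd, min, max
    groups: GroupSummary
    pairwise: dict  # index name -> list[PairwiseComparison]
    correlations: dict  # (index_or_var, covariate) -> CorrelationResult
    kappa: KappaResult
    warnings: list = field(default_factory=list)

    def groups_frame(self) -> pd.DataFrame:
        rows = []
        for gi, g in enumerate(self.groups.grades):
            row = {"grade": str(g), "n": self.groups.sizes[gi]}
            for name in TFI_NAMES:
                row[f"{name}_mean"] = self.groups.means[name][gi]
                row[f"{name}_sd"] = self.groups.sds[name][gi]
            rows.append(row)
        return pd.DataFrame(rows)

    def pairwise_frame(self) -> pd.DataFrame:
        rows = []
        for name in TFI_NAMES:
            for cmp_ in self.pairwise.get(name, []):
                rows.append(
                    {
                        "index": name,
                        "group_a": str(cmp_.group_a),
                        "group_b": str(cmp_.group_b),
                        "t_statistic": cmp_.t_statistic,
                        "p_value": cmp_.p_value,
                        "significant": "yes" if cmp_.p_value < ALPHA else "no",
                    }
                )
        return pd.DataFrame(
            rows,
            columns=[
                "index", "group_a", "group_b", "t_statistic", "p_value", "significant",
            ],
        )

    def correlations_frame(self) -> pd.DataFrame:
        rows = []
        for (a, b), res in self.correlations.items():
            rows.append(
                {
                    "variable": a,
                    "covariate": b,
                    "rho": res.rho,
                    "p_value": res.p_value,
                    "n": res.n,
                    "significant": "yes" if res.p_value < ALPHA else "no",
                }
            )
        return pd.DataFrame(
            rows, columns=["variable", "covariate", "rho", "p_value", "n", "significant"]
        )

    def write(self, out_dir: str | Path) -> None:
        """Write report_groups.csv, report_pairwise.csv, report_correlations.csv
        and a plain-text summary."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.groups_frame().to_csv(out / "report_groups.csv", index=False)
        self.pairwise_frame().to_csv(out / "report_pairwise.csv", index=False)
        self.correlations_frame().to_csv(out / "report_correlations.csv", index=False)
        (out / "report_summary.txt").write_text(self.text_summary())

    def text_summary(self) -> str:
        lines = [f"Cohort: {self.n_eyes} eyes", ""]
        lines.append("Descriptives (mean ± SD [min–max]):")
        for row in self.descriptives.itertuples():
            lines.append(
                f"  {row.variable:22s} {row.mean:8.3f} ± {row.sd:6.3f} "
                f"[{row.min:.3f}–{row.max:.3f}]"
            )
        lines.append("")
        lines.append("Index by tessellation grade (mean ± SD):")
        hdr = "  grade  n    " + "  ".join(f"{n:>15s}" for n in TFI_NAMES)
        lines.append(hdr)
        for gi, g in enumerate(self.groups.grades):
            cells = "  ".join(
                f"{self.groups.means[n][gi]:7.3f} ± {self.groups.sds[n][gi]:5.3f}"
                for n in TFI_NAMES
            )
            lines.append(f"  {str(g):5s}  {self.groups.sizes[gi]:<4d} {cells}")
        for g in self.groups.empty_grades:
            lines.append(f"  {str(g):5s}  absent from cohort")
        lines.append("")
        lines.append("All-pairs Steel-Dwass comparisons:")
        for name in TFI_NAMES:
            for c in self.pairwise.get(name, []):
                star = " *" if c.p_value < ALPHA else "  (n.s.)"
                lines.append(
                    f"  {name}  {str(c.group_a)} vs {str(c.group_b)}: "
                    f"t = {c.t_statistic:7.3f}, p = {c.p_value:.4f}{star}"
                )
        lines.append("")
        lines.append("Spearman correlations:")
        for (a, b), res in self.correlations.items():
            star = " *" if res.p_value < ALPHA else ""
            lines.append(
                f"  {a} vs {b}: rho = {res.rho:7.3f}, p = {res.p_value:.4f}{star}"
            )
        lines.append("")
        lines.append(
            f"Rater agreement: Fleiss kappa = {self.kappa.kappa:.3f} "
            f"(observed {self.kappa.observed_agreement:.3f}, "
            f"chance {self.kappa.expected_agreement:.3f}, "
            f"{self.kappa.n_items} eyes x {self.kappa.n_raters} raters)"
        )
        if self.warnings:
            lines.append("")
            lines.append("Warnings:")
            lines.extend(f"  {w}" for w in self.warnings)
        return "\n".join(lines) + "\n"


COHORT_CSV_COLUMNS = [
    "eye_id", "age", "axial_length", "spherical_equivalent", "sfct", "nct",
    "grade_rater1", "grade_rater2", "grade_rater3",
]


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Read the cohort metadata table; grades are validated as NT|WT|ST."""
    df = pd.read_csv(path, dtype={"eye_id": str})
    if list(df.columns) != COHORT_CSV_COLUMNS:
        raise ValueError(
            f"cohort CSV must have columns {COHORT_CSV_COLUMNS}, "
            f"got {list(df.columns)}"
        )
    for col in ("grade_rater1", "grade_rater2", "grade_rater3"):
        # dtype=object keeps Grade members; int64 inference would strip them
        df[col] = pd.Series(
            [Grade.parse(s) for s in df[col]], index=df.index, dtype=object
        )
    return df


def _grade_counts(records: Sequence[EyeRecord]) -> np.ndarray:
    counts = np.zeros((len(records), len(Grade)), dtype=int)
    for i, r in enumerate(records):
        for g in r.rater_grades:
            counts[i, int(g)] += 1
    return counts


def run_study(records: Sequence[EyeRecord]) -> StudyReport:
    """Run the full statistical battery over a cohort of eye records.

    Produces the group summaries, all-pairs Steel-Dwass comparisons per
    index, Spearman correlations of every index with SFCT, NCT and axial
    length (plus axial length against both thicknesses), and the Fleiss
    kappa of the rater grades.  Grades with fewer than 2 eyes are excluded
    from the pairwise tests with a warning.  The 0.05 threshold is applied
    only as a significance label in the report, never as a data filter.
    """
    records = list(records)
    if len(records) < 3:
        raise ValueError(f"need >= 3 eyes, got {len(records)}")
    warnings: list[str] = []

    desc_rows = []
    for var in COVARIATE_NAMES:
        v = np.array([getattr(r, var) for r in records], dtype=float)
        desc_rows.append(
            {"variable": var, "mean": v.mean(), "sd": v.std(ddof=1),
             "min": v.min(), "max": v.max()}
        )
    for name in TFI_NAMES:
        v = np.array([getattr(r.tfi, name) for r in records])
        desc_rows.append(
            {"variable": name, "mean": v.mean(), "sd": v.std(ddof=1),
             "min": v.min(), "max": v.max()}
        )
    descriptives = pd.DataFrame(desc_rows)

    groups = group_summary(records)
    for g in groups.empty_grades:
        warnings.append(f"grade {g} absent; omitted from pairwise tests")

    usable = [
        g for gi, g in enumerate(groups.grades) if groups.sizes[gi] >= 2
    ]
    for gi, g in enumerate(groups.grades):
        if groups.sizes[gi] < 2:
            warnings.append(
                f"grade {g} has only {groups.sizes[gi]} eye(s); "
                "omitted from pairwise tests"
            )
    pairwise: dict = {}
    if len(usable) >= 2:
        sub = [r for r in records if r.consensus in usable]
        glabels = np.array([int(r.consensus) for r in sub])
        for name in TFI_NAMES:
            vals = np.array([getattr(r.tfi, name) for r in sub])
            pairwise[name] = [
                PairwiseComparison(
                    group_a=Grade(c.group_a),
                    group_b=Grade(c.group_b),
                    t_statistic=c.t_statistic,
                    p_value=c.p_value,
                )
                for c in steel_dwass(vals, glabels)
            ]
    else:
        warnings.append("fewer than 2 usable grades; pairwise tests skipped")

    correlations: dict = {}
    ct_vars = ("sfct", "nct", "axial_length")
    for name in TFI_NAMES:
        iv = np.array([getattr(r.tfi, name) for r in records])
        for cov in ct_vars:
            cv = np.array([getattr(r, cov) for r in records])
            correlations[(name, cov)] = spearman(iv, cv)
    al = np.array([r.axial_length for r in records])
    for cov in ("sfct", "nct"):
        cv = np.array([getattr(r, cov) for r in records])
        correlations[("axial_length", cov)] = spearman(al, cv)

    kappa = fleiss_kappa(_grade_counts(records))

    return StudyReport(
        n_eyes=len(records),
        descriptives=descriptives,
        groups=groups,
        pairwise=pairwise,
        correlations=correlations,
        kappa=kappa,
        warnings=warnings,
    )
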