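"""Paired dual-timepoint statistics and the report tables.

For every feature and tumour group (all / benign / malignant) the early
and late cohort values are compared with the related-samples Wilcoxon
signed-rank test, and their monotone association measured with Spearman
correlation.  A feature is called significantly changed when the Wilcoxon
p is below 0.05, with the direction arrow given by the sign of the median
paired difference.  No multiple-testing correction is applied -- each of
the 99 features is tested at the nominal level and the number of tests is
carried in the report so the family-wise exposure is visible.

Inter-observer agreement uses the two-way random-effects, absolute
agreement, single-measure intraclass correlation ICC(2,1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .catalog import ALL_FEATURES, FAMILY_OF, FAMILY_SIZES
from .errors import ValidationError

#: largest n at which the exact signed-rank null distribution is used
EXACT_WILCOXON_MAX_N = 25


@dataclass
class PairedTestResult:
    statistic: float
    p: float
    n: int                 # pairs remaining after zero-difference removal
    method: str            # exact | normal | degenerate
    degenerate: bool = False


from functools import lru_cache


@lru_cache(maxsize=64)
def _signed_rank_cdf(n: int) -> np.ndarray:
    """CDF of the signed-rank statistic under the null, enumerating the
    2**n equiprobable sign assignments via convolution of the per-rank
    generating functions."""
    max_w = n * (n + 1) // 2
    counts = np.zeros(max_w + 1)
    counts[0] = 1.0
    for rank in range(1, n + 1):
        shifted = np.zeros_like(counts)
        shifted[rank:] = counts[:-rank]
        counts = counts + shifted
    return np.cumsum(counts / counts.sum())


def _exact_signed_rank_p(statistic: float, n: int) -> float:
    """Two-sided exact p: twice the tail beyond the observed statistic,
    using the symmetry of the null distribution."""
    cdf = _signed_rank_cdf(n)
    max_w = n * (n + 1) // 2
    lo = min(statistic, max_w - statistic)
    p = 2.0 * cdf[int(round(lo))]
    return min(1.0, float(p))


def wilcoxon_signed_rank(
    early, late, zero_method: str = "wilcox", method: str = "auto"
) -> PairedTestResult:
    """Related-samples Wilcoxon signed-rank test, two-sided.

    Zero differences are discarded (``wilcox``; ``pratt`` keeps them in the
    ranking), ties are mid-ranked.  For tie-free samples of n <= 25 the
    exact enumeration distribution is used; otherwise a normal
    approximation with tie-corrected variance.  ``method`` can force
    ``"exact"`` or ``"normal"``.  All differences zero gives p = 1 with
    the degenerate flag set.
    """
    if method not in ("auto", "exact", "normal"):
        raise ValidationError(f"unknown method {method!r}")
    early = np.asarray(early, dtype=float)
    late = np.asarray(late, dtype=float)
    if early.shape != late.shape:
        raise ValidationError("paired samples must have equal length")
    if zero_method not in ("wilcox", "pratt"):
        raise ValidationError(f"unknown zero_method {zero_method!r}")
    d = late - early
    if np.all(d == 0):
        return PairedTestResult(0.0, 1.0, 0, "degenerate", True)
    n0 = int((d == 0).sum())
    nz = d[d != 0] if zero_method == "wilcox" else d
    n_eff = int((nz != 0).sum())
    if n_eff < 5:
        raise ValidationError(f"need >= 5 non-zero paired differences, got {n_eff}")
    ranks = sps.rankdata(np.abs(nz))
    w_plus = float(ranks[nz > 0].sum())
    n = int(nz.size)
    has_ties = np.unique(np.abs(nz)).size != nz.size
    use_exact = (
        method == "exact"
        or (method == "auto" and n <= EXACT_WILCOXON_MAX_N)
    ) and not has_ties and zero_method == "wilcox"
    if method == "exact" and not use_exact:
        raise ValidationError("exact method requires tie-free data and wilcox zeros")
    if use_exact:
        p = _exact_signed_rank_p(w_plus, n)
        return PairedTestResult(w_plus, p, n_eff, "exact")
    # normal approximation with tie-corrected variance (Pratt additionally
    # subtracts the zero block from the moments)
    if zero_method == "pratt":
        mean = (n * (n + 1) - n0 * (n0 + 1)) / 4.0
        var = (n * (n + 1) * (2 * n + 1) - n0 * (n0 + 1) * (2 * n0 + 1)) / 24.0
        w_plus_c = float(ranks[nz > 0].sum())
        tie_vals = np.abs(nz[nz != 0])
    else:
        mean = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        w_plus_c = w_plus
        tie_vals = np.abs(nz)
    _, tie_counts = np.unique(tie_vals, return_counts=True)
    var -= (tie_counts**3 - tie_counts).sum() / 48.0
    if var <= 0:
        return PairedTestResult(w_plus_c, 1.0, n_eff, "degenerate", True)
    # continuity-corrected two-sided z; keeps the branch within 0.01 of the
    # exact enumeration at the n = 25 switchover
    z = max(abs(w_plus_c - mean) - 0.5, 0.0) / math.sqrt(var)
    p = 2.0 * sps.norm.sf(z)
    return PairedTestResult(w_plus_c, min(1.0, float(p)), n_eff, "normal")


@dataclass
class CorrelationResult:
    r: float
    p: float
    degenerate: bool = False


def spearman(early, late) -> CorrelationResult:
    """Spearman rank correlation (mid-ranks for ties), two-sided p by the
    t approximation."""
    early = np.asarray(early, dtype=float)
    late = np.asarray(late, dtype=float)
    if early.size != late.size or early.size < 4:
        raise ValidationError("spearman needs >= 4 paired observations")
    if np.unique(early).size < 2 or np.unique(late).size < 2:
        return CorrelationResult(float("nan"), float("nan"), True)
    r, p = sps.spearmanr(early, late)
    return CorrelationResult(float(r), float(p))


def icc_agreement(ratings: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single
    measure, for a subjects x raters matrix.

    Computed from the standard two-way mean-squares decomposition:
    ``(MS_R - MS_E) / (MS_R + (k-1) MS_E + k (MS_C - MS_E) / n)``.
    Degenerate between-subject variance (all subjects identical) yields
    NaN rather than an arbitrary value.
    """
    ratings = np.asarray(ratings, dtype=float)
    if ratings.ndim != 2 or ratings.shape[1] < 2 or ratings.shape[0] < 5:
        raise ValidationError("icc_agreement needs >= 5 subjects and >= 2 raters")
    n, k = ratings.shape
    grand = ratings.mean()
    row_means = ratings.mean(axis=1)
    col_means = ratings.mean(axis=0)
    ms_r = k * ((row_means - grand) ** 2).sum() / (n - 1)
    ms_c = n * ((col_means - grand) ** 2).sum() / (k - 1)
    resid = ratings - row_means[:, None] - col_means[None, :] + grand
    ms_e = (resid**2).sum() / ((n - 1) * (k - 1))
    denom = ms_r + (k - 1) * ms_e + k * (ms_c - ms_e) / n
    if denom == 0:
        return float("nan")
    return float((ms_r - ms_e) / denom)


@dataclass
class ComparisonRow:
    """Per-feature paired statistics for one tumour group."""

    feature: str
    family: str
    group: str
    n: int
    early_median: float
    early_min: float
    early_max: float
    late_median: float
    late_min: float
    late_max: float
    direction: str          # up | down | none
    wilcoxon_p: float
    spearman_r: float
    spearman_p: float
    degenerate: bool = False

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _direction(diffs: np.ndarray, p: float, alpha: float) -> str:
    if not (p < alpha):
        return "none"
    med = float(np.median(diffs))
    if med > 0:
        return "up"
    if med < 0:
        return "down"
    return "none"


def build_comparison_table(
    features: pd.DataFrame,
    alpha: float = 0.05,
    groups: tuple[str, ...] = ("all", "benign", "malignant"),
    zero_method: str = "wilcox",
    min_group_size: int = 5,
) -> list[ComparisonRow]:
    """Paired early/late statistics per feature and group.

    ``features`` is the wide per-scan table (columns ``patient_id``,
    ``timepoint``, ``group`` + the 99 features).  Patients missing either
    timepoint are dropped; pairs with a flagged-NA value for a feature are
    dropped for that feature only.  Groups with fewer than
    ``min_group_size`` complete patients are skipped.
    """
    for col in ("patient_id", "timepoint"):
        if col not in features.columns:
            raise ValidationError(f"feature table lacks required column {col!r}")
    wide_e = features[features["timepoint"] == "early"].set_index("patient_id")
    wide_l = features[features["timepoint"] == "late"].set_index("patient_id")
    common = wide_e.index.intersection(wide_l.index)
    wide_e = wide_e.loc[common]
    wide_l = wide_l.loc[common]
    patient_group = wide_e["group"] if "group" in wide_e.columns else pd.Series("unknown", index=common)

    rows: list[ComparisonRow] = []
    for group in groups:
        sel = np.ones(len(common), dtype=bool) if group == "all" else (patient_group == group).to_numpy()
        if sel.sum() < min_group_size:
            continue
        for feat in ALL_FEATURES:
            e = wide_e.loc[common[sel], feat].to_numpy(dtype=float)
            l = wide_l.loc[common[sel], feat].to_numpy(dtype=float)
            ok = np.isfinite(e) & np.isfinite(l)
            e, l = e[ok], l[ok]
            if e.size < min_group_size:
                rows.append(
                    ComparisonRow(
                        feat, FAMILY_OF[feat], group, int(e.size),
                        *(float("nan"),) * 6, "none", float("nan"),
                        float("nan"), float("nan"), True,
                    )
                )
                continue
            try:
                wt = wilcoxon_signed_rank(e, l, zero_method=zero_method)
            except ValidationError:
                wt = PairedTestResult(float("nan"), float("nan"), 0, "degenerate", True)
            sp = spearman(e, l) if e.size >= 4 else CorrelationResult(float("nan"), float("nan"), True)
            p = wt.p if np.isfinite(wt.p) else 1.0
            rows.append(
                ComparisonRow(
                    feature=feat,
                    family=FAMILY_OF[feat],
                    group=group,
                    n=int(e.size),
                    early_median=float(np.median(e)),
                    early_min=float(e.min()),
                    early_max=float(e.max()),
                    late_median=float(np.median(l)),
                    late_min=float(l.min()),
                    late_max=float(l.max()),
                    direction=_direction(l - e, p, alpha),
                    wilcoxon_p=wt.p,
                    spearman_r=sp.r,
                    spearman_p=sp.p,
                    degenerate=wt.degenerate or sp.degenerate,
                )
            )
    return rows


@dataclass
class FamilySummary:
    group: str
    family: str
    family_size: int
    n_significant: int
    n_up: int
    n_down: int


def summarize_families(table: list[ComparisonRow]) -> list[FamilySummary]:
    """Counts of significantly changed features per family and group,
    split by direction; denominators are the fixed family sizes
    37/25/31/6 (+ total 99)."""
    out: list[FamilySummary] = []
    groups = sorted({r.group for r in table}, key=lambda g: ("all", "benign", "malignant").index(g))
    for group in groups:
        rows_g = [r for r in table if r.group == group]
        total_up = total_down = 0
        for family in ("first", "second", "high", "fractal"):
            rows_f = [r for r in rows_g if r.family == family]
            up = sum(r.direction == "up" for r in rows_f)
            down = sum(r.direction == "down" for r in rows_f)
            total_up += up
            total_down += down
            out.append(
                FamilySummary(group, family, FAMILY_SIZES[family], up + down, up, down)
            )
        out.append(FamilySummary(group, "total", 99, total_up + total_down, total_up, total_down))
    return out


def comparison_frame(table: list[ComparisonRow]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in table])


def summary_frame(summaries: list[FamilySummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])


_ARROW = {"up": "↑", "down": "↓", "none": "-"}


def comparison_markdown(table: list[ComparisonRow]) -> str:
    """Markdown report mirroring the per-feature comparison layout:
    medians (ranges) per timepoint, direction arrow and p per group,
    Spearman r (p) for all tumours."""
    by_feat: dict[str, dict[str, ComparisonRow]] = {}
    for r in table:
        by_feat.setdefault(r.feature, {})[r.group] = r
    n_tests = sum(1 for r in table if not r.degenerate)
    lines = [
        "# Early vs late feature comparison",
        "",
        f"Wilcoxon signed-rank tests performed (uncorrected): {n_tests}",
        "",
        "| Feature | Early median (range) | Late median (range) | dir (all) | p (all) "
        "| r (p) | dir (benign) | p (benign) | dir (malignant) | p (malignant) |",
        "|---|---|---|---|---|---|---|---|---|---|",
    ]

    def _fmt(x: float) -> str:
        if not np.isfinite(x):
            return "NA"
        return f"{x:.4g}"

    for feat in ALL_FEATURES:
        groups = by_feat.get(feat, {})
        a = groups.get("all")
        if a is None:
            continue
        b = groups.get("benign")
        m = groups.get("malignant")
        cells = [
            feat,
            f"{_fmt(a.early_median)} ({_fmt(a.early_min)}–{_fmt(a.early_max)})",
            f"{_fmt(a.late_median)} ({_fmt(a.late_min)}–{_fmt(a.late_max)})",
            _ARROW[a.direction],
            _fmt(a.wilcoxon_p),
            f"{_fmt(a.spearman_r)} ({_fmt(a.spearman_p)})",
            _ARROW[b.direction] if b else "NA",
            _fmt(b.wilcoxon_p) if b else "NA",
            _ARROW[m.direction] if m else "NA",
            _fmt(m.wilcoxon_p) if m else "NA",
        ]
        lines.append("| " + " | ".join(cells) + " |")
    lines.append("")
    return "\n".join(lines)
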