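"""Cohort comparison statistics.

The procedure mirrors standard clinical-imaging practice: a
Kolmogorov–Smirnov (Lilliefors) normality gate, two-sided pooled-variance
Student's t-tests per variable with a Bonferroni-corrected family
significance level, and Pearson correlations between measurement families
(e.g. disc Hb sectors against peripapillary RNFL thicknesses, or against
disease stage).  The normality gate is advisory — it is logged, never used
to switch tests silently.

Families and their Bonferroni sizes follow the report layout: the Hb
family (mean + 24 sectors, m = 25, 0.05/25 = 0.002), the Cirrus RNFL
family (mean + 4 quadrants + 12 clock hours, m = 17, level ≈ 0.003) and
the Spectralis family (mean + 4 quadrants + 4 sectors, m = 9, ≈ 0.006).
"""

from __future__ import annotations

import io as _io
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from onhcolor.exceptions import InsufficientSampleError, ValidationError

__all__ = [
    "NormalityResult",
    "ComparisonRow",
    "CorrelationResult",
    "normality_gate",
    "bonferroni_alpha",
    "compare_groups",
    "correlate",
    "report_tables",
    "HB_VARIABLES",
    "CIRRUS_VARIABLES",
    "SPECTRALIS_VARIABLES",
]

logger = logging.getLogger(__name__)

GROUPS = ("healthy", "PD")

HB_VARIABLES = ["mean_hb"] + [f"hb_{s}" for s in range(1, 25)]
CIRRUS_VARIABLES = (
    ["cirrus_mean"]
    + [f"cirrus_{q}" for q in ("superior", "nasal", "inferior", "temporal")]
    + [f"cirrus_h{h}" for h in range(1, 13)]
)
SPECTRALIS_VARIABLES = (
    ["spectralis_mean"]
    + [f"spectralis_{q}" for q in ("superior", "nasal", "inferior", "temporal")]
    + [f"spectralis_{s}" for s in ("superonasal", "inferonasal", "inferotemporal", "superotemporal")]
)


@dataclass(frozen=True)
class NormalityResult:
    normal: bool
    statistic: float
    p_value: float
    n: int


@dataclass(frozen=True)
class ComparisonRow:
    """One variable's two-group comparison (group 1 = healthy, 2 = PD)."""

    variable: str
    n1: int
    n2: int
    mean1: float
    sd1: float
    mean2: float
    sd2: float
    t_stat: float
    p_value: float
    alpha_corrected: float
    significant: bool
    degenerate: bool = False

    @property
    def difference(self) -> float:
        return self.mean1 - self.mean2


@dataclass(frozen=True)
class CorrelationResult:
    left: str
    right: str
    pearson_r: float
    p_value: float
    n: int
    flagged: bool = False


def normality_gate(values, alpha: float = 0.05) -> NormalityResult:
    """Lilliefors-style KS test against a normal with estimated mean/sd.

    Advisory: the pipeline logs the verdict and proceeds with t-tests
    either way.  A zero-variance (constant) sample is degenerate and
    reported non-normal.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 5:
        raise InsufficientSampleError(f"normality gate needs n >= 5, got {x.size}")
    if np.ptp(x) == 0:
        return NormalityResult(normal=False, statistic=np.inf, p_value=0.0, n=x.size)
    from statsmodels.stats.diagnostic import lilliefors

    stat, p = lilliefors(x, dist="norm")
    normal = bool(p >= alpha)
    logger.info("normality gate: n=%d D=%.4f p=%.4f -> %s", x.size, stat, p,
                "normal" if normal else "non-normal")
    return NormalityResult(normal=normal, statistic=float(stat), p_value=float(p), n=x.size)


def bonferroni_alpha(base_alpha: float, m: int) -> float:
    """Family-corrected significance level ``base_alpha / m``."""
    if m < 1:
        raise ValidationError(f"comparison count must be >= 1, got {m}")
    if not 0.0 < base_alpha < 1.0:
        raise ValidationError(f"base alpha must be in (0, 1), got {base_alpha}")
    return base_alpha / m


def compare_groups(
    cohort: pd.DataFrame,
    variables: list[str],
    base_alpha: float = 0.05,
    group_col: str = "group",
    welch: bool = False,
) -> list[ComparisonRow]:
    """Two-sided Student's t per variable with Bonferroni family correction.

    The pooled-variance (classic Student) test is the default; Welch's
    unequal-variance variant is available behind ``welch=True`` for
    sensitivity analyses when group SDs differ markedly.  Missing values
    are dropped per variable (complete-case).  Rows are returned in the
    input variable order.
    """
    if not variables:
        raise ValidationError("no variables to compare")
    alpha_c = bonferroni_alpha(base_alpha, len(variables))
    rows: list[ComparisonRow] = []
    for var in variables:
        x1 = cohort.loc[cohort[group_col] == GROUPS[0], var].dropna().to_numpy(float)
        x2 = cohort.loc[cohort[group_col] == GROUPS[1], var].dropna().to_numpy(float)
        if x1.size < 2 or x2.size < 2:
            raise InsufficientSampleError(f"{var}: both groups need n >= 2")
        m1, m2 = x1.mean(), x2.mean()
        s1 = x1.std(ddof=1)
        s2 = x2.std(ddof=1)
        degenerate = False
        if s1 == 0.0 and s2 == 0.0:
            if m1 == m2:
                t, p = 0.0, 1.0
            else:  # zero variance but different means: t undefined
                t, p, degenerate = np.inf, 0.0, True
        else:
            t, p = sps.ttest_ind(x1, x2, equal_var=not welch)
        rows.append(
            ComparisonRow(
                variable=var,
                n1=int(x1.size), n2=int(x2.size),
                mean1=float(m1), sd1=float(s1),
                mean2=float(m2), sd2=float(s2),
                t_stat=float(t), p_value=float(p),
                alpha_corrected=alpha_c,
                significant=bool(p < alpha_c),
                degenerate=degenerate,
            )
        )
    return rows


def correlate(
    cohort: pd.DataFrame,
    left: list[str],
    right: list[str],
) -> pd.DataFrame:
    """Pearson r (two-sided p) for every left x right variable pair.

    Pairwise-complete observations; pairs with a zero-variance column are
    returned with NaN r and ``flagged=True``.  The result is a tidy frame
    with columns left, right, pearson_r, p_value, n, flagged.
    """
    out: list[CorrelationResult] = []
    for lv in left:
        for rv in right:
            cols = [lv] if lv == rv else [lv, rv]
            sub = cohort[cols].dropna()
            n = len(sub)
            if n < 3:
                raise InsufficientSampleError(f"({lv}, {rv}): need n >= 3, got {n}")
            x = sub[lv].to_numpy(float)
            y = sub[rv].to_numpy(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                logger.warning("correlate: zero-variance column in (%s, %s)", lv, rv)
                out.append(CorrelationResult(lv, rv, np.nan, np.nan, n, flagged=True))
                continue
            r, p = sps.pearsonr(x, y)
            out.append(CorrelationResult(lv, rv, float(r), float(p), n))
    return pd.DataFrame(out)


def report_tables(rows: list[ComparisonRow], family_alpha: float | None = None) -> tuple[str, str]:
    """Format comparison rows as (CSV, Markdown) report strings.

    Column order is fixed: variable, healthy "mean (SD)", PD "mean (SD)",
    P, significant.  The family-corrected level is printed in a footnote.
    CSV additionally carries the raw numeric columns so the report
    round-trips without loss.
    """
    if not rows:
        raise ValidationError("no comparison rows to report")
    alpha = family_alpha if family_alpha is not None else rows[0].alpha_corrected
    df = pd.DataFrame(
        {
            "variable": [r.variable for r in rows],
            "healthy_mean_sd": [f"{r.mean1:.2f} ({r.sd1:.2f})" for r in rows],
            "pd_mean_sd": [f"{r.mean2:.2f} ({r.sd2:.2f})" for r in rows],
            "p_value": [r.p_value for r in rows],
            "significant": [r.significant for r in rows],
            "n1": [r.n1 for r in rows],
            "n2": [r.n2 for r in rows],
            "mean1": [r.mean1 for r in rows],
            "sd1": [r.sd1 for r in rows],
            "mean2": [r.mean2 for r in rows],
            "sd2": [r.sd2 for r in rows],
            "t_stat": [r.t_stat for r in rows],
        }
    )
    buf = _io.StringIO()
    df.to_csv(buf, index=False)
    csv_text = buf.getvalue()

    lines = [
        "| Variable | Healthy mean (SD) | PD mean (SD) | P | Significant |",
        "|---|---|---|---|---|",
    ]
    for r in rows:
        p_txt = f"**{r.p_value:.3g}**" if r.significant else f"{r.p_value:.3g}"
        lines.append(
            f"| {r.variable} | {r.mean1:.2f} ({r.sd1:.2f}) | "
            f"{r.mean2:.2f} ({r.sd2:.2f}) | {p_txt} | {'*' if r.significant else ''} |"
        )
    lines.append("")
    lines.append(
        f"Significant: P < {alpha:.4g} (Student's t with Bonferroni correction, "
        f"family of {len(rows)} comparisons)."
    )
    return csv_text, "\n".join(lines)
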