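"""Agreement between manual and semi-automatic counts.

Implements the validation layer for paired counts of the same scans by two
methods (raters): the intraclass correlation coefficient and Bland-Altman
analysis, plus diagnostics of the Bland-Altman point cloud (trend of the
differences with the pair means; homogeneity of the difference variability
between the low-count and high-count halves).

Conventions
-----------
* Differences are ``d = manual - semi`` throughout.
* ICC defaults to the two-way, absolute-agreement, single-measures form
  ICC(A,1): with n subjects and k = 2 raters, from the two-way ANOVA mean
  squares MSR (subjects), MSC (raters) and MSE,

      ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE)).

  Absolute agreement is the clinical question here (a systematic offset
  between the counting modalities must lower the coefficient); the
  consistency form ICC(C,1) is available via ``model="consistency"``.
* Limits of agreement are ``bias ± 1.96 · SD(d)`` with the n-1 sample SD;
  ``loa_halfwidth`` is the 1.96·SD half-width.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["PairedCounts", "AgreementStats", "icc", "bland_altman",
           "cloud_diagnostics", "agree_report"]


@dataclass(frozen=True)
class PairedCounts:
    """Manual and semi-automatic counts of the same n >= 2 scans."""

    manual: np.ndarray
    semi: np.ndarray
    ids: tuple | None = None

    def __post_init__(self):
        m = np.asarray(self.manual, dtype=np.float64)
        s = np.asarray(self.semi, dtype=np.float64)
        if m.ndim != 1 or s.ndim != 1 or len(m) != len(s):
            raise ValueError("manual and semi must be 1-D and equal length")
        if len(m) < 2:
            raise ValueError("need at least 2 pairs")
        if (m < 0).any() or (s < 0).any():
            raise ValueError("counts must be non-negative")
        if self.ids is not None and len(self.ids) != len(m):
            raise ValueError("ids length must match the counts")
        m.setflags(write=False)
        s.setflags(write=False)
        object.__setattr__(self, "manual", m)
        object.__setattr__(self, "semi", s)

    @property
    def n(self) -> int:
        return len(self.manual)

    @property
    def differences(self) -> np.ndarray:
        return self.manual - self.semi

    @property
    def means(self) -> np.ndarray:
        return (self.manual + self.semi) / 2.0


@dataclass(frozen=True)
class AgreementStats:
    """Bundled agreement summary for one manual-vs-method comparison."""

    n: int
    icc: float
    bias: float
    loa_halfwidth: float
    trend_slope: float = math.nan
    trend_p: float = math.nan
    levene_p: float = math.nan
    notes: str = ""


def icc(paired: PairedCounts, model: str = "absolute") -> float:
    """Intraclass correlation for n subjects x 2 raters.

    ``model`` is "absolute" (ICC(A,1), default) or "consistency" (ICC(C,1)).
    All-identical data (zero total variance) is perfect agreement by
    convention: returns 1.0 with a warning.
    """
    if model not in ("absolute", "consistency"):
        raise ValueError("model must be 'absolute' or 'consistency'")
    table = np.column_stack([paired.manual, paired.semi])
    n, k = table.shape
    grand = table.mean()
    if np.allclose(table, grand):
        warnings.warn("all values identical; ICC defined as 1.0",
                      stacklevel=2)
        return 1.0
    row_means = table.mean(axis=1)
    col_means = table.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((table - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if model == "consistency":
        return float((msr - mse) / (msr + (k - 1) * mse))
    return float((msr - mse)
                 / (msr + (k - 1) * mse + (k / n) * (msc - mse)))


def bland_altman(paired: PairedCounts) -> dict:
    """Bias (mean of d = manual - semi) and 1.96·SD limits half-width."""
    d = paired.differences
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return {"bias": bias, "loa_halfwidth": 1.96 * sd}


def cloud_diagnostics(paired: PairedCounts) -> dict:
    """Trend and variability-homogeneity diagnostics of the (m, d) cloud.

    Trend: OLS of d on the pair means m, slope with its two-sided p-value.
    Homogeneity: pairs split at the median of m; Brown-Forsythe/Levene test
    (absolute deviations from the group medians) on d between the halves.
    Requires n >= 4.
    """
    if paired.n < 4:
        raise ValueError(
            f"cloud diagnostics need at least 4 pairs, got {paired.n}")
    d = paired.differences
    m = paired.means
    if np.ptp(m) == 0:
        return {"trend_slope": math.nan, "trend_p": math.nan,
                "levene_p": math.nan,
                "notes": "all pair means identical; trend undefined"}
    fit = stats.linregress(m, d)
    med = np.median(m)
    low, high = d[m <= med], d[m > med]
    if (len(low) >= 2 and len(high) >= 2
            and (np.ptp(low) > 0 or np.ptp(high) > 0)):
        levene_p = float(stats.levene(low, high, center="median").pvalue)
    else:
        levene_p = math.nan   # degenerate: no variability to compare
    return {"trend_slope": float(fit.slope), "trend_p": float(fit.pvalue),
            "levene_p": levene_p, "notes": ""}


def agree_report(paired: PairedCounts, model: str = "absolute",
                 plots_dir=None, prefix: str = "agreement") -> AgreementStats:
    """ICC + Bland-Altman + cloud diagnostics, optionally with plots.

    With fewer than 4 pairs the cloud diagnostics are refused (reported as
    NaN with an explanatory note); ICC and Bland-Altman are always computed.
    When ``plots_dir`` is given, a manual-vs-semi scatterplot with identity
    line and a Bland-Altman plot (d vs m with bias and ±1.96·SD lines) are
    written there as PNG.
    """
    ba = bland_altman(paired)
    icc_val = icc(paired, model=model)
    if paired.n >= 4:
        diag = cloud_diagnostics(paired)
        notes = diag.pop("notes")
    else:
        diag = {"trend_slope": math.nan, "trend_p": math.nan,
                "levene_p": math.nan}
        notes = (f"cloud diagnostics refused: need >= 4 pairs, "
                 f"got {paired.n}")
    result = AgreementStats(n=paired.n, icc=icc_val, notes=notes,
                            **ba, **diag)
    if plots_dir is not None:
        _write_plots(paired, result, plots_dir, prefix)
    return result


def _write_plots(paired, result, plots_dir, prefix):
    import pathlib

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plots_dir = pathlib.Path(plots_dir)
    plots_dir.mkdir(parents=True, exist_ok=True)

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(paired.manual, paired.semi, s=14, alpha=0.7)
    lim = max(paired.manual.max(), paired.semi.max()) * 1.05 + 1
    ax.plot([0, lim], [0, lim], "k--", lw=1, label="identity")
    ax.set_xlabel("manual count (foci)")
    ax.set_ylabel("semi-automatic count (foci)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(plots_dir / f"{prefix}_scatter.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(paired.means, paired.differences, s=14, alpha=0.7)
    ax.axhline(result.bias, color="C1", label=f"bias {result.bias:.2f}")
    for sgn in (+1, -1):
        ax.axhline(result.bias + sgn * result.loa_halfwidth, color="C2",
                   ls="--",
                   label="±1.96 SD" if sgn > 0 else None)
    ax.set_xlabel("pair mean (foci)")
    ax.set_ylabel("manual − semi-automatic (foci)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(plots_dir / f"{prefix}_bland_altman.png", dpi=120)
    plt.close(fig)
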