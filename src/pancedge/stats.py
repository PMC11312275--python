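"""Study-level statistics: paired t-test, ROC/AUROC, Youden threshold.

The paired design compares, within each patient, the margin score of a
tumor-bearing border segment against a healthy segment. Cancer is the
positive class and is predicted by *low* scores, so:

* sensitivity at threshold t = fraction of tumor scores strictly below t,
* specificity at threshold t = fraction of healthy scores at or above t,
* the AUROC equals the probability that a random healthy score exceeds a
  random tumor score (ties counted half) — the Mann-Whitney identity, which
  the trapezoidal integration over midpoint thresholds reproduces exactly.

The operating threshold is chosen by maximizing the Youden index
J = sensitivity + specificity - 1; with perfectly separated groups this
lands on the midpoint of the separating gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "PairedSample",
    "TTestResult",
    "ROCResult",
    "StudySummary",
    "paired_t_test",
    "roc_curve",
    "youden_threshold",
    "cohort_report",
    "plot_roc",
    "plot_groups",
]


@dataclass(frozen=True)
class PairedSample:
    """One patient's pair of margin scores, px."""

    patient_id: str
    pms_tumor: float
    pms_healthy: float


@dataclass(frozen=True)
class TTestResult:
    """Two-sided paired t-test on per-patient differences (tumor - healthy)."""

    t: float
    df: int
    p: float
    mean_diff: float
    degenerate: bool = False


@dataclass
class ROCResult:
    """ROC operating characteristics with cancer-positive-below-threshold convention."""

    thresholds: np.ndarray
    sens: np.ndarray
    spec: np.ndarray
    auc: float
    youden_threshold: float
    youden_sens: float
    youden_spec: float


def paired_t_test(pairs: list[PairedSample]) -> TTestResult:
    """Paired t-test with sample (n-1) standard deviation.

    Zero-variance differences are flagged degenerate: a nonzero mean then
    reports p = 0 (infinitely strong evidence under the model), a zero mean
    reports t = 0, p = 1.
    """
    n = len(pairs)
    if n < 2:
        raise ValueError(f"paired t-test needs at least 2 pairs, got {n}")
    d = np.array([p.pms_tumor - p.pms_healthy for p in pairs], dtype=float)
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    df = n - 1
    if sd == 0.0:
        if mean == 0.0:
            return TTestResult(t=0.0, df=df, p=1.0, mean_diff=0.0, degenerate=True)
        t = np.inf if mean > 0 else -np.inf
        return TTestResult(t=t, df=df, p=0.0, mean_diff=mean, degenerate=True)
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return TTestResult(t=float(t), df=df, p=p, mean_diff=mean)


def roc_curve(scores_cancer, scores_healthy) -> ROCResult:
    """ROC over midpoint thresholds between adjacent distinct pooled scores.

    Sentinel thresholds at -inf and +inf anchor the (0, 0) and (1, 1)
    corners; the AUC is the trapezoidal integral of sensitivity against
    false-positive rate.
    """
    cancer = np.asarray(scores_cancer, dtype=float)
    healthy = np.asarray(scores_healthy, dtype=float)
    if cancer.size == 0 or healthy.size == 0:
        raise ValueError("both score lists must be non-empty")
    pooled = np.unique(np.concatenate([cancer, healthy]))
    mids = (pooled[:-1] + pooled[1:]) / 2.0 if pooled.size > 1 else np.empty(0)
    thresholds = np.concatenate([[-np.inf], mids, [np.inf]])
    sens = (cancer[None, :] < thresholds[:, None]).mean(axis=1)
    spec = (healthy[None, :] >= thresholds[:, None]).mean(axis=1)
    fpr = 1.0 - spec
    auc = float(np.trapezoid(sens, fpr))
    thr, ysens, yspec = _youden(thresholds, sens, spec)
    return ROCResult(
        thresholds=thresholds,
        sens=sens,
        spec=spec,
        auc=auc,
        youden_threshold=thr,
        youden_sens=ysens,
        youden_spec=yspec,
    )


def _youden(thresholds, sens, spec):
    j = sens + spec - 1.0
    idx = int(np.flatnonzero(j == j.max())[0])  # ties -> smallest threshold
    return float(thresholds[idx]), float(sens[idx]), float(spec[idx])


def youden_threshold(roc: ROCResult) -> tuple[float, float, float]:
    """The stored Youden-optimal operating point (threshold, sens, spec)."""
    return roc.youden_threshold, roc.youden_sens, roc.youden_spec


@dataclass
class StudySummary:
    """Structure of a paired margin-score study report."""

    n: int
    tumor_mean: float
    tumor_sd: float
    healthy_mean: float
    healthy_sd: float
    ttest: TTestResult
    roc: ROCResult
    threshold_used: float
    confusion: dict = field(default_factory=dict)
    sens_at_threshold: float = 0.0
    spec_at_threshold: float = 0.0
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.ttest.p < self.alpha

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "tumor_mean": self.tumor_mean,
            "tumor_sd": self.tumor_sd,
            "healthy_mean": self.healthy_mean,
            "healthy_sd": self.healthy_sd,
            "t": self.ttest.t,
            "df": self.ttest.df,
            "p": self.ttest.p,
            "mean_diff": self.ttest.mean_diff,
            "auc": self.roc.auc,
            "youden_threshold": self.roc.youden_threshold,
            "youden_sens": self.roc.youden_sens,
            "youden_spec": self.roc.youden_spec,
            "threshold_used": self.threshold_used,
            "confusion": self.confusion,
            "sens_at_threshold": self.sens_at_threshold,
            "spec_at_threshold": self.spec_at_threshold,
            "significant": self.significant,
        }


def cohort_report(
    pairs: list[PairedSample],
    threshold: float | None = None,
    alpha: float = 0.05,
) -> StudySummary:
    """Full study summary: group statistics, paired t-test, ROC, threshold table.

    ``threshold=None`` classifies at the cohort's own Youden-optimal cutoff;
    pass an external value (e.g. a previously published one) to evaluate a
    fixed rule instead.
    """
    if len(pairs) < 2:
        raise ValueError("cohort report needs at least 2 pairs")
    tumor = np.array([p.pms_tumor for p in pairs], dtype=float)
    healthy = np.array([p.pms_healthy for p in pairs], dtype=float)
    ttest = paired_t_test(pairs)
    roc = roc_curve(tumor, healthy)
    thr = roc.youden_threshold if threshold is None else float(threshold)
    tp = int((tumor < thr).sum())
    fn = int((tumor >= thr).sum())
    tn = int((healthy >= thr).sum())
    fp = int((healthy < thr).sum())
    return StudySummary(
        n=len(pairs),
        tumor_mean=float(tumor.mean()),
        tumor_sd=float(tumor.std(ddof=1)),
        healthy_mean=float(healthy.mean()),
        healthy_sd=float(healthy.std(ddof=1)),
        ttest=ttest,
        roc=roc,
        threshold_used=thr,
        confusion={"tp": tp, "fn": fn, "tn": tn, "fp": fp},
        sens_at_threshold=tp / len(pairs),
        spec_at_threshold=tn / len(pairs),
        alpha=alpha,
    )


def plot_roc(roc: ROCResult, path) -> None:
    """ROC curve figure with the Youden operating point marked."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(1.0 - roc.spec, roc.sens, "-o", ms=3)
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.plot(1.0 - roc.youden_spec, roc.youden_sens, "r*", ms=12)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"AUROC = {roc.auc:.4f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_groups(pairs: list[PairedSample], path, threshold: float | None = None) -> None:
    """Box/whisker plot of the two score groups, with an optional threshold line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tumor = [p.pms_tumor for p in pairs]
    healthy = [p.pms_healthy for p in pairs]
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.boxplot([tumor, healthy], tick_labels=["tumor", "healthy"])
    if threshold is not None:
        ax.axhline(threshold, color="r", ls="--", lw=1, label=f"threshold {threshold:.4f}")
        ax.legend()
    ax.set_ylabel("margin score (px)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
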