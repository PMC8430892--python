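"""Cohort-level EV-signature analysis.

Given a samples x genes expression table, two-group cluster labels and a
candidate gene universe, this module derives the EV-secretion gene signature
(linear fold change > 1.2 between clusters), scores each sample by the
median expression of the signature genes (the *EV score*), splits the cohort
at the median score into EV-high and EV-low strata, and compares their
survival with a Kaplan-Meier / log-rank analysis.  The hazard ratio uses the
observed/expected (Pike) estimator,

    HR = (O_hi / E_hi) / (O_lo / E_lo),   se(log HR) = sqrt(1/E_hi + 1/E_lo),

whose O and E come from the same risk-table accounting as the log-rank
statistic.  The cytolytic score — geometric mean of GZMA and PRF1 expression
with a 0.01 offset — serves as an immune-activity covariate, and per-gene
Spearman correlations relate the EV score to arbitrary gene panels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

log = logging.getLogger(__name__)


@dataclass
class CohortTables:
    """Expression, survival and grouping tables for one cohort.

    ``expression``: samples x genes, non-negative normalized values.
    ``survival``: columns sample_id, time (years), event (0 censored /
    1 death), optional group.  ``cluster_labels``: two-level label per
    sample (an input here; how the clusters were obtained is out of scope).
    """

    expression: pd.DataFrame
    survival: pd.DataFrame
    cluster_labels: pd.Series | None = None
    candidate_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if "time" in self.survival.columns and (self.survival["time"] <= 0).any():
            raise ValueError("survival times must be > 0")
        if self.cluster_labels is not None:
            if self.cluster_labels.nunique() != 2:
                raise ValueError("cluster_labels must take exactly two values")


@dataclass
class SurvivalSummary:
    logrank_statistic: float
    logrank_p: float
    hazard_ratio: float          # first (Hi) vs second (Lo) stratum
    hr_ci: tuple[float, float]   # 95% CI
    median_survival: dict[str, float | str]  # per stratum; "not reached" if KM > 0.5
    km_curves: dict[str, pd.DataFrame] = field(default_factory=dict)
    observed: dict[str, float] = field(default_factory=dict)
    expected: dict[str, float] = field(default_factory=dict)


def derive_signature(expression: pd.DataFrame, cluster_labels: pd.Series,
                     candidate_genes: list[str] | tuple[str, ...],
                     fc_threshold: float = 1.2,
                     high_label: str | None = None,
                     log_scale: bool = False) -> list[str]:
    """Genes with (mean in high cluster)/(mean in low cluster) > threshold.

    Fold change is computed on linear-scale means by default; ``log_scale``
    switches to the ratio of geometric means.  Genes whose denominator mean
    is zero are skipped with a logged reason.  Strict inequality: FC exactly
    at the threshold is not selected.
    """
    labels = cluster_labels.loc[expression.index]
    levels = sorted(labels.unique())
    if len(levels) != 2:
        raise ValueError("need exactly two clusters")
    if high_label is None:
        high_label = levels[0] if levels[0] == "high" else levels[-1]
        # prefer an explicit "high" level name when present
        if "high" in levels:
            high_label = "high"
    low_label = next(l for l in levels if l != high_label)
    hi = expression.loc[labels == high_label]
    lo = expression.loc[labels == low_label]
    if len(hi) < 2 or len(lo) < 2:
        raise ValueError("each cluster needs >= 2 samples")

    selected = []
    for gene in candidate_genes:
        if gene not in expression.columns:
            raise KeyError(f"candidate gene {gene!r} missing from expression")
        if log_scale:
            num = float(np.exp(np.log(hi[gene] + 1e-12).mean()))
            den = float(np.exp(np.log(lo[gene] + 1e-12).mean()))
        else:
            num, den = float(hi[gene].mean()), float(lo[gene].mean())
        if den == 0:
            log.warning("gene %s skipped: zero mean in the low cluster", gene)
            continue
        if num / den > fc_threshold:
            selected.append(gene)
    return selected


def ev_score(expression: pd.DataFrame, signature_genes: list[str]) -> pd.Series:
    """Per-sample median expression across the signature genes."""
    missing = [g for g in signature_genes if g not in expression.columns]
    if missing:
        raise KeyError(f"signature genes missing from expression: {missing}")
    return expression[list(signature_genes)].median(axis=1).rename("ev_score")


def stratify_by_median(scores: pd.Series) -> pd.Series:
    """Median split: score > cohort median -> 'Hi', otherwise (ties) -> 'Lo'."""
    med = scores.median()
    return pd.Series(np.where(scores > med, "Hi", "Lo"),
                     index=scores.index, name="stratum")


def cytolytic_score(expression: pd.DataFrame, offset: float = 0.01) -> pd.Series:
    """Geometric mean of GZMA and PRF1 expression: sqrt((GZMA+o)(PRF1+o))."""
    for gene in ("GZMA", "PRF1"):
        if gene not in expression.columns:
            raise KeyError(f"cytolytic score requires gene {gene!r}")
    return np.sqrt((expression["GZMA"] + offset)
                   * (expression["PRF1"] + offset)).rename("cytolytic_score")


def _logrank_accounting(time: np.ndarray, event: np.ndarray, in_first: np.ndarray
                        ) -> tuple[float, float, float, float, float]:
    """O, E per group and hypergeometric variance over shared event times.

    Returns (O1, E1, O2, E2, V) where group 1 is ``in_first``.
    """
    order = np.argsort(time, kind="stable")
    time, event, in_first = time[order], event[order], in_first[order]
    event_times = np.unique(time[event == 1])
    O1 = float(event[in_first].sum())
    O2 = float(event[~in_first].sum())
    E1 = V = 0.0
    for t in event_times:
        at_risk = time >= t
        n = float(at_risk.sum())
        n1 = float((at_risk & in_first).sum())
        d = float(((time == t) & (event == 1)).sum())
        E1 += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    E2 = (O1 + O2) - E1
    return O1, E1, O2, E2, V


def survival_compare(survival: pd.DataFrame, strata: pd.Series,
                     hi_label: str = "Hi", lo_label: str = "Lo"
                     ) -> SurvivalSummary:
    """KM curves, log-rank test and O/E hazard ratio (Hi vs Lo).

    Raises ``ValueError`` when neither stratum has any event (log-rank
    undefined).
    """
    df = survival.set_index("sample_id").loc[strata.index]
    time = df["time"].to_numpy(float)
    event = df["event"].to_numpy(int)
    is_hi = (strata == hi_label).to_numpy()
    if is_hi.all() or (~is_hi).all():
        raise ValueError("both strata must be non-empty")
    if event.sum() == 0:
        raise ValueError("no events in either stratum: log-rank undefined")

    O1, E1, O2, E2, V = _logrank_accounting(time, event, is_hi)
    chi2 = (O1 - E1) ** 2 / V if V > 0 else 0.0
    p = float(stats.chi2.sf(chi2, df=1))

    if O1 > 0 and O2 > 0 and E1 > 0 and E2 > 0:
        hr = (O1 / E1) / (O2 / E2)
        se = np.sqrt(1.0 / E1 + 1.0 / E2)
        ci = (float(hr * np.exp(-1.959964 * se)), float(hr * np.exp(1.959964 * se)))
    else:  # one stratum event-free: HR degenerates
        hr = 0.0 if O1 == 0 else np.inf
        ci = (0.0, np.inf)

    medians: dict[str, float | str] = {}
    curves: dict[str, pd.DataFrame] = {}
    for label, mask in ((hi_label, is_hi), (lo_label, ~is_hi)):
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event[mask], label=label)
        med = kmf.median_survival_time_
        medians[label] = "not reached" if np.isinf(med) else float(med)
        curves[label] = kmf.survival_function_

    return SurvivalSummary(
        logrank_statistic=float(chi2), logrank_p=p, hazard_ratio=float(hr),
        hr_ci=ci, median_survival=medians, km_curves=curves,
        observed={hi_label: O1, lo_label: O2},
        expected={hi_label: E1, lo_label: E2})


def score_gene_correlation(ev_scores: pd.Series, expression: pd.DataFrame,
                           gene_list: list[str]) -> pd.DataFrame:
    """Spearman rho and p between the EV score and each listed gene."""
    rows = []
    for gene in gene_list:
        if gene not in expression.columns:
            raise KeyError(f"gene {gene!r} missing from expression")
        rho, p = stats.spearmanr(ev_scores.to_numpy(),
                                 expression.loc[ev_scores.index, gene].to_numpy())
        rows.append({"gene": gene, "rho": float(rho), "p": float(p)})
    return pd.DataFrame(rows).set_index("gene")
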