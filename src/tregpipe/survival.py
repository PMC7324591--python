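"""Reference-gene-ratio survival screen.

Candidate genes are first required to correlate positively with the reference
gene (FOXP3 by default, Pearson r > 0.5) and to be expressed above background
(mean > 20 RPM).  Each passing gene's per-patient RPM is divided by the
reference RPM; patients are split at the cohort median of that ratio into low
and high groups, and the groups' overall-survival and disease-free-survival
curves are compared with a log-rank test.  Multi-gene signatures combine
z-standardized per-gene ratios before the same median split.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

SUBTYPES = ("LuminalA", "LuminalB", "Basal", "Her2")


@dataclass
class SurvivalCohort:
    """Per-patient survival endpoints plus an RPM expression matrix.

    ``clinical`` is indexed by patient with columns subtype, os_time,
    os_event, dfs_time, dfs_event; ``rpm`` is gene-by-patient reads per
    million.  OS is time to death; DFS is time to recurrence or death.
    """

    clinical: pd.DataFrame
    rpm: pd.DataFrame
    reference: str = "FOXP3"

    def __post_init__(self) -> None:
        required = ("os_time", "os_event", "dfs_time", "dfs_event")
        for col in required:
            if col not in self.clinical.columns:
                raise ValueError(f"clinical table is missing column {col!r}")
        if (self.clinical[["os_time", "dfs_time"]] < 0).any().any():
            raise ValueError("survival times must be >= 0")
        for col in ("os_event", "dfs_event"):
            if not self.clinical[col].isin([0, 1]).all():
                raise ValueError(f"{col} must be binary")
        missing = [p for p in self.clinical.index if p not in self.rpm.columns]
        if missing:
            raise ValueError(f"patients without expression: {missing[:5]}")

    @property
    def patients(self) -> pd.Index:
        return self.clinical.index

    def filter_subtypes(self, subtypes: list[str]) -> "SurvivalCohort":
        keep = self.clinical[self.clinical["subtype"].isin(subtypes)].index
        return SurvivalCohort(
            clinical=self.clinical.loc[keep],
            rpm=self.rpm[keep],
            reference=self.reference,
        )


@dataclass
class RatioScore:
    """Per-patient gene:reference ratio scores and the median-split grouping."""

    scores: pd.Series
    groups: pd.Series  # "low" / "high"
    median: float
    n_dropped: int = 0
    degenerate: bool = False


@dataclass
class LogRankResult:
    """Two-group log-rank comparison with Kaplan-Meier summaries."""

    statistic: float
    p_value: float
    group_summary: pd.DataFrame
    km_curves: dict[str, pd.DataFrame] = field(default_factory=dict)


def correlation_filter(
    cohort: SurvivalCohort,
    gene_panel: list[str],
    reference: str | None = None,
    r_min: float = 0.5,
    rpm_min: float = 20.0,
    method: str = "pearson",
    log_transform: bool = False,
) -> pd.DataFrame:
    """Select genes positively correlated with the reference gene's RPM.

    A gene passes when its correlation with the reference across patients is
    strictly greater than ``r_min`` and its mean RPM is strictly greater than
    ``rpm_min``.  Zero-variance genes are excluded (not failed) with a reason.
    ``method`` may be "pearson" or "spearman"; ``log_transform`` correlates
    log1p(RPM) instead of raw RPM.
    """
    reference = reference or cohort.reference
    if reference not in cohort.rpm.index:
        raise ValueError(f"reference gene {reference!r} absent from RPM matrix")
    if len(cohort.patients) < 3:
        raise ValueError("need at least 3 patients with expression")

    ref = cohort.rpm.loc[reference, cohort.patients].to_numpy(float)
    ref_t = np.log1p(ref) if log_transform else ref
    rows = []
    for gene in gene_panel:
        if gene not in cohort.rpm.index:
            rows.append((gene, np.nan, np.nan, False, "absent"))
            continue
        x = cohort.rpm.loc[gene, cohort.patients].to_numpy(float)
        mean_rpm = float(np.mean(x))
        xt = np.log1p(x) if log_transform else x
        if np.std(xt) == 0 or np.std(ref_t) == 0:
            rows.append((gene, np.nan, mean_rpm, False, "zero_variance"))
            continue
        if method == "pearson":
            r = float(stats.pearsonr(xt, ref_t)[0])
        elif method == "spearman":
            r = float(stats.spearmanr(xt, ref_t)[0])
        else:
            raise ValueError("method must be 'pearson' or 'spearman'")
        rows.append((gene, r, mean_rpm, bool(r > r_min and mean_rpm > rpm_min), ""))
    return pd.DataFrame(
        rows, columns=["gene", "r", "mean_rpm", "passed", "excluded_reason"]
    ).set_index("gene")


def _median_split(scores: pd.Series) -> RatioScore:
    median = float(scores.median())
    groups = pd.Series(np.where(scores > median, "high", "low"), index=scores.index)
    degenerate = groups.nunique() < 2
    if degenerate:
        warnings.warn("degenerate median split: all patients in one group", stacklevel=3)
    return RatioScore(scores=scores, groups=groups, median=median, degenerate=degenerate)


def ratio_score(cohort: SurvivalCohort, gene: str, reference: str | None = None) -> RatioScore:
    """Per-patient gene:reference RPM ratio with a cohort-median split.

    Patients with reference RPM = 0 are dropped (their count is logged).
    A patient is "high" when its ratio strictly exceeds the median; ties go
    to "low".
    """
    reference = reference or cohort.reference
    for g in (gene, reference):
        if g not in cohort.rpm.index:
            raise ValueError(f"gene {g!r} absent from RPM matrix")
    ref = cohort.rpm.loc[reference, cohort.patients].astype(float)
    keep = ref > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("ratio_score(%s): dropped %d patient(s) with %s RPM = 0", gene, n_dropped, reference)
    if not keep.any():
        raise ValueError(f"all patients have {reference} RPM = 0")
    ratios = cohort.rpm.loc[gene, cohort.patients][keep] / ref[keep]
    rs = _median_split(ratios.astype(float))
    rs.n_dropped = n_dropped
    return rs


def signature_ratio_score(
    cohort: SurvivalCohort,
    genes: list[str],
    reference: str | None = None,
    combine: str = "mean_z",
) -> RatioScore:
    """Combined multi-gene ratio score with a cohort-median split.

    Each gene's per-patient ratio is z-standardized across patients and the
    scores are averaged (``combine='mean_z'``, default); ``'geometric_mean'``
    instead takes the geometric mean of the raw ratios.  A single-gene
    signature reproduces :func:`ratio_score` grouping exactly.
    """
    if not genes:
        raise ValueError("signature gene list is empty")
    reference = reference or cohort.reference
    ref = cohort.rpm.loc[reference, cohort.patients].astype(float)
    keep = ref > 0
    n_dropped = int((~keep).sum())
    if not keep.any():
        raise ValueError(f"all patients have {reference} RPM = 0")
    ratios = pd.DataFrame(
        {g: cohort.rpm.loc[g, cohort.patients][keep] / ref[keep] for g in genes}
    ).astype(float)
    if combine == "mean_z":
        std = ratios.std(ddof=1).replace(0, np.nan)
        z = (ratios - ratios.mean()) / std
        combined = z.mean(axis=1)
        # A constant ratio carries no ranking information; fall back to the
        # raw ratio so single-gene degenerate cases still split (all-low).
        combined = combined.fillna(0.0) if combined.isna().all() else combined
    elif combine == "geometric_mean":
        combined = np.exp(np.log(ratios.clip(lower=1e-300)).mean(axis=1))
    else:
        raise ValueError("combine must be 'mean_z' or 'geometric_mean'")
    rs = _median_split(combined)
    rs.n_dropped = n_dropped
    return rs


def km_estimate(
    times: np.ndarray | pd.Series,
    events: np.ndarray | pd.Series,
    group_labels: np.ndarray | pd.Series,
) -> dict[str, pd.DataFrame]:
    """Kaplan-Meier product-limit curves per group (right-censored data).

    Returns, per group label, a table with columns time, survival and
    at_risk; each curve is a non-increasing step function starting at 1 that
    drops only at event times.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    group_labels = np.asarray(group_labels)
    curves: dict[str, pd.DataFrame] = {}
    for g in np.unique(group_labels):
        mask = group_labels == g
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask])
        tab = kmf.event_table
        surv = kmf.survival_function_
        curves[str(g)] = pd.DataFrame(
            {
                "time": surv.index.to_numpy(float),
                "survival": surv.iloc[:, 0].to_numpy(float),
                "at_risk": tab["at_risk"].reindex(surv.index).to_numpy(float),
            }
        )
    return curves


def logrank_test(
    times: np.ndarray | pd.Series,
    events: np.ndarray | pd.Series,
    group_labels: np.ndarray | pd.Series,
    curves: bool = True,
) -> LogRankResult:
    """Two-group log-rank test (observed minus expected events, 1 df).

    At each distinct event time the observed events in one group are compared
    with their hypergeometric expectation given the at-risk sets; the
    chi-square statistic is (sum(O-E))^2 / sum(V) referred to chi2(1).  A
    group with zero members is an error; zero total events yields p = 1 with
    a warning.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    group_labels = np.asarray(group_labels)
    labels = np.unique(group_labels)
    if len(labels) != 2:
        raise ValueError(f"log-rank requires exactly 2 non-empty groups, got {len(labels)}")
    m0, m1 = group_labels == labels[0], group_labels == labels[1]
    summary = pd.DataFrame(
        {
            "n": [int(m0.sum()), int(m1.sum())],
            "events": [int(events[m0].sum()), int(events[m1].sum())],
        },
        index=[str(labels[0]), str(labels[1])],
    )
    km = km_estimate(times, events, group_labels) if curves else {}
    if events.sum() == 0:
        warnings.warn("no events observed; log-rank p set to 1", stacklevel=2)
        return LogRankResult(0.0, 1.0, summary, km)
    res = _lifelines_logrank(times[m0], times[m1], event_observed_A=events[m0], event_observed_B=events[m1])
    return LogRankResult(
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
        group_summary=summary,
        km_curves=km,
    )


def _risk_direction(curves: dict[str, pd.DataFrame]) -> str:
    """poor-prognosis iff the high group's KM is inferior at the last common time."""
    if set(curves) != {"low", "high"}:
        return "undetermined"
    t_common = min(curves["low"]["time"].max(), curves["high"]["time"].max())

    def surv_at(curve: pd.DataFrame, t: float) -> float:
        ok = curve[curve["time"] <= t]
        return float(ok["survival"].iloc[-1]) if len(ok) else 1.0

    s_low, s_high = surv_at(curves["low"], t_common), surv_at(curves["high"], t_common)
    if s_high < s_low:
        return "poor"
    if s_high > s_low:
        return "good"
    return "neutral"


def screen(
    cohort: SurvivalCohort,
    deg_list: list[str],
    reference: str | None = None,
    r_min: float = 0.5,
    rpm_min: float = 20.0,
    endpoints: tuple[str, ...] = ("os", "dfs"),
    add_bh: bool = True,
) -> pd.DataFrame:
    """Run the full ratio screen over a candidate gene list.

    Composes correlation filtering, ratio median-splits and per-endpoint
    log-rank tests.  The risk direction is "poor" when the high-ratio group
    has the inferior Kaplan-Meier curve at the last common time point.  Raw
    log-rank p-values are reported; an optional Benjamini-Hochberg column is
    added per endpoint when ``add_bh``.
    """
    reference = reference or cohort.reference
    if not deg_list:
        cols = ["r", "mean_rpm", "passed"]
        for ep in endpoints:
            cols += [f"{ep}_p", f"{ep}_direction"]
        return pd.DataFrame(columns=cols)
    corr = correlation_filter(cohort, deg_list, reference, r_min=r_min, rpm_min=rpm_min)
    rows = []
    for gene in deg_list:
        rec: dict = {
            "gene": gene,
            "r": corr.loc[gene, "r"],
            "mean_rpm": corr.loc[gene, "mean_rpm"],
            "passed": bool(corr.loc[gene, "passed"]),
        }
        if rec["passed"]:
            rs = ratio_score(cohort, gene, reference)
            clin = cohort.clinical.loc[rs.groups.index]
            for ep in endpoints:
                if rs.degenerate:
                    rec[f"{ep}_p"], rec[f"{ep}_direction"] = np.nan, "undetermined"
                    continue
                lr = logrank_test(clin[f"{ep}_time"], clin[f"{ep}_event"], rs.groups)
                rec[f"{ep}_p"] = lr.p_value
                rec[f"{ep}_direction"] = _risk_direction(lr.km_curves)
        else:
            for ep in endpoints:
                rec[f"{ep}_p"], rec[f"{ep}_direction"] = np.nan, "not_tested"
        rows.append(rec)
    out = pd.DataFrame(rows).set_index("gene")
    if add_bh:
        for ep in endpoints:
            pvals = out[f"{ep}_p"]
            ok = pvals.notna()
            adj = pd.Series(np.nan, index=out.index)
            if ok.any():
                adj[ok] = multipletests(pvals[ok], method="fdr_bh")[1]
            out[f"{ep}_p_bh"] = adj
    return out


def read_cohort(clinical_path, rpm_path, reference: str = "FOXP3") -> SurvivalCohort:
    """Load a clinical CSV (indexed by patient) and an RPM TSV (gene x patient)."""
    clinical = pd.read_csv(clinical_path, index_col=0)
    rpm = pd.read_csv(rpm_path, sep="\t", index_col=0)
    return SurvivalCohort(clinical=clinical, rpm=rpm, reference=reference)
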