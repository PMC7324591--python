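"""Consensus differential expression between Treg and Tconv samples.

The pipeline normalizes raw counts to the mean per-sample coverage, converts
normalized counts into binary expression flags (signal when >= 20), restricts
testing to the P50 universe (flag 1 in at least half of the compared samples),
runs three complementary per-gene statistics — a negative-binomial Wald test,
an empirical-Bayes moderated t-test on log counts, and an exact Wilcoxon
rank-sum test — and calls a gene differential only when all three agree at
p <= 0.05 with a linear fold of at least 1.2 in a consistent direction.
Per-tissue calls are then combined into Venn signature classes (common Treg
"UUU", common Tconv "DDD", tissue-unique, other).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FormatError

REQUIRED_METADATA = ("patient", "tissue", "subset")
TEST_NAMES = ("nb_wald", "moderated_t", "rank")


@dataclass
class CountMatrix:
    """Gene-by-sample counts with per-sample metadata (patient, tissue, subset)."""

    counts: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate gene identifiers")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample identifiers")
        missing = [s for s in self.counts.columns if s not in self.metadata.index]
        if missing:
            raise ValueError(f"samples without metadata: {missing}")
        for col in REQUIRED_METADATA:
            if col not in self.metadata.columns:
                raise ValueError(f"metadata is missing column {col!r}")
            if self.metadata.loc[self.counts.columns, col].isna().any():
                raise ValueError(f"metadata column {col!r} has missing values")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def samples_for(self, tissue: str | None = None, subset: str | None = None) -> list[str]:
        meta = self.metadata.loc[self.counts.columns]
        mask = pd.Series(True, index=meta.index)
        if tissue is not None:
            mask &= meta["tissue"] == tissue
        if subset is not None:
            mask &= meta["subset"] == subset
        return list(meta.index[mask])


@dataclass
class FlagMatrix:
    """Binary expression flags: 1 when the normalized count is >= threshold."""

    flags: pd.DataFrame
    threshold: float = 20.0


def read_count_matrix(counts_path, metadata_path) -> CountMatrix:
    """Load a counts TSV (first column gene id) and a sample-metadata TSV."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(metadata_path, sep="\t", index_col=0)
    for col in REQUIRED_METADATA:
        if col not in meta.columns:
            raise FormatError(f"metadata file {metadata_path} is missing column {col!r}")
    return CountMatrix(counts=counts, metadata=meta)


def normalize_mean_coverage(cm: CountMatrix) -> CountMatrix:
    """Scale each sample so its total equals the mean of all sample totals.

    Within-sample count ratios are preserved exactly (a single positive scale
    factor per sample).
    """
    totals = cm.counts.sum(axis=0).astype(float)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total count: {list(zero.index)}")
    factors = totals.mean() / totals
    return CountMatrix(counts=cm.counts * factors, metadata=cm.metadata)


def compute_flags(norm: CountMatrix, threshold: float = 20.0) -> FlagMatrix:
    """Background/signal flags on normalized counts: flag 1 iff count >= threshold."""
    return FlagMatrix(flags=(norm.counts >= threshold).astype(int), threshold=threshold)


def p50_list(flags: FlagMatrix, comparison_samples: list[str]) -> list[str]:
    """Genes flagged as signal in at least half of the compared samples.

    "At least half" is evaluated exactly on rationals (2 * n_flagged >= n), so
    2 of 4 samples suffice but 2 of 5 do not.
    """
    if not comparison_samples:
        raise ValueError("comparison_samples must be non-empty")
    unknown = [s for s in comparison_samples if s not in flags.flags.columns]
    if unknown:
        raise ValueError(f"unknown sample id(s): {unknown}")
    sub = flags.flags[comparison_samples]
    n = len(comparison_samples)
    keep = 2 * sub.sum(axis=1) >= n
    return list(sub.index[keep])


def _group_arrays(cm: CountMatrix, group_a: list[str], group_b: list[str]) -> tuple[np.ndarray, np.ndarray]:
    for name, grp in (("groupA", group_a), ("groupB", group_b)):
        if len(grp) < 2:
            raise ValueError(f"{name} needs at least 2 samples, got {len(grp)}")
        unknown = [s for s in grp if s not in cm.counts.columns]
        if unknown:
            raise ValueError(f"unknown sample id(s) in {name}: {unknown}")
    a = cm.counts[group_a].to_numpy(dtype=float)
    b = cm.counts[group_b].to_numpy(dtype=float)
    return a, b


def _result_frame(genes: pd.Index, fold: np.ndarray, p: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame({"fold": fold, "p": p}, index=genes)


def de_test_nb_wald(
    cm: CountMatrix,
    group_a: list[str],
    group_b: list[str],
    shrink_weight: float = 0.5,
    normalized: bool = False,
) -> pd.DataFrame:
    """Per-gene negative-binomial Wald test on mean-coverage-normalized counts.

    Each gene is modeled as NB with a gene dispersion estimated by the method
    of moments (pooled within groups) and shrunk toward a mean–dispersion
    trend fitted across genes, alpha(mu) = a0 + a1/mu, with mixing weight
    ``shrink_weight`` on the trend.  The Wald statistic is the log-fold
    change over its delta-method standard error,
    Var(log fold) = (1/muA + alpha)/nA + (1/muB + alpha)/nB, with a two-sided
    normal p-value.  The reported fold is linear, meanA/meanB.  Genes with
    zero counts in both groups are reported with NaN (excluded from testing).
    """
    norm = cm if normalized else normalize_mean_coverage(cm)
    a, b = _group_arrays(norm, group_a, group_b)
    na, nb = a.shape[1], b.shape[1]
    mu_a, mu_b = a.mean(axis=1), b.mean(axis=1)
    mu = np.concatenate([a, b], axis=1).mean(axis=1)

    # Method-of-moments dispersion, pooled across the two groups.
    with np.errstate(divide="ignore", invalid="ignore"):
        var_pool = (a.var(axis=1, ddof=1) * (na - 1) + b.var(axis=1, ddof=1) * (nb - 1)) / (
            na + nb - 2
        )
        mu_pool = (mu_a * na + mu_b * nb) / (na + nb)
        alpha_raw = (var_pool - mu_pool) / np.square(mu_pool)
    alpha_raw = np.where(np.isfinite(alpha_raw), np.clip(alpha_raw, 0.0, 10.0), np.nan)

    # Mean–dispersion trend alpha(mu) = a0 + a1/mu, fitted on informative genes.
    ok = np.isfinite(alpha_raw) & (mu_pool > 0) & (alpha_raw > 0)
    if ok.sum() >= 10:
        X = np.column_stack([np.ones(ok.sum()), 1.0 / mu_pool[ok]])
        coef, *_ = np.linalg.lstsq(X, alpha_raw[ok], rcond=None)
        with np.errstate(divide="ignore"):
            trend = np.maximum(coef[0] + coef[1] / mu_pool, 1e-8)
    else:
        trend = np.full_like(mu_pool, np.nanmedian(alpha_raw[ok]) if ok.any() else 0.1)
    alpha = np.where(
        np.isfinite(alpha_raw),
        shrink_weight * trend + (1 - shrink_weight) * alpha_raw,
        trend,
    )
    # Bound below by the trend: with few replicates the method-of-moments
    # estimate is noisy downward, and an underestimated dispersion inflates
    # the Wald statistic.
    alpha = np.clip(np.maximum(alpha, trend), 1e-8, 10.0)

    testable = (mu_a > 0) & (mu_b > 0)
    fold = np.full(len(mu), np.nan)
    p = np.full(len(mu), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_fold = np.log(mu_a) - np.log(mu_b)
        se2 = (1.0 / mu_a + alpha) / na + (1.0 / mu_b + alpha) / nb
        z = log_fold / np.sqrt(se2)
    fold[testable] = np.exp(log_fold[testable])
    p[testable] = 2.0 * stats.norm.sf(np.abs(z[testable]))
    # Degenerate but nonzero genes with identical group means: null result.
    p[testable & (log_fold == 0)] = 1.0
    return _result_frame(norm.genes, fold, p)


def de_test_moderated_t(
    cm: CountMatrix,
    group_a: list[str],
    group_b: list[str],
    d0: float = 4.0,
    pseudocount: float = 0.5,
    normalized: bool = False,
) -> pd.DataFrame:
    """Empirical-Bayes moderated t-test on log2(normalized count + pseudocount).

    Per-gene variances are shrunk toward the pooled prior variance s0^2 (the
    mean of the per-gene pooled variances) with ``d0`` prior degrees of
    freedom: s~^2 = (d0 s0^2 + d s^2) / (d0 + d), d = nA + nB - 2.  The
    statistic is referred to a t distribution with d + d0 degrees of freedom.
    The reported fold is the geometric-mean fold, 2**(mean log2 difference).
    """
    norm = cm if normalized else normalize_mean_coverage(cm)
    a, b = _group_arrays(norm, group_a, group_b)
    na, nb = a.shape[1], b.shape[1]
    la, lb = np.log2(a + pseudocount), np.log2(b + pseudocount)
    d = na + nb - 2
    s2 = (la.var(axis=1, ddof=1) * (na - 1) + lb.var(axis=1, ddof=1) * (nb - 1)) / d
    s0_sq = float(np.mean(s2)) if len(s2) else 0.0
    s2_mod = (d0 * s0_sq + d * s2) / (d0 + d)
    diff = la.mean(axis=1) - lb.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(s2_mod * (1.0 / na + 1.0 / nb))
    p = np.where(
        s2_mod > 0,
        2.0 * stats.t.sf(np.abs(np.where(np.isfinite(t), t, 0.0)), df=d + d0),
        1.0,
    )
    p[(s2_mod > 0) & (diff == 0)] = 1.0

    mu_a, mu_b = a.mean(axis=1), b.mean(axis=1)
    testable = (mu_a > 0) & (mu_b > 0)
    # The method's own effect estimate: geometric-mean fold on the log2 scale.
    fold = np.where(testable, np.exp2(diff), np.nan)
    p = np.where(testable, p, np.nan)
    return _result_frame(norm.genes, fold, p)


def de_test_rank(
    cm: CountMatrix,
    group_a: list[str],
    group_b: list[str],
    normalized: bool = False,
) -> pd.DataFrame:
    """Exact Wilcoxon rank-sum test per gene on normalized counts.

    Uses the exact null distribution when both groups have <= 10 samples and
    the gene has no ties, and the tie-corrected normal approximation
    otherwise.  Constant genes (all values tied) are reported with p = 1.
    """
    norm = cm if normalized else normalize_mean_coverage(cm)
    a, b = _group_arrays(norm, group_a, group_b)
    na, nb = a.shape[1], b.shape[1]
    exact_ok = na <= 10 and nb <= 10
    mu_a, mu_b = a.mean(axis=1), b.mean(axis=1)
    testable = (mu_a > 0) & (mu_b > 0)

    # The method's own effect estimate: median of all pairwise ratios
    # (Hodges-Lehmann style), consistent with the rank statistic.
    fold = np.full(a.shape[0], np.nan)
    p = np.full(a.shape[0], np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        pairwise = a[:, :, None] / b[:, None, :]
        pairwise = np.where(np.isfinite(pairwise), pairwise, np.nan)
        hl = np.nanmedian(pairwise.reshape(a.shape[0], -1), axis=1)
    fold[testable] = hl[testable]
    for i in np.nonzero(testable)[0]:
        xa, xb = a[i], b[i]
        pooled = np.concatenate([xa, xb])
        if np.all(pooled == pooled[0]):
            p[i] = 1.0
            continue
        has_ties = len(np.unique(pooled)) < len(pooled)
        method = "exact" if exact_ok and not has_ties else "asymptotic"
        res = stats.mannwhitneyu(xa, xb, alternative="two-sided", method=method)
        p[i] = min(float(res.pvalue), 1.0)
    return _result_frame(norm.genes, fold, p)


def consensus(
    results: dict[str, pd.DataFrame],
    p_max: float = 0.05,
    fold_min: float = 1.2,
    require_direction: bool = True,
) -> pd.DataFrame:
    """Combine the three per-gene tests into consensus calls U, D or N.

    A gene is called U (up in group A) only when every method has p <= p_max
    and linear fold >= fold_min; D symmetrically with fold <= 1/fold_min.
    Both bounds are inclusive.  Direction must agree across methods when
    ``require_direction`` (default).  The reported fold is the median of the
    three estimates; genes missing from any method are called N.
    """
    if set(results) != set(TEST_NAMES):
        raise ValueError(f"results must have keys {TEST_NAMES}, got {sorted(results)}")
    genes = results[TEST_NAMES[0]].index
    for name in TEST_NAMES[1:]:
        if not genes.equals(results[name].index):
            raise ValueError(f"gene index mismatch between methods ({name})")

    folds = np.column_stack([results[n]["fold"].to_numpy(float) for n in TEST_NAMES])
    ps = np.column_stack([results[n]["p"].to_numpy(float) for n in TEST_NAMES])
    complete = np.isfinite(folds).all(axis=1) & np.isfinite(ps).all(axis=1)

    sig = (ps <= p_max).all(axis=1)
    up = (folds >= fold_min).all(axis=1)
    down = (folds <= 1.0 / fold_min).all(axis=1)
    if not require_direction:
        # Direction taken from the median fold; significance still unanimous.
        med = np.nanmedian(folds, axis=1)
        up = up | (sig & (med >= fold_min) & (folds >= fold_min).any(axis=1))
        down = down | (sig & (med <= 1.0 / fold_min) & (folds <= 1.0 / fold_min).any(axis=1))

    call = np.where(complete & sig & up, "U", np.where(complete & sig & down, "D", "N"))
    out = pd.DataFrame(
        {
            "fold": np.where(complete, np.median(folds, axis=1), np.nan),
            "p_nb_wald": ps[:, 0],
            "p_moderated_t": ps[:, 1],
            "p_rank": ps[:, 2],
            "call": call,
        },
        index=genes,
    )
    return out


@dataclass
class TissueComparison:
    """One tissue's Treg-vs-Tconv consensus run and its intermediate products."""

    tissue: str
    p50_genes: list[str]
    table: pd.DataFrame
    n_samples: int = 0
    notes: dict = field(default_factory=dict)


def run_tissue_comparison(
    cm: CountMatrix,
    tissue: str,
    subset_a: str = "Treg",
    subset_b: str = "Tconv",
    flag_threshold: float = 20.0,
    p_max: float = 0.05,
    fold_min: float = 1.2,
    d0: float = 4.0,
    shrink_weight: float = 0.5,
) -> TissueComparison:
    """Full per-tissue pipeline: normalize, flag, P50-filter, three tests, consensus.

    Genes failing the P50 filter are excluded from testing entirely (the flag
    universe gates the statistics).
    """
    group_a = cm.samples_for(tissue=tissue, subset=subset_a)
    group_b = cm.samples_for(tissue=tissue, subset=subset_b)
    norm = normalize_mean_coverage(cm)
    flags = compute_flags(norm, threshold=flag_threshold)
    universe = p50_list(flags, group_a + group_b)
    sub = CountMatrix(counts=norm.counts.loc[universe], metadata=norm.metadata)
    results = {
        "nb_wald": de_test_nb_wald(sub, group_a, group_b, shrink_weight=shrink_weight, normalized=True),
        "moderated_t": de_test_moderated_t(sub, group_a, group_b, d0=d0, normalized=True),
        "rank": de_test_rank(sub, group_a, group_b, normalized=True),
    }
    table = consensus(results, p_max=p_max, fold_min=fold_min)
    return TissueComparison(
        tissue=tissue,
        p50_genes=universe,
        table=table,
        n_samples=len(group_a) + len(group_b),
    )


SIGNATURE_TISSUES = ("NI", "I", "T")


def classify_pattern(triple: tuple[str, str, str]) -> str:
    """Map an (NI, I, T) call triple to its Venn signature class."""
    if triple == ("U", "U", "U"):
        return "common_treg"
    if triple == ("D", "D", "D"):
        return "common_tconv"
    if triple == ("N", "N", "N"):
        return "unclassified"
    non_n = [(t, c) for t, c in zip(SIGNATURE_TISSUES, triple) if c != "N"]
    if len(non_n) == 1:
        tissue, call = non_n[0]
        side = "treg" if call == "U" else "tconv"
        return f"{tissue}_unique_{side}"
    return "other"


def venn_signatures(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Combine per-tissue consensus tables into Venn signature classes.

    ``tables`` maps tissue (NI, I, T) to a consensus table with a ``call``
    column.  Genes absent from a tissue's table (for example, failing that
    tissue's P50 filter) are treated as N there.  Every gene in the union
    receives exactly one class.
    """
    missing = [t for t in SIGNATURE_TISSUES if t not in tables]
    if missing:
        raise ValueError(f"missing tissue table(s): {missing}")
    genes = sorted(set().union(*(tables[t].index for t in SIGNATURE_TISSUES)))
    calls = {
        t: tables[t]["call"].reindex(genes).fillna("N") for t in SIGNATURE_TISSUES
    }
    out = pd.DataFrame(calls, index=pd.Index(genes, name="gene"))
    out["signature"] = [
        classify_pattern(tuple(row)) for row in out[list(SIGNATURE_TISSUES)].itertuples(index=False)
    ]
    return out


def signature_counts(venn: pd.DataFrame) -> pd.Series:
    """Counts of genes per signature class (every gene in exactly one class)."""
    return venn["signature"].value_counts()
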