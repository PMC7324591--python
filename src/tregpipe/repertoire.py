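"""TCR-beta clonotype repertoires: ingestion, noise filtering and sharing statistics.

A clonotype is the exact triple (V call, J call, CDR3 sequence).  Sorted-sample
repertoires are filtered with a two-stage noise rule (drop clones below a
minimum read count, then keep the most strongly expressed fraction of the
remaining clones) before clonal-expansion curves, repertoire-overlap
percentages and top-K clone tracking are computed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import pandas as pd

from .errors import EmptyInputError, EmptyRepertoireError, FormatError

TISSUES = ("NI", "I", "T")
SUBSETS = ("Treg", "Tconv")
ALPHABETS = ("nt", "aa")

CloneKey = tuple[str, str, str]


@dataclass(frozen=True)
class CloneRecord:
    """One clonotype in one sample: (V, J, CDR3) with its read count.

    ``frequency`` is the fraction of the repertoire's total reads and is
    recomputed after every filter; ``raw_frequency`` preserves the pre-filter
    value for reporting.
    """

    v_gene: str
    j_gene: str
    cdr3: str
    count: int
    frequency: float = 0.0
    raw_frequency: float | None = None

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError(f"clone count must be >= 1, got {self.count}")

    @property
    def key(self) -> CloneKey:
        return (self.v_gene, self.j_gene, self.cdr3)


@dataclass
class Repertoire:
    """A sorted sample's clonotype table with sample-level metadata."""

    sample_id: str
    patient_id: str
    tissue: str
    subset: str
    clones: list[CloneRecord] = field(default_factory=list)
    alphabet: str = "nt"
    # Parameters of the noise filter already applied, if any; re-applying the
    # filter with identical parameters is then a no-op (idempotence).
    filters: dict | None = None

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise ValueError(f"tissue must be one of {TISSUES}, got {self.tissue!r}")
        if self.subset not in SUBSETS:
            raise ValueError(f"subset must be one of {SUBSETS}, got {self.subset!r}")
        if self.alphabet not in ALPHABETS:
            raise ValueError(f"alphabet must be one of {ALPHABETS}, got {self.alphabet!r}")
        keys = [c.key for c in self.clones]
        if len(keys) != len(set(keys)):
            raise ValueError(f"duplicate clonotype keys in repertoire {self.sample_id}")

    def __len__(self) -> int:
        return len(self.clones)

    @property
    def total_count(self) -> int:
        return sum(c.count for c in self.clones)

    def keys(self) -> set[CloneKey]:
        return {c.key for c in self.clones}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "v_gene": [c.v_gene for c in self.clones],
                "j_gene": [c.j_gene for c in self.clones],
                "cdr3": [c.cdr3 for c in self.clones],
                "count": [c.count for c in self.clones],
                "frequency": [c.frequency for c in self.clones],
                "raw_frequency": [c.raw_frequency for c in self.clones],
            }
        )


@dataclass(frozen=True)
class OverlapResult:
    """Shared-clonotype statistic: shared / reference clones x 100."""

    numerator: int
    denominator: int
    percent: float
    reference_sample: str
    query_sample: str


@dataclass
class CloneTrackTable:
    """Top-K reference clones and their frequencies in each target sample.

    ``table`` has one row per tracked clone (v_gene, j_gene, cdr3,
    reference_frequency, then one column per target sample id);
    ``summary_mass`` maps each target sample id to the cumulative frequency
    of the K tracked clones in that sample.
    """

    reference_sample: str
    k: int
    table: pd.DataFrame
    summary_mass: dict[str, float]


def _with_frequencies(clones: list[CloneRecord], keep_raw: bool = False) -> list[CloneRecord]:
    total = sum(c.count for c in clones)
    if total == 0:
        return []
    return [
        replace(
            c,
            frequency=c.count / total,
            raw_frequency=(c.raw_frequency if keep_raw and c.raw_frequency is not None else c.count / total),
        )
        for c in clones
    ]


def _sort_key(clone: CloneRecord) -> tuple[int, CloneKey]:
    # Descending count, ties broken lexicographically on the clonotype key so
    # rank-based selection is deterministic.
    return (-clone.count, clone.key)


def strip_allele(call: str) -> str:
    """Drop an allele suffix from a gene call: ``TRBV7-2*01`` -> ``TRBV7-2``."""
    return call.split("*", 1)[0]


def read_clonotype_table(
    path,
    alphabet: str = "nt",
    *,
    sample_id: str | None = None,
    patient_id: str = "P0",
    tissue: str = "NI",
    subset: str = "Treg",
    strip_alleles: bool = True,
) -> Repertoire:
    """Read an AIRR rearrangement-style TSV into a :class:`Repertoire`.

    Requires columns ``v_call``, ``j_call``, ``duplicate_count`` and the CDR3
    column matching ``alphabet`` (``junction`` for nucleotide, ``junction_aa``
    for amino acid).  Rows with identical (V, J, CDR3) keys are merged by
    summing counts; frequencies are computed over the merged table.
    """
    if alphabet not in ALPHABETS:
        raise ValueError(f"alphabet must be one of {ALPHABETS}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    cdr3_col = "junction" if alphabet == "nt" else "junction_aa"
    for col in ("v_call", "j_call", cdr3_col, "duplicate_count"):
        if col not in df.columns:
            raise FormatError(f"clonotype table {path} is missing required column {col!r}")
    counts = pd.to_numeric(df["duplicate_count"], errors="raise").astype(int)
    v = df["v_call"].map(strip_allele) if strip_alleles else df["v_call"]
    j = df["j_call"].map(strip_allele) if strip_alleles else df["j_call"]
    merged: dict[CloneKey, int] = {}
    for key, n in zip(zip(v, j, df[cdr3_col]), counts):
        if n <= 0:
            continue
        merged[key] = merged.get(key, 0) + int(n)
    if not merged or sum(merged.values()) == 0:
        raise EmptyRepertoireError(f"clonotype table {path} has zero total count")
    clones = _with_frequencies(
        [CloneRecord(vg, jg, c3, n) for (vg, jg, c3), n in merged.items()]
    )
    return Repertoire(
        sample_id=sample_id if sample_id is not None else str(path),
        patient_id=patient_id,
        tissue=tissue,
        subset=subset,
        clones=clones,
        alphabet=alphabet,
    )


def filter_repertoire(
    rep: Repertoire,
    min_count: int = 3,
    keep_rank_fraction: float = 0.90,
    mode: str = "rank",
) -> Repertoire:
    """Two-stage noise filter: drop clones with ``count < min_count`` then keep
    the most strongly expressed fraction of the survivors.

    ``mode='rank'`` (default) keeps the top ``ceil(keep_rank_fraction * n)``
    clones by count; ``mode='mass'`` keeps the shortest count-sorted prefix
    whose cumulative read fraction reaches ``keep_rank_fraction``.  Ties are
    broken lexicographically by clonotype key.  Frequencies are renormalized
    over the retained clones; pre-filter frequencies are preserved in
    ``raw_frequency``.  The applied parameters are recorded on the result, so
    re-filtering with the same parameters is a no-op.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    if not (0 < keep_rank_fraction <= 1):
        raise ValueError("keep_rank_fraction must be in (0, 1]")
    if mode not in ("rank", "mass"):
        raise ValueError("mode must be 'rank' or 'mass'")

    params = {"min_count": min_count, "keep_rank_fraction": keep_rank_fraction, "mode": mode}
    if rep.filters == params:
        return replace(rep)

    survivors = sorted((c for c in rep.clones if c.count >= min_count), key=_sort_key)
    if not survivors:
        if rep.clones:
            warnings.warn(
                f"filter removed every clone of {rep.sample_id}", stacklevel=2
            )
        return replace(rep, clones=[], filters=params)

    if mode == "rank":
        n_keep = math.ceil(keep_rank_fraction * len(survivors))
        kept = survivors[:n_keep]
    else:
        total = sum(c.count for c in survivors)
        target = keep_rank_fraction * total
        kept, acc = [], 0
        for c in survivors:
            kept.append(c)
            acc += c.count
            if acc >= target - 1e-12:
                break

    kept = [replace(c, raw_frequency=c.frequency) for c in kept]
    return replace(rep, clones=_with_frequencies(kept, keep_raw=True), filters=params)


def cumulative_frequency_curve(rep: Repertoire) -> list[tuple[int, float]]:
    """Clonal-expansion curve: (rank, cumulative frequency of the top-rank clones).

    Clones are sorted by descending frequency (ties lexicographic); the final
    cumulative value is 1 within numerical tolerance.
    """
    if not rep.clones:
        raise EmptyInputError(f"repertoire {rep.sample_id} is empty")
    clones = sorted(rep.clones, key=_sort_key)
    out, acc = [], 0.0
    for r, c in enumerate(clones, start=1):
        acc += c.frequency
        out.append((r, acc))
    return out


def expansion_index(rep: Repertoire, top_n: int) -> float:
    """Cumulative frequency of the ``top_n`` most frequent clones (in [0, 1])."""
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    if not rep.clones:
        raise EmptyInputError(f"repertoire {rep.sample_id} is empty")
    curve = cumulative_frequency_curve(rep)
    return curve[min(top_n, len(curve)) - 1][1]


def subset_overlap(reference: Repertoire, query: Repertoire) -> OverlapResult:
    """Shared clonotypes between two repertoires as a percentage of the reference.

    percent = |keys(reference) ∩ keys(query)| / |keys(reference)| x 100.  The
    statistic is symmetric in the numerator only; the denominator is always the
    reference (the Treg repertoire, in the intra-tissue comparison).
    """
    if reference.alphabet != query.alphabet:
        raise ValueError(
            f"alphabet mismatch: {reference.alphabet} vs {query.alphabet}"
        )
    if not reference.clones:
        raise EmptyRepertoireError(
            f"reference repertoire {reference.sample_id} is empty: percent undefined"
        )
    shared = reference.keys() & query.keys()
    denom = len(reference.keys())
    return OverlapResult(
        numerator=len(shared),
        denominator=denom,
        percent=100.0 * len(shared) / denom,
        reference_sample=reference.sample_id,
        query_sample=query.sample_id,
    )


def cross_tissue_overlap(tumor_reference: Repertoire, tdln_query: Repertoire) -> OverlapResult:
    """Inter-tissue sharing: tumor-subset clones found in a TDLN repertoire.

    Identical statistic to :func:`subset_overlap` with the tumor repertoire as
    reference; provided as a named entry point so reports can label intra- vs
    inter-tissue comparisons distinctly.
    """
    return subset_overlap(tumor_reference, tdln_query)


def track_top_clones(
    reference: Repertoire, targets: list[Repertoire], k: int = 100
) -> CloneTrackTable:
    """Track the top-``k`` reference clones across target samples.

    Reference clones are ranked by descending count (ties lexicographic).  For
    each target the per-clone frequency is 0 when the clonotype is absent; the
    summary mass per target is the cumulative frequency of the K tracked
    clones in that target sample.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not reference.clones:
        raise EmptyInputError(f"reference repertoire {reference.sample_id} is empty")
    for t in targets:
        if t.alphabet != reference.alphabet:
            raise ValueError(f"alphabet mismatch: {reference.alphabet} vs {t.alphabet}")

    top = sorted(reference.clones, key=_sort_key)[:k]
    rows: dict[str, list] = {
        "v_gene": [c.v_gene for c in top],
        "j_gene": [c.j_gene for c in top],
        "cdr3": [c.cdr3 for c in top],
        "reference_frequency": [c.frequency for c in top],
    }
    summary: dict[str, float] = {}
    for t in targets:
        freq_by_key = {c.key: c.frequency for c in t.clones}
        freqs = [freq_by_key.get(c.key, 0.0) for c in top]
        rows[t.sample_id] = freqs
        summary[t.sample_id] = float(sum(freqs))
    return CloneTrackTable(
        reference_sample=reference.sample_id,
        k=k,
        table=pd.DataFrame(rows),
        summary_mass=summary,
    )
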