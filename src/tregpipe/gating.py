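"""Deterministic boolean gating of CD4+ T cells from categorical marker calls.

Two independent axes are classified per cell.  The naive/memory axis follows
the Sakaguchi CD45RA/FOXP3 quadrant scheme (naive Treg, effector Treg, FOXP3+
non-Treg, memory Tconv, naive Tconv).  The helper axis follows the
chemokine-receptor tree: Th1 (CXCR3+), Th2 (CXCR3-CCR6-CCR4+), Th17
(CXCR3-CCR6+CCR4+CCR10-), Th22 (CXCR3-CCR6+CCR4+CCR10+) and Tfh
(PD-1 high CXCR5+), with cells negative for all assessed chemokine receptors
called non-polarized and unnamed combinations called other.  Continuous
fluorescence thresholds are out of scope: inputs are pre-called categories.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FormatError

MARKER_VOCAB: dict[str, tuple[str, ...]] = {
    "CD45RA": ("pos", "neg"),
    "FOXP3": ("neg", "low", "high"),
    "CXCR3": ("pos", "neg"),
    "CCR6": ("pos", "neg"),
    "CCR4": ("pos", "neg"),
    "CCR10": ("pos", "neg"),
    "CXCR5": ("pos", "neg"),
    "PD1": ("neg", "int", "high"),
}
HELPER_MARKERS = ("CXCR3", "CCR6", "CCR4", "CCR10", "CXCR5", "PD1")

CD4_CLASSES = (
    "naive_Treg",
    "eff_Treg",
    "foxp3_nonTreg",
    "memory_Tconv",
    "naive_Tconv",
    "unclassified",
)
HELPER_CLASSES = ("Th1", "Th2", "Th17", "Th22", "Tfh", "non_polarized", "other")

_CD45RA_FOXP3_MAP = {
    ("pos", "low"): "naive_Treg",
    ("neg", "high"): "eff_Treg",
    ("neg", "low"): "foxp3_nonTreg",
    ("neg", "neg"): "memory_Tconv",
    ("pos", "neg"): "naive_Tconv",
    ("pos", "high"): "unclassified",
}


def classify_cd45ra_foxp3(cd45ra: str, foxp3: str) -> str:
    """Five-way CD45RA/FOXP3 classification of a CD4+ T cell.

    (CD45RA+, FOXP3 low) -> naive Treg; (-, high) -> effector Treg;
    (-, low) -> FOXP3+ non-Treg; (-, -) -> memory Tconv; (+, -) -> naive
    Tconv; the (+, high) corner falls outside the five printed gates and is
    returned as unclassified.
    """
    if cd45ra not in MARKER_VOCAB["CD45RA"]:
        raise ValueError(f"invalid CD45RA call {cd45ra!r}")
    if foxp3 not in MARKER_VOCAB["FOXP3"]:
        raise ValueError(f"invalid FOXP3 call {foxp3!r}")
    return _CD45RA_FOXP3_MAP[(cd45ra, foxp3)]


def classify_helper(
    cxcr3: str,
    ccr6: str,
    ccr4: str,
    ccr10: str,
    cxcr5: str,
    pd1: str,
    tfh_precedence: bool = True,
) -> str:
    """Helper/helper-like polarization class from chemokine receptors and PD-1.

    Tfh (PD-1 high and CXCR5+) is evaluated first by default so that a
    PD-1-high CXCR5+ CXCR3+ cell is Tfh, not Th1 (``tfh_precedence=False``
    moves Tfh after the chemokine tree).  Cells negative for every assessed
    chemokine receptor are non-polarized; combinations the scheme does not
    name are returned as other.
    """
    for name, val in zip(HELPER_MARKERS, (cxcr3, ccr6, ccr4, ccr10, cxcr5, pd1)):
        if val not in MARKER_VOCAB[name]:
            raise ValueError(f"invalid {name} call {val!r}")

    def chemokine_tree() -> str | None:
        if cxcr3 == "pos":
            return "Th1"
        if ccr6 == "neg" and ccr4 == "pos":
            return "Th2"
        if ccr6 == "pos" and ccr4 == "pos":
            return "Th17" if ccr10 == "neg" else "Th22"
        return None

    tfh = pd1 == "high" and cxcr5 == "pos"
    if tfh_precedence and tfh:
        return "Tfh"
    named = chemokine_tree()
    if named is not None:
        return named
    if tfh:
        return "Tfh"
    if all(m == "neg" for m in (cxcr3, ccr6, ccr4, ccr10, cxcr5)):
        return "non_polarized"
    return "other"


def load_events(path) -> pd.DataFrame:
    """Load a per-cell CSV of categorical marker calls, validating vocabularies."""
    df = pd.read_csv(path, dtype=str)
    if "sample_id" not in df.columns:
        raise FormatError("event table is missing column 'sample_id'")
    return validate_events(df)


def validate_events(df: pd.DataFrame) -> pd.DataFrame:
    """Reject unknown markers levels; extra non-marker columns pass through."""
    for marker, vocab in MARKER_VOCAB.items():
        if marker in df.columns:
            bad = set(df[marker].dropna().unique()) - set(vocab)
            if bad:
                raise FormatError(f"unknown {marker} call(s): {sorted(bad)}")
    return df


def classify_events(events: pd.DataFrame, axis: str, tfh_precedence: bool = True) -> pd.Series:
    """Classify every cell on one axis ('cd4' or 'helper')."""
    if len(events) == 0:
        return pd.Series(dtype=object)
    validate_events(events)
    if axis == "cd4":
        return events.apply(
            lambda r: classify_cd45ra_foxp3(r["CD45RA"], r["FOXP3"]), axis=1
        )
    if axis == "helper":
        return events.apply(
            lambda r: classify_helper(
                r["CXCR3"], r["CCR6"], r["CCR4"], r["CCR10"], r["CXCR5"], r["PD1"],
                tfh_precedence=tfh_precedence,
            ),
            axis=1,
        )
    raise ValueError("axis must be 'cd4' or 'helper'")


def subset_frequencies(events: pd.DataFrame, axis: str) -> pd.DataFrame:
    """Per-sample class counts and percentages of the parent population.

    Every class of the axis appears in the output, with 0% when no cell falls
    in it; percentages over an axis sum to 100 per sample.
    """
    classes = CD4_CLASSES if axis == "cd4" else HELPER_CLASSES
    calls = classify_events(events, axis)
    out_rows = []
    if len(events) == 0:
        return pd.DataFrame(columns=["sample_id", "class", "count", "percent"])
    for sample, idx in events.groupby("sample_id").groups.items():
        counts = calls.loc[idx].value_counts()
        total = int(counts.sum())
        for cls in classes:
            n = int(counts.get(cls, 0))
            out_rows.append(
                {
                    "sample_id": sample,
                    "class": cls,
                    "count": n,
                    "percent": 100.0 * n / total if total else 0.0,
                }
            )
    return pd.DataFrame(out_rows)


def paired_subset_correlation(
    freq_a: pd.Series | np.ndarray, freq_b: pd.Series | np.ndarray
) -> tuple[float, float, float]:
    """Pearson correlation between paired per-sample subset frequencies.

    Returns (r, r_squared, two-sided p from the t transform); requires at
    least 3 paired samples.
    """
    a = np.asarray(freq_a, dtype=float)
    b = np.asarray(freq_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired frequency vectors must have equal length")
    if len(a) < 3:
        raise ValueError("need at least 3 paired samples")
    r, p = stats.pearsonr(a, b)
    return float(r), float(r) ** 2, float(p)


def enumerate_helper_space() -> pd.DataFrame:
    """All combinations of the helper-axis marker vocabularies with their class.

    The full cartesian product (2*2*2*2*2*3 = 96 combinations) maps each cell
    state to exactly one class; useful for audit tables and totality checks.
    """
    rows = []
    vocabs = [MARKER_VOCAB[m] for m in HELPER_MARKERS]
    for combo in itertools.product(*vocabs):
        rows.append(dict(zip(HELPER_MARKERS, combo)) | {"helper_class": classify_helper(*combo)})
    return pd.DataFrame(rows)
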