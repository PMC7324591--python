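"""Synthetic data generators with recorded ground truth.

Every pipeline input can be generated with known planted structure: clonotype
tables with power-law (Zipf) clone sizes and planted shared clonotypes,
negative-binomial count matrices with planted fold changes, proportional-
hazards survival cohorts whose hazard is tied to a gene:reference expression
ratio, and categorical marker event tables drawn from class archetypes.

All generators are pure functions of (parameters, seed).  A global seed is
expanded into per-generator seeds by hashing the generator name together with
the seed, so adding a new generator never perturbs the output of existing
ones.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .deg import CountMatrix
from .gating import MARKER_VOCAB
from .repertoire import CloneKey, CloneRecord, Repertoire, _with_frequencies
from .survival import SurvivalCohort

# TCGA-BRCA-like subtype composition (562 Luminal A, 209 Luminal B, 190 Basal,
# 82 Her2+), available as the `paper-like` preset.
PAPER_SUBTYPE_WEIGHTS = {"LuminalA": 562, "LuminalB": 209, "Basal": 190, "Her2": 82}

V_GENES = tuple(f"TRBV{i}" for i in range(1, 31))
J_GENES = tuple(f"TRBJ{i}-{j}" for i in (1, 2) for j in range(1, 8))
NT = np.array(list("ACGT"))
AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass
class GroundTruth:
    """Planted parameters serialized alongside every generated dataset."""

    generator: str
    seed: int
    params: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, default=_jsonable, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, set):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def child_seed(seed: int, name: str) -> int:
    """Stable per-component seed derived from the global seed and a name."""
    digest = hashlib.sha256(f"{seed}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _rng(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(child_seed(seed, name))


def _random_cdr3s(rng: np.random.Generator, n: int, alphabet: str = "nt") -> list[str]:
    letters = NT if alphabet == "nt" else AA
    out: set[str] = set()
    while len(out) < n:
        lengths = rng.integers(30, 46, size=n - len(out))
        for length in lengths:
            out.add("".join(rng.choice(letters, size=int(length))))
    return sorted(out)[:n]


def _random_keys(rng: np.random.Generator, n: int, alphabet: str = "nt") -> list[CloneKey]:
    cdr3s = _random_cdr3s(rng, n, alphabet)
    vs = rng.choice(V_GENES, size=n)
    js = rng.choice(J_GENES, size=n)
    return [(str(v), str(j), c) for v, j, c in zip(vs, js, cdr3s)]


def _zipf_probs(n: int, alpha: float) -> np.ndarray:
    ranks = np.arange(1, n + 1, dtype=float)
    w = ranks**-alpha
    return w / w.sum()


def _repertoire_from_keys(
    rng: np.random.Generator,
    keys: list[CloneKey],
    zipf_alpha: float,
    total_reads: int,
    sample_id: str,
    patient_id: str,
    tissue: str,
    subset: str,
    alphabet: str,
) -> Repertoire:
    # Shuffle so planted (shared) keys are not systematically the most
    # expanded clones; counts are multinomial over Zipf(alpha) probabilities.
    order = rng.permutation(len(keys))
    probs = _zipf_probs(len(keys), zipf_alpha)
    counts = rng.multinomial(total_reads, probs)
    clones = [
        CloneRecord(*keys[order[i]], count=int(c))
        for i, c in enumerate(counts)
        if c > 0
    ]
    return Repertoire(
        sample_id=sample_id,
        patient_id=patient_id,
        tissue=tissue,
        subset=subset,
        clones=_with_frequencies(clones),
        alphabet=alphabet,
    )


def gen_repertoire(
    n_clones: int,
    zipf_alpha: float = 1.2,
    total_reads: int | None = None,
    seed: int = 0,
    sample_id: str = "S1",
    patient_id: str = "P1",
    tissue: str = "NI",
    subset: str = "Treg",
    alphabet: str = "nt",
) -> tuple[Repertoire, GroundTruth]:
    """One synthetic repertoire with Zipf clone-size structure.

    Default Zipf exponents elsewhere in the package are 1.2 for Treg-like
    (expanded) and 0.6 for Tconv-like repertoires, reproducing the
    qualitative ordering of Treg vs Tconv clonality.
    """
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    total_reads = total_reads if total_reads is not None else 100 * n_clones
    rng = _rng(seed, f"repertoire:{sample_id}")
    keys = _random_keys(rng, n_clones, alphabet)
    rep = _repertoire_from_keys(
        rng, keys, zipf_alpha, total_reads, sample_id, patient_id, tissue, subset, alphabet
    )
    gt = GroundTruth(
        "gen_repertoire",
        seed,
        {
            "n_clones": n_clones,
            "zipf_alpha": zipf_alpha,
            "total_reads": total_reads,
            "sample_id": sample_id,
            "n_realized": len(rep),
        },
    )
    return rep, gt


def gen_shared_pair(
    n_clones: int,
    sharing_fraction: float,
    seed: int = 0,
    zipf_alpha: tuple[float, float] = (1.2, 0.6),
    total_reads: int | None = None,
    tissue: str = "NI",
    patient_id: str = "P1",
    alphabet: str = "nt",
) -> tuple[Repertoire, Repertoire, GroundTruth]:
    """A (reference Treg, query Tconv) pair with planted clonotype sharing.

    Exactly ``round(sharing_fraction * n_clones)`` reference clonotype keys
    (sampled without replacement) are copied into the query, which is filled
    with fresh keys back to ``n_clones``.  The realized planted overlap is
    recorded in the ground truth.
    """
    if not 0 <= sharing_fraction <= 1:
        raise ValueError("sharing_fraction must be in [0, 1]")
    total_reads = total_reads if total_reads is not None else 100 * n_clones
    rng = _rng(seed, f"shared_pair:{patient_id}:{tissue}")
    ref_keys = _random_keys(rng, n_clones, alphabet)
    n_shared = int(round(sharing_fraction * n_clones))
    shared_idx = rng.choice(n_clones, size=n_shared, replace=False)
    shared = [ref_keys[i] for i in sorted(shared_idx)]
    fill = _random_keys(rng, n_clones - len(shared), alphabet)
    query_keys = shared + fill

    ref = _repertoire_from_keys(
        rng, ref_keys, zipf_alpha[0], total_reads,
        f"{patient_id}_{tissue}_Treg", patient_id, tissue, "Treg", alphabet,
    )
    query = _repertoire_from_keys(
        rng, query_keys, zipf_alpha[1], total_reads,
        f"{patient_id}_{tissue}_Tconv", patient_id, tissue, "Tconv", alphabet,
    )
    gt = GroundTruth(
        "gen_shared_pair",
        seed,
        {
            "n_clones": n_clones,
            "sharing_fraction": sharing_fraction,
            "planted_shared": len(shared),
            "planted_fraction": len(shared) / n_clones,
        },
    )
    return ref, query, gt


def gen_linked_repertoires(
    n_patients: int = 2,
    n_clones: int = 1000,
    treg_tconv_sharing: float = 0.17,
    tumor_tdln_sharing: float = 0.2,
    zipf_alpha: dict[str, float] | None = None,
    total_reads: int | None = None,
    seed: int = 0,
    alphabet: str = "nt",
) -> tuple[list[Repertoire], GroundTruth]:
    """A patients x tissues x subsets repertoire set with planted sharing.

    Per patient and tissue (NI, I, T) the Tconv repertoire shares a planted
    fraction of the Treg clonotypes (intra-tissue Treg/Tconv sharing, the
    pTreg signature); additionally the TDLN Tconv repertoires carry a planted
    fraction of the tumor Treg clonotypes (inter-tissue trafficking).
    """
    zipf_alpha = zipf_alpha or {"Treg": 1.2, "Tconv": 0.6}
    total_reads = total_reads if total_reads is not None else 100 * n_clones
    reps: list[Repertoire] = []
    planted: dict[str, float] = {}
    for p in range(1, n_patients + 1):
        pid = f"P{p}"
        rng = _rng(seed, f"linked:{pid}")
        treg_keys: dict[str, list[CloneKey]] = {
            t: _random_keys(rng, n_clones, alphabet) for t in ("NI", "I", "T")
        }
        tumor_treg = treg_keys["T"]

        def pick(keys: list[CloneKey], fraction: float) -> list[CloneKey]:
            k = int(round(fraction * len(keys)))
            idx = rng.choice(len(keys), size=k, replace=False)
            return [keys[i] for i in sorted(idx)]

        for t in ("NI", "I", "T"):
            intra = pick(treg_keys[t], treg_tconv_sharing)
            cross: list[CloneKey] = []
            if t != "T":
                cross = pick(tumor_treg, tumor_tdln_sharing)
            seen = dict.fromkeys(intra + cross)
            fill = _random_keys(rng, max(n_clones - len(seen), 0), alphabet)
            tconv_keys = list(seen) + fill
            planted[f"{pid}:{t}:treg_tconv"] = len(intra) / n_clones
            if t != "T":
                planted[f"{pid}:{t}:tumor_tdln"] = len(cross) / n_clones
            reps.append(
                _repertoire_from_keys(
                    rng, treg_keys[t], zipf_alpha["Treg"], total_reads,
                    f"{pid}_{t}_Treg", pid, t, "Treg", alphabet,
                )
            )
            reps.append(
                _repertoire_from_keys(
                    rng, tconv_keys, zipf_alpha["Tconv"], total_reads,
                    f"{pid}_{t}_Tconv", pid, t, "Tconv", alphabet,
                )
            )
    gt = GroundTruth(
        "gen_linked_repertoires",
        seed,
        {
            "n_patients": n_patients,
            "n_clones": n_clones,
            "treg_tconv_sharing": treg_tconv_sharing,
            "tumor_tdln_sharing": tumor_tdln_sharing,
            "planted_fractions": planted,
        },
    )
    return reps, gt


def gen_counts(
    n_genes: int = 2000,
    n_per_group: tuple[int, int] = (5, 5),
    frac_de: float = 0.0,
    true_fold: float = 4.0,
    dispersion: float = 0.1,
    lib_size_range: tuple[float, float] = (0.7, 1.3),
    mean_log: float = np.log(150.0),
    mean_sigma: float = 1.0,
    tissue: str = "NI",
    seed: int = 0,
) -> tuple[CountMatrix, GroundTruth]:
    """Negative-binomial count matrix with planted fold changes.

    Gene base means are log-normal; a fraction ``frac_de`` of genes get their
    mean multiplied by ``true_fold`` in one group (half up in group A, half
    down).  Counts are NB(mean, dispersion); per-sample library-size factors
    are uniform over ``lib_size_range``.  Group A samples are labelled Treg
    and group B Tconv in the attached metadata.
    """
    rng = _rng(seed, f"counts:{tissue}")
    na, nb = n_per_group
    base = rng.lognormal(mean=mean_log, sigma=mean_sigma, size=n_genes)

    n_de = int(round(frac_de * n_genes))
    de_idx = rng.choice(n_genes, size=n_de, replace=False) if n_de else np.array([], dtype=int)
    direction = np.zeros(n_genes)
    if n_de:
        up = rng.random(n_de) < 0.5
        direction[de_idx[up]] = 1
        direction[de_idx[~up]] = -1

    mu_a = base * np.where(direction == 1, true_fold, 1.0)
    mu_b = base * np.where(direction == -1, true_fold, 1.0)
    lib = rng.uniform(*lib_size_range, size=na + nb)
    mu = np.concatenate(
        [np.outer(mu_a, lib[:na]), np.outer(mu_b, lib[na:])], axis=1
    )
    if dispersion > 0:
        r = 1.0 / dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
    else:
        counts = rng.poisson(mu)

    genes = [f"G{i:05d}" for i in range(n_genes)]
    samples = [f"{tissue}_Treg_{i+1}" for i in range(na)] + [
        f"{tissue}_Tconv_{i+1}" for i in range(nb)
    ]
    meta = pd.DataFrame(
        {
            "patient": [f"P{i+1}" for i in range(na)] + [f"P{i+1}" for i in range(nb)],
            "tissue": tissue,
            "subset": ["Treg"] * na + ["Tconv"] * nb,
        },
        index=samples,
    )
    cm = CountMatrix(counts=pd.DataFrame(counts, index=genes, columns=samples), metadata=meta)
    gt = GroundTruth(
        "gen_counts",
        seed,
        {
            "n_genes": n_genes,
            "n_per_group": list(n_per_group),
            "frac_de": frac_de,
            "true_fold": true_fold,
            "dispersion": dispersion,
            "tissue": tissue,
            "de_genes": [genes[i] for i in de_idx],
            "de_direction": {genes[i]: int(direction[i]) for i in de_idx},
        },
    )
    return cm, gt


def gen_survival_cohort(
    n: int = 300,
    subtype_weights: dict[str, float] | None = None,
    beta: float = 0.7,
    censor_rate: float = 0.3,
    gene_panel: tuple[str, ...] = ("CD80", "CCR8", "HAVCR2", "GENE_NULL1", "GENE_NULL2"),
    planted_gene: str = "CD80",
    reference: str = "FOXP3",
    base_hazard: float = 1.0 / 1500.0,
    ratio_sigma: float = 0.3,
    seed: int = 0,
) -> tuple[SurvivalCohort, GroundTruth]:
    """Proportional-hazards cohort whose risk is tied to a gene:reference ratio.

    Reference RPM is log-normal; every panel gene is generated as
    reference * exp(offset + ratio_sigma * eps) so raw-RPM correlation with
    the reference is high (the planted and null genes all pass the
    correlation filter by construction).  The planted gene's standardized
    log-ratio z drives an exponential event-time hazard base_hazard *
    exp(beta * z); disease-free survival is the minimum of the death and an
    independent recurrence process (so DFS <= OS), and censoring is an
    independent exponential with hazard chosen so that roughly
    ``censor_rate`` of patients are censored under beta = 0
    (``censor_rate=0`` disables censoring).
    """
    subtype_weights = subtype_weights or PAPER_SUBTYPE_WEIGHTS
    if planted_gene not in gene_panel:
        raise ValueError("planted_gene must be in gene_panel")
    rng = _rng(seed, "survival_cohort")
    patients = [f"PT{i:04d}" for i in range(n)]
    w = np.array(list(subtype_weights.values()), dtype=float)
    subtypes = rng.choice(list(subtype_weights), size=n, p=w / w.sum())

    ref_rpm = rng.lognormal(mean=np.log(30.0), sigma=0.5, size=n)
    rpm_rows = {reference: ref_rpm}
    z_planted = np.zeros(n)
    for gene in gene_panel:
        eps = rng.standard_normal(n)
        rpm_rows[gene] = ref_rpm * np.exp(0.3 + ratio_sigma * eps)
        if gene == planted_gene:
            z_planted = eps
    rpm = pd.DataFrame(rpm_rows, index=patients).T

    hazard = base_hazard * np.exp(beta * z_planted)
    os_latent = rng.exponential(1.0 / hazard)
    rec_latent = rng.exponential(1.0 / (1.5 * hazard))
    dfs_latent = np.minimum(os_latent, rec_latent)
    if censor_rate > 0:
        c_hazard = base_hazard * censor_rate / (1.0 - censor_rate)
        censor = rng.exponential(1.0 / c_hazard, size=n)
    else:
        censor = np.full(n, np.inf)

    clinical = pd.DataFrame(
        {
            "subtype": subtypes,
            "os_time": np.minimum(os_latent, censor),
            "os_event": (os_latent <= censor).astype(int),
            "dfs_time": np.minimum(dfs_latent, censor),
            "dfs_event": (dfs_latent <= censor).astype(int),
        },
        index=pd.Index(patients, name="patient"),
    )
    cohort = SurvivalCohort(clinical=clinical, rpm=rpm, reference=reference)
    gt = GroundTruth(
        "gen_survival_cohort",
        seed,
        {
            "n": n,
            "beta": beta,
            "censor_rate": censor_rate,
            "planted_gene": planted_gene,
            "reference": reference,
            "gene_panel": list(gene_panel),
            "subtype_weights": subtype_weights,
        },
    )
    return cohort, gt


# Marker archetypes consistent with the gating schemes: each fixes every
# marker so the classifiers recover the class deterministically.
_BASE = {"CXCR3": "neg", "CCR6": "neg", "CCR4": "neg", "CCR10": "neg", "CXCR5": "neg", "PD1": "neg"}
ARCHETYPES: dict[str, dict[str, str]] = {
    "naive_Treg": {"CD45RA": "pos", "FOXP3": "low", **_BASE},
    "eff_Treg": {"CD45RA": "neg", "FOXP3": "high", **_BASE},
    "foxp3_nonTreg": {"CD45RA": "neg", "FOXP3": "low", **_BASE},
    "memory_Tconv": {"CD45RA": "neg", "FOXP3": "neg", **_BASE},
    "naive_Tconv": {"CD45RA": "pos", "FOXP3": "neg", **_BASE},
    "Th1": {"CD45RA": "neg", "FOXP3": "neg", **_BASE, "CXCR3": "pos"},
    "Th2": {"CD45RA": "neg", "FOXP3": "neg", **_BASE, "CCR4": "pos"},
    "Th17": {"CD45RA": "neg", "FOXP3": "neg", **_BASE, "CCR6": "pos", "CCR4": "pos"},
    "Th22": {"CD45RA": "neg", "FOXP3": "neg", **_BASE, "CCR6": "pos", "CCR4": "pos", "CCR10": "pos"},
    "Tfh": {"CD45RA": "neg", "FOXP3": "neg", **_BASE, "PD1": "high", "CXCR5": "pos"},
    "non_polarized": {"CD45RA": "neg", "FOXP3": "neg", **_BASE},
}


def gen_events(
    n_cells: int,
    class_mixture: dict[str, float],
    seed: int = 0,
    sample_id: str = "S1",
    noise: float = 0.0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Per-cell categorical marker table drawn from class archetypes.

    ``class_mixture`` maps archetype names (see :data:`ARCHETYPES`) to
    weights.  With ``noise`` > 0 each marker call is independently resampled
    uniformly from its vocabulary with that probability.  The true archetype
    of every cell is recorded in the ground truth.
    """
    unknown = set(class_mixture) - set(ARCHETYPES)
    if unknown:
        raise ValueError(f"unknown archetype(s): {sorted(unknown)}")
    rng = _rng(seed, f"events:{sample_id}")
    names = list(class_mixture)
    w = np.array([class_mixture[k] for k in names], dtype=float)
    if n_cells == 0 or not names:
        cols = ["sample_id", "true_class"] + list(MARKER_VOCAB)
        return pd.DataFrame(columns=cols), GroundTruth("gen_events", seed, {"n_cells": 0})
    labels = rng.choice(names, size=n_cells, p=w / w.sum())
    rows = []
    for lab in labels:
        markers = dict(ARCHETYPES[lab])
        if noise > 0:
            for m, vocab in MARKER_VOCAB.items():
                if rng.random() < noise:
                    markers[m] = str(rng.choice(vocab))
        rows.append({"sample_id": sample_id, "true_class": lab, **markers})
    df = pd.DataFrame(rows)
    gt = GroundTruth(
        "gen_events",
        seed,
        {
            "n_cells": n_cells,
            "class_mixture": class_mixture,
            "noise": noise,
            "realized_counts": {k: int(v) for k, v in pd.Series(labels).value_counts().items()},
        },
    )
    return df, gt
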