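"""Relative synonymous codon usage (RSCU) and PCA ordination of gene classes.

RSCU for codon j of amino-acid family i with n_i synonymous codons is
x_ij / (X_i / n_i): the observed count over its expectation under uniform
usage within the family, so every observed family averages to 1.  Methionine
and tryptophan (single-codon families) and the stop codons are excluded,
leaving 59 codons.  Genes of 500 nt or less are filtered out before analysis
(strictly "longer than 500 bp"; configurable) because short genes give noisy,
drift-dominated RSCU vectors.

The ordination is a centered (by default unscaled — RSCU is already
dimensionless and family-normalized) PCA over the gene x 59 RSCU matrix,
with unobserved families imputed at the no-information value 1 and a
deterministic sign convention (largest-magnitude loading positive per
component).
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from ._genetic_code import AA_TO_CODONS, STOP_CODONS
from .io_formats import SequenceRecord

__all__ = [
    "RSCU_CODONS",
    "RSCUProfile",
    "PcaResult",
    "count_codons",
    "rscu",
    "filter_genes",
    "profiles_from_records",
    "pca_rscu",
]

#: amino-acid families retained for RSCU: sense codons minus ATG (Met) and
#: TGG (Trp); 18 families, 59 codons
RSCU_FAMILIES: dict[str, tuple[str, ...]] = {
    aa: codons for aa, codons in AA_TO_CODONS.items() if len(codons) > 1
}
RSCU_CODONS: tuple[str, ...] = tuple(sorted(c for fam in RSCU_FAMILIES.values() for c in fam))
assert len(RSCU_CODONS) == 59


@dataclass
class RSCUProfile:
    """Per-gene RSCU vector over the 59 retained codons.

    ``values[codon]`` is NaN for codons of families never observed in the
    gene; those families are listed in ``missing_families``.
    """

    gene_id: str
    class_label: str
    values: dict[str, float]
    missing_families: list[str] = field(default_factory=list)


@dataclass
class PcaResult:
    scores: pd.DataFrame  # genes x components
    loadings: pd.DataFrame  # codons x components
    explained_variance_fraction: np.ndarray
    class_labels: list[str]


def count_codons(cds: SequenceRecord | str) -> Counter:
    """In-frame codon counts; codons containing N or gaps are skipped and a
    terminal stop codon is excluded."""
    seq = cds.seq if isinstance(cds, SequenceRecord) else cds
    name = cds.id if isinstance(cds, SequenceRecord) else "<sequence>"
    if len(seq) % 3 != 0:
        raise ValueError(f"length of {name} ({len(seq)}) is not a multiple of 3")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    counts = Counter(c for c in codons if set(c) <= set("ACGT"))
    if not counts:
        warnings.warn(f"no countable codons in {name}")
    return counts


def rscu(counts: Counter | dict[str, int], gene_id: str = "gene", class_label: str = "") -> RSCUProfile:
    """RSCU values from codon counts (ATG, TGG and stops excluded)."""
    values: dict[str, float] = {}
    missing: list[str] = []
    for aa, codons in RSCU_FAMILIES.items():
        family_total = sum(counts.get(c, 0) for c in codons)
        if family_total == 0:
            missing.append(aa)
            for c in codons:
                values[c] = math.nan
            continue
        expected = family_total / len(codons)
        for c in codons:
            values[c] = counts.get(c, 0) / expected
    return RSCUProfile(gene_id=gene_id, class_label=class_label, values=values, missing_families=sorted(missing))


def filter_genes(
    genes: list[SequenceRecord], min_len: int = 500, strict_gt: bool = True
) -> list[SequenceRecord]:
    """Keep genes longer than ``min_len`` nt (``>=`` when ``strict_gt`` False)."""
    if strict_gt:
        kept = [g for g in genes if len(g.seq) > min_len]
    else:
        kept = [g for g in genes if len(g.seq) >= min_len]
    n_removed = len(genes) - len(kept)
    if n_removed:
        warnings.warn(f"filtered out {n_removed} gene(s) at the {min_len} nt length threshold")
    return kept


def profiles_from_records(
    records: list[SequenceRecord],
    class_label: str = "",
    min_len: int = 500,
    strict_gt: bool = True,
) -> list[RSCUProfile]:
    """Length-filter, count and normalize a batch of CDS records."""
    kept = filter_genes(records, min_len=min_len, strict_gt=strict_gt)
    return [rscu(count_codons(rec), gene_id=rec.id, class_label=class_label) for rec in kept]


def rscu_matrix(profiles: list[RSCUProfile], impute: float = 1.0) -> pd.DataFrame:
    """Genes x 59 RSCU matrix with unobserved families imputed.

    The default imputation value 1 is the no-information expectation under
    uniform usage, which keeps missing families from pulling genes anywhere.
    """
    data = np.array(
        [[p.values.get(c, math.nan) for c in RSCU_CODONS] for p in profiles], dtype=float
    )
    data = np.where(np.isnan(data), impute, data)
    return pd.DataFrame(data, index=[p.gene_id for p in profiles], columns=list(RSCU_CODONS))


def pca_rscu(
    profiles: list[RSCUProfile],
    n_components: int = 2,
    scale: bool = False,
    impute: float = 1.0,
) -> PcaResult:
    """Centered PCA of RSCU profiles (optionally unit-variance scaled).

    Deterministic sign convention: within each component the loading of
    largest magnitude is made positive.  Degenerate input (all profiles
    identical) yields all-zero scores and zero explained variance.
    """
    if len(profiles) < 3:
        raise ValueError("need at least 3 profiles for a PCA")
    if n_components > len(profiles):
        raise ValueError("fewer profiles than requested components")
    mat = rscu_matrix(profiles, impute=impute)
    X = mat.to_numpy()
    X = X - X.mean(axis=0, keepdims=True)
    if scale:
        sd = X.std(axis=0, ddof=1)
        X = X / np.where(sd > 0, sd, 1.0)

    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    if np.allclose(X, 0.0):
        scores = pd.DataFrame(np.zeros((len(profiles), n_components)), index=mat.index, columns=comp_names)
        loadings = pd.DataFrame(np.zeros((X.shape[1], n_components)), index=mat.columns, columns=comp_names)
        return PcaResult(scores, loadings, np.zeros(n_components), [p.class_label for p in profiles])

    pca = PCA(n_components=n_components, svd_solver="full")
    T = pca.fit_transform(X)
    L = pca.components_.T  # codons x components
    for k in range(n_components):
        pivot = np.argmax(np.abs(L[:, k]))
        if L[pivot, k] < 0:
            L[:, k] = -L[:, k]
            T[:, k] = -T[:, k]
    scores = pd.DataFrame(T, index=mat.index, columns=comp_names)
    loadings = pd.DataFrame(L, index=mat.columns, columns=comp_names)
    return PcaResult(scores, loadings, pca.explained_variance_ratio_.copy(), [p.class_label for p in profiles])
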