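"""Jaccard and signed Jaccard similarity between direction-labelled signatures.

The signed Jaccard index (SJI) between two signatures with up/down gene sets
(U1, D1) and (U2, D2) is

    SJI = ( J(U1,U2) + J(D1,D2) - J(U1,D2) - J(D1,U2) ) / 2

where J is the plain Jaccard coefficient |A∩B| / |A∪B|.  SJI lies in
[-1, +1]: +1 for an identical regulation pattern, -1 for a perfectly
inverted one, 0 for unrelated sets (or same- and cross-overlap cancelling).
The score is unranked by design — membership and direction only, no
weights or ranks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .signatures import GeneSignature

log = logging.getLogger(__name__)

__all__ = ["SimilarityScore", "jaccard", "signed_jaccard", "pairwise_sji_matrix"]

SJI_COLUMNS = [
    "drug_signature_id",
    "disease_signature_id",
    "sji",
    "j_uu",
    "j_dd",
    "j_ud",
    "j_du",
]


@dataclass(frozen=True)
class SimilarityScore:
    """A similarity value with its audit trail.

    For a plain Jaccard score ``same_count``/``all_count`` are the
    intersection and union sizes.  For an SJI the four component Jaccard
    terms are retained (up/up, down/down, up/down, down/up).
    """

    value: float
    same_count: int | None = None
    all_count: int | None = None
    j_up_up: float | None = None
    j_down_down: float | None = None
    j_up_down: float | None = None
    j_down_up: float | None = None


def jaccard(set_a: Iterable[str], set_b: Iterable[str]) -> SimilarityScore:
    """Jaccard coefficient |A∩B| / |A∪B|; two empty sets score 0 by convention."""
    a, b = set(set_a), set(set_b)
    same = len(a & b)
    all_ = len(a | b)
    if all_ == 0:
        log.debug("jaccard of two empty sets: 0 by convention")
        return SimilarityScore(value=0.0, same_count=0, all_count=0)
    return SimilarityScore(value=same / all_, same_count=same, all_count=all_)


def signed_jaccard(sig1: GeneSignature, sig2: GeneSignature) -> SimilarityScore:
    """Signed Jaccard index between two signatures.

    Symmetric in its arguments, and exactly antisymmetric under swapping one
    signature's up and down sets.
    """
    j_uu = jaccard(sig1.up_genes, sig2.up_genes).value
    j_dd = jaccard(sig1.down_genes, sig2.down_genes).value
    j_ud = jaccard(sig1.up_genes, sig2.down_genes).value
    j_du = jaccard(sig1.down_genes, sig2.up_genes).value
    # grouped so that swapping sig2's directions negates the value exactly
    value = ((j_uu - j_ud) + (j_dd - j_du)) / 2.0
    return SimilarityScore(
        value=value, j_up_up=j_uu, j_down_down=j_dd, j_up_down=j_ud, j_down_up=j_du
    )


def _membership(
    signatures: Sequence[GeneSignature], gene_index: dict[str, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean gene×signature indicator matrices for up and down sets."""
    n_genes, n_sigs = len(gene_index), len(signatures)
    up = np.zeros((n_genes, n_sigs), dtype=np.int32)
    down = np.zeros((n_genes, n_sigs), dtype=np.int32)
    for j, sig in enumerate(signatures):
        for g in sig.up_genes:
            up[gene_index[g], j] = 1
        for g in sig.down_genes:
            down[gene_index[g], j] = 1
    return up, down


def _jaccard_grid(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise Jaccard between the columns of two indicator matrices."""
    inter = a.T @ b
    sizes_a = a.sum(axis=0)[:, None]
    sizes_b = b.sum(axis=0)[None, :]
    union = sizes_a + sizes_b - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        j = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    return j


def pairwise_sji_matrix(
    drugs: Sequence[GeneSignature], diseases: Sequence[GeneSignature]
) -> pd.DataFrame:
    """All drug-signature × disease-signature SJIs as a long-form table.

    Exactly ``len(drugs) * len(diseases)`` rows, ordered lexicographically by
    (drug signature id, disease signature id).  Columns: the SJI plus its
    four component Jaccard terms for audit.
    """
    if not drugs or not diseases:
        raise ValueError("both signature collections must be non-empty")
    drugs = sorted(drugs, key=lambda s: s.signature_id)
    diseases = sorted(diseases, key=lambda s: s.signature_id)
    universe = sorted(
        set().union(*(s.genes for s in drugs)) | set().union(*(s.genes for s in diseases))
    )
    gene_index = {g: i for i, g in enumerate(universe)}
    up_a, down_a = _membership(drugs, gene_index)
    up_b, down_b = _membership(diseases, gene_index)

    j_uu = _jaccard_grid(up_a, up_b)
    j_dd = _jaccard_grid(down_a, down_b)
    j_ud = _jaccard_grid(up_a, down_b)
    j_du = _jaccard_grid(down_a, up_b)
    sji = ((j_uu - j_ud) + (j_dd - j_du)) / 2.0

    drug_ids = [s.signature_id for s in drugs]
    disease_ids = [s.signature_id for s in diseases]
    index = pd.MultiIndex.from_product(
        [drug_ids, disease_ids], names=["drug_signature_id", "disease_signature_id"]
    )
    frame = pd.DataFrame(
        {
            "sji": sji.ravel(),
            "j_uu": j_uu.ravel(),
            "j_dd": j_dd.ravel(),
            "j_ud": j_ud.ravel(),
            "j_du": j_du.ravel(),
        },
        index=index,
    ).reset_index()
    return frame[SJI_COLUMNS]
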