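"""Per-gene relative-reversal scores over drug-disease assay pairs.

For each gene and each group of signature-level (assay) pairs, count how
often the gene is regulated in the same direction in the drug and disease
signatures (NS: up/up or down/down) versus the reverse direction (NR:
up/down or down/up), and form the net direction rate

    D% = (NS - NR) / total pairs * 100

with the group's total pair count in the denominator — pairs where the gene
is absent from either signature dilute the rate.  The relative reversal
score of a gene is the indicated-minus-random difference

    G^I-R% = D^I% - D^R%

A strongly negative G^I-R% marks a gene whose expression is reversed
between drug and disease specifically when the drug is indicated for the
disease.  As the difference of two rates in [-100, 100], the score is
bounded by ±200 by construction (see the methods note on the range).
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .signatures import GeneSignature

log = logging.getLogger(__name__)

__all__ = [
    "count_directions",
    "g_ir_scores",
    "select_top_reversed",
    "write_ranked_list",
]

SCORE_COLUMNS = [
    "gene",
    "ns_indicated",
    "nr_indicated",
    "d_indicated",
    "ns_random",
    "nr_random",
    "d_random",
    "g_ir",
]

SAME = "same"
REVERSE = "reverse"

AssayPair = tuple[GeneSignature, GeneSignature]


def count_directions(drug_sig: GeneSignature, disease_sig: GeneSignature) -> dict[str, str]:
    """Per-gene direction agreement between one drug and one disease signature.

    Returns ``{gene: "same" | "reverse"}`` for genes present in both
    signatures; genes absent from either side are simply not in the mapping.
    """
    labels: dict[str, str] = {}
    for gene in drug_sig.up_genes:
        if gene in disease_sig.up_genes:
            labels[gene] = SAME
        elif gene in disease_sig.down_genes:
            labels[gene] = REVERSE
    for gene in drug_sig.down_genes:
        if gene in disease_sig.down_genes:
            labels[gene] = SAME
        elif gene in disease_sig.up_genes:
            labels[gene] = REVERSE
    return labels


def _group_counts(
    pairs: Sequence[AssayPair],
) -> tuple[dict[str, int], dict[str, int], dict[str, int]]:
    ns: dict[str, int] = {}
    nr: dict[str, int] = {}
    present: dict[str, int] = {}
    for drug_sig, disease_sig in pairs:
        for gene, label in count_directions(drug_sig, disease_sig).items():
            present[gene] = present.get(gene, 0) + 1
            if label == SAME:
                ns[gene] = ns.get(gene, 0) + 1
            else:
                nr[gene] = nr.get(gene, 0) + 1
    return ns, nr, present


def g_ir_scores(
    indicated_assay_pairs: Sequence[AssayPair],
    random_assay_pairs: Sequence[AssayPair],
    gene_universe: Iterable[str] | None = None,
    denominator: str = "all_pairs",
) -> pd.DataFrame:
    """G^I-R% score table over two groups of signature-level pairs.

    ``denominator="all_pairs"`` (default) divides NS - NR by the total
    number of pairs in the group, absent pairs included;
    ``"present_pairs"`` restricts the denominator to pairs where the gene
    occurs in both signatures (sensitivity-analysis variant).  The gene
    universe defaults to every gene appearing in any involved signature.
    """
    if not indicated_assay_pairs or not random_assay_pairs:
        raise ValueError("both assay-pair groups must be non-empty")
    if denominator not in ("all_pairs", "present_pairs"):
        raise ValueError(f"unknown denominator rule {denominator!r}")

    ns_i, nr_i, present_i = _group_counts(indicated_assay_pairs)
    ns_r, nr_r, present_r = _group_counts(random_assay_pairs)

    if gene_universe is None:
        universe: set[str] = set()
        for group in (indicated_assay_pairs, random_assay_pairs):
            for drug_sig, disease_sig in group:
                universe |= drug_sig.genes | disease_sig.genes
    else:
        universe = set(gene_universe)

    n_ind = len(indicated_assay_pairs)
    n_rand = len(random_assay_pairs)

    rows = []
    for gene in sorted(universe):
        a_ns, a_nr = ns_i.get(gene, 0), nr_i.get(gene, 0)
        b_ns, b_nr = ns_r.get(gene, 0), nr_r.get(gene, 0)
        if denominator == "all_pairs":
            denom_i, denom_r = n_ind, n_rand
        else:
            denom_i = present_i.get(gene, 0)
            denom_r = present_r.get(gene, 0)
        d_i = (a_ns - a_nr) / denom_i * 100.0 if denom_i else 0.0
        d_r = (b_ns - b_nr) / denom_r * 100.0 if denom_r else 0.0
        rows.append(
            {
                "gene": gene,
                "ns_indicated": a_ns,
                "nr_indicated": a_nr,
                "d_indicated": d_i,
                "ns_random": b_ns,
                "nr_random": b_nr,
                "d_random": d_r,
                "g_ir": d_i - d_r,
            }
        )
    return pd.DataFrame(rows, columns=SCORE_COLUMNS)


def select_top_reversed(
    scores: pd.DataFrame,
    fraction: float | None = None,
    count: int | None = None,
) -> list[str]:
    """The most-reversed genes: ascending G^I-R%, ties broken by symbol.

    Exactly one of ``fraction`` (top floor(n·fraction) genes) or ``count``
    must be given.
    """
    if (fraction is None) == (count is None):
        raise ValueError("give exactly one of fraction or count")
    if scores.empty:
        raise ValueError("empty score table")
    if fraction is not None:
        if not 0.0 < fraction <= 1.0:
            raise ValueError(f"fraction must be in (0, 1], got {fraction}")
        count = math.floor(len(scores) * fraction)
    ranked = scores.sort_values(["g_ir", "gene"], kind="mergesort")
    return ranked["gene"].head(count).tolist()


def write_ranked_list(
    genes: Sequence[str],
    txt_path: str | Path,
    gmt_path: str | Path | None = None,
    set_name: str = "top_reversed_genes",
) -> None:
    """Export a ranked gene list as plain text and, optionally, one GMT line."""
    Path(txt_path).write_text("\n".join(genes) + "\n")
    if gmt_path is not None:
        Path(gmt_path).write_text(
            "\t".join([set_name, "ranked most-reversed genes", *genes]) + "\n"
        )
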