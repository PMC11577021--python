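"""Count normalization (nRC) and the abundance / guide-count filters.

Raw read counts are converted to normalized read counts (nRC): each
barcode's count divided by the sample total and multiplied by the number
of gRNAs in its library, so that the per-sample mean nRC is 1.  Each
sublibrary is an independently transduced and sequenced pool, so totals
and the scaling constant are computed within sublibrary by default.

Barcodes that drop below ``min_nrc`` in any of a screen's four samples
are excluded (their fold changes would be dominated by counting noise),
and genes left with fewer than ``min_guides_per_gene`` barcodes are then
excluded as unreliably scored.  nRC is computed once on the full library
and not recomputed after filtering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from ciber.errors import ValidationError
from ciber.reference_io import BarcodeReference


@dataclass(frozen=True)
class FilterConfig:
    min_nrc: float = 0.05
    min_guides_per_gene: int = 3

    def __post_init__(self) -> None:
        problems = []
        if self.min_nrc < 0:
            problems.append(f"min_nrc must be >= 0, got {self.min_nrc}")
        if self.min_guides_per_gene < 1:
            problems.append(f"min_guides_per_gene must be >= 1, got {self.min_guides_per_gene}")
        if problems:
            raise ValidationError(problems)


@dataclass
class NormalizedTable:
    """nRC matrix (barcode x sample) plus the per-sublibrary scaling sizes."""

    nrc: pd.DataFrame
    library_size: dict[str, int]


def normalize(
    counts: pd.DataFrame,
    reference: Sequence[BarcodeReference],
    per_sublibrary: bool = True,
) -> NormalizedTable:
    """Compute nRC = count / sample total x library size, within sublibrary.

    With ``per_sublibrary=False`` the whole reference is treated as one
    pool (single-pool data).  A zero sample total is an error naming the
    sample, since nRC is undefined there.
    """
    by_id = {r.barcode_id: r for r in reference}
    missing = [b for b in counts.index if b not in by_id]
    if missing:
        raise ValidationError(f"count table has barcodes absent from the reference: {missing[:5]}")
    sublib = pd.Series(
        {b: (by_id[b].sublibrary if per_sublibrary else "all") for b in counts.index},
        name="sublibrary",
    )

    nrc = pd.DataFrame(index=counts.index, columns=counts.columns, dtype=float)
    library_size: dict[str, int] = {}
    problems = []
    for label, barcode_ids in sublib.groupby(sublib).groups.items():
        block = counts.loc[barcode_ids]
        n = len(barcode_ids)
        library_size[str(label)] = n
        totals = block.sum(axis=0)
        zero = totals[totals == 0].index.tolist()
        if zero:
            problems.append(f"sublibrary {label!r}: zero total count in samples {zero}")
            continue
        nrc.loc[barcode_ids] = block.div(totals, axis=1) * n
    if problems:
        raise ValidationError(problems)
    return NormalizedTable(nrc=nrc, library_size=library_size)


def apply_filters(
    nrc: pd.DataFrame,
    reference: Sequence[BarcodeReference],
    config: FilterConfig = FilterConfig(),
) -> tuple[list[str], list[str], pd.DataFrame]:
    """Apply the per-screen barcode and gene filters.

    ``nrc`` must hold the four samples of one screen (cells/sEVs x
    Cas9+/-).  A barcode is removed iff its nRC is strictly below
    ``min_nrc`` in at least one sample; a gene is then removed iff its
    retained barcodes number fewer than ``min_guides_per_gene``.

    Returns (retained barcode_ids, retained genes, exclusion log) where
    the log has columns item/kind/reason.  The operation is idempotent.
    """
    by_id = {r.barcode_id: r for r in reference}
    gene_of = {b: by_id[b].gene for b in nrc.index}

    low = (nrc < config.min_nrc).any(axis=1)
    removed_barcodes = nrc.index[low].tolist()
    retained_barcodes = nrc.index[~low].tolist()

    log_rows = [{"item": b, "kind": "barcode", "reason": "low_nrc"} for b in removed_barcodes]

    guides_per_gene: dict[str, int] = {}
    for b in retained_barcodes:
        guides_per_gene[gene_of[b]] = guides_per_gene.get(gene_of[b], 0) + 1
    removed_genes = {g for g, n in guides_per_gene.items() if n < config.min_guides_per_gene}
    # genes whose every guide fell to the nRC filter disappear silently otherwise
    for gene in {gene_of[b] for b in removed_barcodes} - set(guides_per_gene):
        removed_genes.add(gene)
    retained_genes = [g for g in dict.fromkeys(gene_of[b] for b in retained_barcodes) if g not in removed_genes]

    log_rows.extend({"item": g, "kind": "gene", "reason": "few_guides"} for g in sorted(removed_genes))
    retained_barcodes = [b for b in retained_barcodes if gene_of[b] not in removed_genes]

    log = pd.DataFrame(log_rows, columns=["item", "kind", "reason"])
    return retained_barcodes, retained_genes, log
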