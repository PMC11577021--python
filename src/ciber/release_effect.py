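"""The release-effect statistic: fold changes, trimmed regression, z-RE.

A gene knockout can change a guide's abundance in the sEV fraction simply
because it changed the producing cells (viability, barcode transcription),
not because it changed vesicle release.  The statistic removes that
confounder by regressing the sEV-fraction fold change on the cellular
fold change and scoring each guide by its residual:

* ``FC_cells = log2(nRC_cells,Cas9+ / nRC_cells,Cas9-)`` and likewise
  ``FC_sEVs`` for the sEV fraction;
* an ordinary least-squares line of ``FC_sEVs`` on ``FC_cells`` is fit
  over all retained guides; tentative residuals are computed;
* within every gene, the single guide with the highest and the single
  guide with the lowest tentative residual are set aside and the line is
  refit on the remaining guides (a robustness trim against outlier
  guides); final residuals (RE, release effect) come from the refit line
  and are reported for every retained guide, trimmed ones included;
* the gene-level RE is the median of its guides' REs, and gene REs are
  z-normalized within each sublibrary to give the z-RE.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from ciber.errors import ValidationError
from ciber.normalization import FilterConfig, apply_filters, normalize
from ciber.reference_io import BarcodeReference, SampleRecord, check_screen_complete

logger = logging.getLogger(__name__)

GUIDE_COLUMNS = ["barcode_id", "gene", "sublibrary", "fc_cells", "fc_sevs", "re", "trimmed"]
GENE_COLUMNS = ["gene", "sublibrary", "n_guides", "re_gene", "z_re"]


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    r: float
    n_points: int

    def predict(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept


def compute_fold_changes(nrc: pd.DataFrame, roles: Mapping[str, str]) -> pd.DataFrame:
    """Per-guide log2 fold changes from the four-sample nRC table.

    ``roles`` maps the four role names ``cells_plus``, ``cells_minus``,
    ``sevs_plus``, ``sevs_minus`` to sample ids (columns of ``nrc``).
    All four nRC values must be positive for every row — the abundance
    filter guarantees this on filtered input.
    """
    required = {"cells_plus", "cells_minus", "sevs_plus", "sevs_minus"}
    missing = required - set(roles)
    if missing:
        raise ValidationError(f"roles mapping lacks {sorted(missing)}")
    quad = nrc[[roles[r] for r in ("cells_plus", "cells_minus", "sevs_plus", "sevs_minus")]]
    if (quad.to_numpy() <= 0).any():
        bad = quad.index[(quad <= 0).any(axis=1)].tolist()
        raise ValidationError(
            f"nonpositive nRC for barcodes {bad[:5]}; apply the abundance filter first"
        )
    return pd.DataFrame(
        {
            "fc_cells": np.log2(nrc[roles["cells_plus"]] / nrc[roles["cells_minus"]]),
            "fc_sevs": np.log2(nrc[roles["sevs_plus"]] / nrc[roles["sevs_minus"]]),
        },
        index=nrc.index,
    )


def fit_line(x, y) -> RegressionFit:
    """Ordinary least-squares fit of y on x with Pearson r of the points."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or np.all(x == x[0]):
        raise ValidationError("regression needs at least 2 distinct x values")
    result = sps.linregress(x, y)
    return RegressionFit(
        slope=float(result.slope),
        intercept=float(result.intercept),
        r=float(result.rvalue),
        n_points=int(x.size),
    )


def _trim_extremes(guides: pd.DataFrame, residuals: np.ndarray) -> np.ndarray:
    """Boolean mask of guides trimmed from the refit: per gene, the single
    highest- and single lowest-residual guide (ties broken by the earliest
    barcode position in the table; a single-guide gene is trimmed once)."""
    trimmed = np.zeros(len(guides), dtype=bool)
    order = np.arange(len(guides))
    frame = pd.DataFrame({"gene": guides["gene"].to_numpy(), "re1": residuals, "pos": order})
    for _, group in frame.groupby("gene", sort=False):
        re1 = group["re1"].to_numpy()
        pos = group["pos"].to_numpy()
        hi = pos[np.lexsort((pos, -re1))[0]]
        lo = pos[np.lexsort((pos, re1))[0]]
        trimmed[hi] = True
        trimmed[lo] = True
    return trimmed


def compute_re(guides: pd.DataFrame) -> tuple[pd.DataFrame, RegressionFit, RegressionFit]:
    """Two-pass trimmed regression; fills ``re`` and ``trimmed`` columns.

    Pass 1 fits all guides and computes tentative residuals; per gene the
    extreme guides are marked trimmed; pass 2 refits on untrimmed guides
    only, and the final RE of *every* guide (trimmed included) is its
    residual from the pass-2 line.  The reported correlation is the
    pass-1 (full point set) Pearson r.
    """
    needed = {"gene", "fc_cells", "fc_sevs"}
    if not needed <= set(guides.columns):
        raise ValidationError(f"guide table lacks columns {sorted(needed - set(guides.columns))}")
    out = guides.copy()
    x = out["fc_cells"].to_numpy(dtype=float)
    y = out["fc_sevs"].to_numpy(dtype=float)

    fit1 = fit_line(x, y)
    residuals1 = y - fit1.predict(x)
    trimmed = _trim_extremes(out, residuals1)
    untrimmed = ~trimmed
    if untrimmed.sum() < 2:
        raise ValidationError(
            f"only {int(untrimmed.sum())} guides remain after trimming; cannot refit"
        )
    fit2 = fit_line(x[untrimmed], y[untrimmed])
    out["re"] = y - fit2.predict(x)
    out["trimmed"] = trimmed
    return out, fit1, fit2


def gene_score(guides: pd.DataFrame, include_trimmed: bool = True) -> pd.DataFrame:
    """Gene-level RE: median over the gene's retained guide REs.

    Guides trimmed from the regression refit still carry final REs and are
    included in the median by default (the trim protects the line fit, not
    the gene summary); ``include_trimmed=False`` switches to the stricter
    reading.  Medians of even counts are the mean of the two middle values.
    """
    table = guides if include_trimmed else guides[~guides["trimmed"]]
    scores = (
        table.groupby("gene", sort=False)
        .agg(sublibrary=("sublibrary", "first"), re_gene=("re", "median"))
        .reset_index()
    )
    # n_guides counts every retained guide of the gene, trimmed or not
    scores["n_guides"] = scores["gene"].map(guides.groupby("gene", sort=False).size())
    return scores[["gene", "sublibrary", "n_guides", "re_gene"]]


def z_normalize(genes: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """z-RE: z-normalize gene REs within each sublibrary.

    ``ddof=1`` (sample SD) by default; ``ddof=0`` gives population SD.
    """
    out = genes.copy()
    z = np.full(len(out), np.nan)
    for label, group in out.groupby("sublibrary", sort=False):
        values = group["re_gene"].to_numpy(dtype=float)
        if values.size < 2:
            raise ValidationError(f"sublibrary {label!r} has fewer than 2 genes; z-RE undefined")
        sd = values.std(ddof=ddof)
        if sd == 0:
            raise ValidationError(f"sublibrary {label!r} has zero RE variance; z-RE undefined")
        z[out.index.get_indexer(group.index)] = (values - values.mean()) / sd
    out["z_re"] = z
    return out


@dataclass
class ScreenResult:
    """Everything ``score_screen`` produces for one screen."""

    guides: pd.DataFrame  # GUIDE_COLUMNS
    genes: pd.DataFrame  # GENE_COLUMNS
    fits: dict[str, tuple[RegressionFit, RegressionFit]]  # sublibrary -> (pass1, pass2)
    exclusions: pd.DataFrame


def score_screen(
    counts: pd.DataFrame,
    manifest: Sequence[SampleRecord],
    reference: Sequence[BarcodeReference],
    screen: str | None = None,
    filter_config: FilterConfig = FilterConfig(),
    include_trimmed_in_median: bool = True,
    sd_ddof: int = 1,
) -> ScreenResult:
    """Run the full scoring pipeline for one screen.

    Normalize (per sublibrary) -> filter -> fold changes -> two-pass
    trimmed regression (per sublibrary, since each sublibrary is an
    independent pool) -> gene medians -> per-sublibrary z-normalization.
    Deterministic; invariant to per-sample sequencing depth and to
    barcode order.
    """
    screens = sorted({r.screen for r in manifest})
    if screen is None:
        if len(screens) != 1:
            raise ValidationError(f"manifest covers screens {screens}; pass `screen` explicitly")
        screen = screens[0]
    lookup = check_screen_complete(manifest, screen)
    sample_ids = [r.sample_id for r in lookup.values()]
    missing = [s for s in sample_ids if s not in counts.columns]
    if missing:
        raise ValidationError(f"count table is missing samples: {missing}")

    by_id = {r.barcode_id: r for r in reference}

    guide_frames, gene_frames, logs = [], [], []
    fits: dict[str, tuple[RegressionFit, RegressionFit]] = {}
    sublibraries = sorted({r.sublibrary for r in reference})
    for sublibrary in sublibraries:
        roles = {
            f"{'cells' if fraction == 'cells' else 'sevs'}_{cas9}": lookup[(sublibrary, fraction, cas9)].sample_id
            for fraction in ("cells", "sEVs")
            for cas9 in ("plus", "minus")
        }
        sub_reference = [r for r in reference if r.sublibrary == sublibrary]
        barcode_ids = [r.barcode_id for r in sub_reference]
        # each sublibrary is an independent pool sequenced in its own four
        # samples, so normalization sees only its own block of the table
        block = counts.loc[barcode_ids, list(dict.fromkeys(roles.values()))]
        nrc = normalize(block, sub_reference, per_sublibrary=True).nrc[list(roles.values())]
        retained_barcodes, _retained_genes, log = apply_filters(nrc, reference, filter_config)
        log = log.copy()
        log["sublibrary"] = sublibrary
        logs.append(log)
        if not retained_barcodes:
            logger.warning("sublibrary %s: no barcodes retained; skipped", sublibrary)
            continue

        fold_changes = compute_fold_changes(nrc.loc[retained_barcodes], roles)
        guides = fold_changes.copy()
        guides.insert(0, "barcode_id", guides.index.astype(str))
        guides = guides.reset_index(drop=True)
        guides["gene"] = [by_id[b].gene for b in guides["barcode_id"]]
        guides["sublibrary"] = sublibrary

        guides, fit1, fit2 = compute_re(guides)
        fits[sublibrary] = (fit1, fit2)
        guide_frames.append(guides[GUIDE_COLUMNS])
        gene_frames.append(gene_score(guides, include_trimmed=include_trimmed_in_median))

    if not guide_frames:
        raise ValidationError(f"screen {screen!r}: no sublibrary retained any barcodes")
    genes = pd.concat(gene_frames, ignore_index=True)
    genes = z_normalize(genes, ddof=sd_ddof)[GENE_COLUMNS]
    return ScreenResult(
        guides=pd.concat(guide_frames, ignore_index=True),
        genes=genes,
        fits=fits,
        exclusions=pd.concat(logs, ignore_index=True) if logs else pd.DataFrame(columns=["item", "kind", "reason", "sublibrary"]),
    )
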