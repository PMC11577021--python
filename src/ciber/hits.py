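"""Hit calling on z-RE and pairwise comparison of two screens.

Genes with z-RE strictly above the threshold (default 1.65, the normal
95th percentile) are upper hits — their knockout increases sEV release —
and genes strictly below the negated threshold are lower hits.  Two
screens run with different sEV markers are compared on their common gene
set: per-gene z-RE differences, a mean +/- k*SD band flagging
marker-specific genes, hit-set overlaps, and the Pearson correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ciber.errors import ValidationError

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 1.65


def call_hits(genes: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD) -> pd.DataFrame:
    """Classify each gene as upper / lower / NS by strict z-RE threshold.

    Genes exactly at +/- threshold are NS ("larger than" is strict).
    """
    if threshold < 0:
        raise ValidationError(f"threshold must be >= 0, got {threshold}")
    out = genes.copy()
    z = out["z_re"].to_numpy(dtype=float)
    hit_class = np.where(z > threshold, "upper", np.where(z < -threshold, "lower", "NS"))
    out["hit_class"] = hit_class
    out["threshold"] = threshold
    return out


@dataclass
class ScreenComparison:
    """Pairwise contrast of two scored screens over their common genes."""

    table: pd.DataFrame  # gene, z_re_a, z_re_b, difference, within_band
    band_center: float
    band_halfwidth: float
    specific_to_a: list[str]
    specific_to_b: list[str]
    pearson_r: float
    overlap_upper: int
    overlap_lower: int
    n_common: int
    dropped_from_a: list[str] = field(default_factory=list)
    dropped_from_b: list[str] = field(default_factory=list)

    def summary(self) -> dict:
        return {
            "n_common": self.n_common,
            "pearson_r": self.pearson_r,
            "band_center": self.band_center,
            "band_halfwidth": self.band_halfwidth,
            "n_specific_to_a": len(self.specific_to_a),
            "n_specific_to_b": len(self.specific_to_b),
            "overlap_upper": self.overlap_upper,
            "overlap_lower": self.overlap_lower,
        }


def compare_screens(
    genes_a: pd.DataFrame,
    genes_b: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
    band_k: float = 2.0,
    ddof: int = 1,
) -> ScreenComparison:
    """Compare two screens on the intersection of their scored genes.

    The difference band is mean(d) +/- band_k * SD(d) over all common
    genes, d = z_re_a - z_re_b; genes outside it are specific to the
    screen whose score is higher.  Genes scored in only one screen are
    dropped (and reported), since a one-sided score cannot be contrasted.
    """
    a = genes_a.set_index("gene")["z_re"]
    b = genes_b.set_index("gene")["z_re"]
    common = a.index.intersection(b.index)
    if len(common) == 0:
        raise ValidationError("the two screens share no scored genes")
    dropped_a = a.index.difference(common).tolist()
    dropped_b = b.index.difference(common).tolist()
    if dropped_a or dropped_b:
        logger.info(
            "comparison drops %d genes unique to A and %d unique to B", len(dropped_a), len(dropped_b)
        )

    za = a.loc[common].to_numpy(dtype=float)
    zb = b.loc[common].to_numpy(dtype=float)
    difference = za - zb
    center = float(difference.mean())
    halfwidth = float(band_k * difference.std(ddof=ddof)) if len(common) > ddof else 0.0
    within = np.abs(difference - center) <= halfwidth

    table = pd.DataFrame(
        {
            "gene": common,
            "z_re_a": za,
            "z_re_b": zb,
            "difference": difference,
            "within_band": within,
        }
    )
    upper_a = set(common[za > threshold])
    upper_b = set(common[zb > threshold])
    lower_a = set(common[za < -threshold])
    lower_b = set(common[zb < -threshold])

    if len(common) >= 2 and za.std() > 0 and zb.std() > 0:
        pearson_r = float(np.corrcoef(za, zb)[0, 1])
    else:
        pearson_r = float("nan")

    return ScreenComparison(
        table=table,
        band_center=center,
        band_halfwidth=halfwidth,
        specific_to_a=sorted(common[(difference - center) > halfwidth]),
        specific_to_b=sorted(common[(difference - center) < -halfwidth]),
        pearson_r=pearson_r,
        overlap_upper=len(upper_a & upper_b),
        overlap_lower=len(lower_a & lower_b),
        n_common=len(common),
        dropped_from_a=dropped_a,
        dropped_from_b=dropped_b,
    )
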