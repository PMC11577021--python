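"""Independent brute-force oracle for the scoring procedure.

A literal, loop-based transcription of the scoring rules in plain Python
(statistics module, closed-form normal equations), deliberately sharing
no code with the package implementation.  Used to cross-check the
vectorized pipeline on small instances.
"""

import math
import statistics


def ols(points):
    """Closed-form normal-equation OLS fit; returns (slope, intercept)."""
    n = len(points)
    sx = sum(x for x, _ in points)
    sy = sum(y for _, y in points)
    sxx = sum(x * x for x, _ in points)
    sxy = sum(x * y for x, y in points)
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return slope, intercept


def pearson(xs, ys):
    mx = statistics.mean(xs)
    my = statistics.mean(ys)
    num = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    den = math.sqrt(sum((x - mx) ** 2 for x in xs) * sum((y - my) ** 2 for y in ys))
    return num / den


def score_screen_oracle(
    counts,
    gene_of,
    sublibrary_of,
    roles,
    min_nrc=0.05,
    min_guides=3,
    ddof=1,
    include_trimmed_in_median=True,
):
    """Score one screen the slow way.

    counts: dict barcode_id -> dict sample_id -> int, all barcodes of the
    library present.  roles: dict role -> sample_id with roles
    cells_plus/cells_minus/sevs_plus/sevs_minus.  Returns
    (guide_rows, gene_rows) as dicts keyed by barcode_id / gene.
    """
    barcodes = list(counts)
    samples = list(roles.values())

    # nRC per sublibrary: divide by sample total within the pool, times pool size
    nrc = {}
    sublibs = sorted({sublibrary_of[b] for b in barcodes})
    for sublib in sublibs:
        members = [b for b in barcodes if sublibrary_of[b] == sublib]
        n = len(members)
        for sample in samples:
            total = sum(counts[b][sample] for b in members)
            for b in members:
                nrc.setdefault(b, {})[sample] = counts[b][sample] / total * n

    guide_rows = {}
    gene_rows = {}
    for sublib in sublibs:
        members = [b for b in barcodes if sublibrary_of[b] == sublib]

        # barcode filter: nRC below threshold in any of the four samples
        retained = [b for b in members if all(nrc[b][s] >= min_nrc for s in samples)]
        # gene filter: fewer than min_guides retained barcodes
        per_gene = {}
        for b in retained:
            per_gene.setdefault(gene_of[b], []).append(b)
        kept_genes = {g for g, bs in per_gene.items() if len(bs) >= min_guides}
        retained = [b for b in retained if gene_of[b] in kept_genes]

        fc_cells = {
            b: math.log2(nrc[b][roles["cells_plus"]] / nrc[b][roles["cells_minus"]]) for b in retained
        }
        fc_sevs = {
            b: math.log2(nrc[b][roles["sevs_plus"]] / nrc[b][roles["sevs_minus"]]) for b in retained
        }

        # pass 1: fit everything, tentative residuals
        slope1, intercept1 = ols([(fc_cells[b], fc_sevs[b]) for b in retained])
        re1 = {b: fc_sevs[b] - (slope1 * fc_cells[b] + intercept1) for b in retained}

        # per gene set aside the single highest- and lowest-residual barcode
        trimmed = set()
        for g in kept_genes:
            group = [b for b in retained if gene_of[b] == g]
            best = group[0]
            for b in group[1:]:
                if re1[b] > re1[best]:
                    best = b
            worst = group[0]
            for b in group[1:]:
                if re1[b] < re1[worst]:
                    worst = b
            trimmed.add(best)
            trimmed.add(worst)

        # pass 2: refit without the trimmed barcodes; final residuals for all
        untrimmed = [b for b in retained if b not in trimmed]
        slope2, intercept2 = ols([(fc_cells[b], fc_sevs[b]) for b in untrimmed])
        re = {b: fc_sevs[b] - (slope2 * fc_cells[b] + intercept2) for b in retained}

        for b in retained:
            guide_rows[b] = {
                "gene": gene_of[b],
                "fc_cells": fc_cells[b],
                "fc_sevs": fc_sevs[b],
                "re": re[b],
                "trimmed": b in trimmed,
            }

        for g in sorted(kept_genes):
            group = [b for b in retained if gene_of[b] == g]
            if not include_trimmed_in_median:
                group = [b for b in group if b not in trimmed]
            gene_rows[g] = {
                "sublibrary": sublib,
                "re_gene": statistics.median(re[b] for b in group),
                "n_guides": len([b for b in retained if gene_of[b] == g]),
            }

    # z-normalize within sublibrary
    for sublib in sublibs:
        genes = [g for g in gene_rows if gene_rows[g]["sublibrary"] == sublib]
        values = [gene_rows[g]["re_gene"] for g in genes]
        mean = statistics.mean(values)
        if ddof == 1:
            sd = statistics.stdev(values)
        else:
            sd = statistics.pstdev(values)
        for g in genes:
            gene_rows[g]["z_re"] = (gene_rows[g]["re_gene"] - mean) / sd

    return guide_rows, gene_rows
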