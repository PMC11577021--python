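"""Synthetic screens with known ground truth.

The generator emulates the statistical structure the scoring model
assumes: each gene g has a cellular effect beta_g (viability, barcode
transcription — anything that changes guide abundance in cells) and a
release effect rho_g (what the screen is after).  Per guide i of gene g,

* baseline abundance  a_i ~ LogNormal(0, sd_baseline)  (library skew),
* FC_cells_i = beta_g + eps_i,
* FC_sEVs_i  = slope * FC_cells_i + rho_g + eps'_i,

with eps, eps' ~ Normal(0, sd_guide_noise), so the sEV-fraction fold
change depends linearly on the cellular one with an additive gene-level
release residual.  Expected counts in the four samples are

    cells/Cas9-: a_i                cells/Cas9+: a_i * 2**FC_cells_i
    sEVs/Cas9-:  a_i * 2**u_i       sEVs/Cas9+:  a_i * 2**(u_i + FC_sEVs_i)

where u_i ~ Normal(0, sd_guide_noise) is a per-guide sEV-loading
deviation shared between the two sEV samples.  Each sample's counts are
drawn multinomially at a fixed total of depth x n_guides (competitive
sequencing of one pool); a negative-binomial per-guide mode is available
for overdispersion studies.  Sequencing error, chimeric reads and index
hopping are not modeled.

Spacers are rejection-sampled to be unique and free of the scaffold key,
and simulated reads are built so the first eligible key occurrence is
the intended one, so barcode counting round-trips exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from ciber.errors import ValidationError
from ciber.reference_io import BarcodeReference, SampleRecord

FRACTION_OF = {"cells": "cells", "sevs": "sEVs"}
SAMPLE_ROLES = ("cells_plus", "cells_minus", "sevs_plus", "sevs_minus")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated screen.

    Defaults mirror a typical pooled screen of this kind: 500 expected
    reads per guide per sample (the cells-per-guide scale shown to give
    reproducible barcoding), unit slope between the two fold changes,
    moderate library skew, and gene effects on the log2 scale.
    """

    n_genes: int = 1000
    guides_per_gene: int = 5
    sublibraries: dict[str, int] | None = None  # label -> gene count; None = one pool
    depth: float = 500.0
    slope: float = 1.0
    sd_baseline: float = 0.5
    sd_guide_noise: float = 0.3
    frac_viability_genes: float = 0.2
    effect_sd_viability: float = 1.0
    frac_release_genes: float = 0.05
    effect_sd_release: float = 1.0
    seed: int = 0
    count_model: str = "multinomial"  # or "negative_binomial"
    nb_dispersion: float = 0.05  # NB: var = mu + nb_dispersion * mu^2
    spacer_length: int = 17
    key: str = "GTTTAAGA"
    screen_label: str = "SIM"

    def validate(self) -> None:
        problems = []
        if self.n_genes < 1:
            problems.append(f"n_genes must be >= 1, got {self.n_genes}")
        if self.guides_per_gene < 1:
            problems.append(f"guides_per_gene must be >= 1, got {self.guides_per_gene}")
        if self.depth <= 0:
            problems.append(f"depth must be > 0, got {self.depth}")
        for name in ("sd_baseline", "sd_guide_noise", "effect_sd_viability", "effect_sd_release"):
            if getattr(self, name) < 0:
                problems.append(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("frac_viability_genes", "frac_release_genes"):
            if not 0 <= getattr(self, name) <= 1:
                problems.append(f"{name} must be in [0, 1], got {getattr(self, name)}")
        if self.count_model not in ("multinomial", "negative_binomial"):
            problems.append(f"count_model must be multinomial or negative_binomial, got {self.count_model!r}")
        if self.nb_dispersion < 0:
            problems.append(f"nb_dispersion must be >= 0, got {self.nb_dispersion}")
        if self.spacer_length < 1:
            problems.append(f"spacer_length must be >= 1, got {self.spacer_length}")
        if not self.key or not set(self.key) <= set("ACGT"):
            problems.append(f"key {self.key!r} must be a non-empty ACGT string")
        if self.sublibraries is not None:
            total = sum(self.sublibraries.values())
            if total != self.n_genes:
                problems.append(
                    f"sublibrary gene counts sum to {total}, expected n_genes = {self.n_genes}"
                )
            for label in self.sublibraries:
                try:
                    float(label)
                    problems.append(f"sublibrary label {label!r} must not be numeric")
                except ValueError:
                    pass
        if problems:
            raise ValidationError(problems)

    def resolved_sublibraries(self) -> dict[str, int]:
        return dict(self.sublibraries) if self.sublibraries else {"SIM1": self.n_genes}


@dataclass
class SimulatedScreen:
    """A generated screen: library, samples, counts and the ground truth."""

    config: SimulationConfig
    reference: list[BarcodeReference]
    manifest: list[SampleRecord]
    counts: pd.DataFrame  # barcode x sample, int
    truth: pd.DataFrame  # gene, sublibrary, beta, rho
    latents: pd.DataFrame  # per guide: fc_cells, fc_sevs, baseline, u

    def sample_id(self, sublibrary: str, role: str) -> str:
        return f"{sublibrary}_{role}"


def _sample_spacers(rng: np.random.Generator, n: int, length: int, key: str) -> list[str]:
    """Unique random spacers containing no occurrence of the key."""
    alphabet = np.array(list("ACGT"))
    spacers: list[str] = []
    seen: set[str] = set()
    while len(spacers) < n:
        batch = ["".join(alphabet[rng.integers(0, 4, size=length)]) for _ in range(max(64, n - len(spacers)))]
        for spacer in batch:
            if spacer in seen or key in spacer:
                continue
            seen.add(spacer)
            spacers.append(spacer)
            if len(spacers) == n:
                break
    return spacers


def _draw_counts(rng: np.random.Generator, expected: np.ndarray, depth: float, model: str, nb_dispersion: float) -> np.ndarray:
    total = int(round(depth * expected.size))
    if model == "multinomial":
        return rng.multinomial(total, expected / expected.sum())
    mu = expected / expected.mean() * depth
    if nb_dispersion == 0:
        return rng.poisson(mu)
    # NB parameterized as Gamma-Poisson: shape r = 1/dispersion, p = r/(r+mu)
    r = 1.0 / nb_dispersion
    return rng.negative_binomial(r, r / (r + mu))


def simulate_screen(config: SimulationConfig) -> SimulatedScreen:
    """Generate one screen under ``config``; bit-reproducible for a fixed seed."""
    config.validate()
    root = np.random.SeedSequence(config.seed)
    rng_spacer, rng_effects, rng_latent, rng_counts = (
        np.random.default_rng(s) for s in root.spawn(4)
    )

    sublibraries = config.resolved_sublibraries()
    genes, gene_sublib = [], []
    offset = 0
    for label, count in sublibraries.items():
        genes.extend(f"G{offset + j:05d}" for j in range(count))
        gene_sublib.extend([label] * count)
        offset += count
    n_genes = len(genes)
    n_guides = n_genes * config.guides_per_gene

    n_viability = int(round(config.frac_viability_genes * n_genes))
    n_release = int(round(config.frac_release_genes * n_genes))
    beta = np.zeros(n_genes)
    rho = np.zeros(n_genes)
    if n_viability:
        chosen = rng_effects.choice(n_genes, size=n_viability, replace=False)
        beta[chosen] = rng_effects.normal(0.0, config.effect_sd_viability, size=n_viability)
    if n_release:
        chosen = rng_effects.choice(n_genes, size=n_release, replace=False)
        rho[chosen] = rng_effects.normal(0.0, config.effect_sd_release, size=n_release)
    truth = pd.DataFrame({"gene": genes, "sublibrary": gene_sublib, "beta": beta, "rho": rho})

    spacers = _sample_spacers(rng_spacer, n_guides, config.spacer_length, config.key)
    reference: list[BarcodeReference] = []
    guide_gene_index = np.repeat(np.arange(n_genes), config.guides_per_gene)
    for i, g in enumerate(guide_gene_index):
        guide_no = i % config.guides_per_gene + 1
        sublib = gene_sublib[g]
        barcode_id = f"{genes[g]}_{spacers[i]}_{guide_no}_{sublib}"
        reference.append(BarcodeReference(barcode_id=barcode_id, gene=genes[g], spacer=spacers[i], sublibrary=sublib))

    baseline = rng_latent.lognormal(0.0, config.sd_baseline, size=n_guides)
    eps = rng_latent.normal(0.0, config.sd_guide_noise, size=n_guides)
    eps_prime = rng_latent.normal(0.0, config.sd_guide_noise, size=n_guides)
    u = rng_latent.normal(0.0, config.sd_guide_noise, size=n_guides)
    fc_cells = beta[guide_gene_index] + eps
    fc_sevs = config.slope * fc_cells + rho[guide_gene_index] + eps_prime

    expected = {
        "cells_minus": baseline,
        "cells_plus": baseline * np.exp2(fc_cells),
        "sevs_minus": baseline * np.exp2(u),
        "sevs_plus": baseline * np.exp2(u + fc_sevs),
    }

    barcode_ids = [r.barcode_id for r in reference]
    counts = pd.DataFrame(index=pd.Index(barcode_ids, name="barcode_id"), dtype="int64")
    manifest: list[SampleRecord] = []
    guide_sublib = np.array([gene_sublib[g] for g in guide_gene_index])
    for label in sublibraries:
        mask = guide_sublib == label
        for role in SAMPLE_ROLES:
            sample_id = f"{label}_{role}"
            column = np.zeros(n_guides, dtype="int64")
            column[mask] = _draw_counts(
                rng_counts, expected[role][mask], config.depth, config.count_model, config.nb_dispersion
            )
            counts[sample_id] = column
            fraction_key, cas9 = role.rsplit("_", 1)
            manifest.append(
                SampleRecord(
                    sample_id=sample_id,
                    fraction=FRACTION_OF[fraction_key],
                    cas9=cas9,
                    screen=config.screen_label,
                    sublibrary=label,
                )
            )

    latents = pd.DataFrame(
        {
            "barcode_id": barcode_ids,
            "gene": [genes[g] for g in guide_gene_index],
            "sublibrary": guide_sublib,
            "baseline": baseline,
            "fc_cells": fc_cells,
            "fc_sevs": fc_sevs,
            "u": u,
        }
    )
    return SimulatedScreen(
        config=config, reference=reference, manifest=manifest, counts=counts, truth=truth, latents=latents
    )


def simulate_fastq(
    screen: SimulatedScreen,
    sample_id: str,
    read_length: int = 50,
    seed: int = 0,
    max_prefix: int | None = None,
) -> tuple[list[tuple[str, str]], pd.Series]:
    """Reads for one sample: random prefix + spacer + key + random tail.

    Returns ``(records, ledger)`` where records are ``(read_id, sequence)``
    in shuffled order and the ledger gives the exact per-barcode read
    numbers (equal to ``screen.counts[sample_id]``).  Prefixes and tails
    are rejection-sampled so the first eligible key occurrence in each
    read is the intended one — counting the reads back recovers the
    ledger exactly.
    """
    if sample_id not in screen.counts.columns:
        raise ValidationError(f"unknown sample {sample_id!r}")
    config = screen.config
    fixed = config.spacer_length + len(config.key)
    if read_length < fixed:
        raise ValidationError(
            f"read_length {read_length} is shorter than spacer + key = {fixed}"
        )
    headroom = read_length - fixed
    if max_prefix is None:
        max_prefix = min(10, headroom)
    if max_prefix > headroom:
        raise ValidationError(f"max_prefix {max_prefix} leaves no room in a {read_length}-nt read")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    alphabet = np.array(list("ACGT"))
    ledger = screen.counts[sample_id].copy()
    spacer_of = {r.barcode_id: r.spacer for r in screen.reference}

    records: list[tuple[str, str]] = []
    for barcode_id, n_reads in ledger.items():
        spacer = spacer_of[barcode_id]
        for j in range(int(n_reads)):
            while True:
                prefix_len = int(rng.integers(0, max_prefix + 1))
                prefix = "".join(alphabet[rng.integers(0, 4, size=prefix_len)])
                tail_len = read_length - prefix_len - fixed
                tail = "".join(alphabet[rng.integers(0, 4, size=tail_len)])
                read = prefix + spacer + config.key + tail
                intended = prefix_len + config.spacer_length
                if read.find(config.key, config.spacer_length) == intended:
                    break
            records.append((f"{sample_id}:{barcode_id}:{j}", read))
    order = rng.permutation(len(records))
    records = [records[i] for i in order]
    return records, ledger


def write_fastq(records: Sequence[tuple[str, str]], path) -> None:
    """Write ``(read_id, sequence)`` records as FASTQ with constant quality."""
    with open(path, "w") as handle:
        for read_id, sequence in records:
            handle.write(f"@{read_id}\n{sequence}\n+\n{'I' * len(sequence)}\n")
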