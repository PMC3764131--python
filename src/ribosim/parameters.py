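"""Per-gene translational parameters from count tables and a codon rate table.

The quantities derived here, per gene:

=========  ====================================================================
``L``      coding-sequence length in codons
``x``      transcript copies per cell
``w``      ribosomes attached per transcript copy
``g``      ribosome density, ribosomes per 100 codons (``g = 100 w / L``)
``E``      total elongation time of the transcript, s (sum of codon times)
``tau``    mean elongation time of one codon, s (``E / L``)
``I``      translation initiation time, s (``I = E / w``)
``m``      mean transcript lifetime, s
``b``      proteins made per transcript over its lifetime (``b = m / I``)
=========  ====================================================================

``w`` is obtained from ribosome-profiling footprint counts: a gene's share
of all footprints in the cell is its share of the actively translating
ribosome pool, and dividing the gene's ribosome allocation by its transcript
copy number ``x`` gives the per-copy load. 85% of cellular ribosomes are
assumed engaged in translation by default.

For organisms that express only a fraction of their genome at a time (the
bacterial case), summing footprints over every profiled gene overstates the
per-cell footprint total; :func:`estimate_total_footprints` instead averages
sums over random subsets of the typical number of simultaneously expressed
genes, drawn without replacement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .codon_kinetics import CodonRateTable
from .errors import (
    ConfigurationError,
    DerivationError,
    InvalidInputError,
    UndefinedCorrelationError,
    UndefinedLoadError,
)
from .simulate import DEFAULT_FOOTPRINT, SimConfig, detect_queuing, validate_cds


@dataclass(frozen=True)
class OrganismConstants:
    """Cell-wide constants of one organism."""

    name: str
    transcriptome_size: float      # transcripts per cell
    ribosomes_per_cell: float
    cell_volume: float             # m^3
    total_trnas: float
    temperature: float             # degrees C
    active_fraction: float = 0.85  # fraction of ribosomes engaged in translation
    footprint: int = DEFAULT_FOOTPRINT

    def __post_init__(self):
        for name in ("transcriptome_size", "ribosomes_per_cell", "cell_volume",
                     "total_trnas"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be positive")
        if not 0 < self.active_fraction <= 1:
            raise InvalidInputError("active_fraction must be in (0, 1]")


@dataclass(frozen=True)
class GeneRecord:
    """One gene's CDS and measured inputs."""

    gene: str
    cds: tuple[str, ...]
    footprint_counts: tuple[float, ...]
    mrna_measure: float                # relative or absolute transcript abundance
    mrna_lifetime: float | None = None  # s

    def __post_init__(self):
        object.__setattr__(self, "cds", tuple(validate_cds(self.cds)))
        object.__setattr__(
            self, "footprint_counts", tuple(float(c) for c in self.footprint_counts)
        )
        if any(c < 0 for c in self.footprint_counts) or self.mrna_measure < 0:
            raise InvalidInputError(f"{self.gene}: counts must be >= 0")

    @property
    def footprint_total(self) -> float:
        return sum(self.footprint_counts)


@dataclass(frozen=True)
class TranslationParams:
    """Derived per-gene translational parameters (SI units)."""

    gene: str
    L: int
    x: float
    w: float
    g: float
    E: float
    tau_mean: float
    I: float
    m: float | None = None
    b: float | None = None


def absolute_mrna(rel: Sequence[float], transcriptome_size: float) -> np.ndarray:
    """Rescale relative transcript abundances to absolute copies per cell.

    Assumes the input covers the transcriptome completely, so the rescaled
    copies sum to ``transcriptome_size`` exactly.
    """
    rel = np.asarray(rel, dtype=float)
    if rel.ndim != 1 or rel.size == 0:
        raise InvalidInputError("rel must be a non-empty 1-D array")
    if (rel < 0).any():
        raise InvalidInputError("relative abundances must be >= 0")
    total = rel.sum()
    if total <= 0:
        raise InvalidInputError("all-zero abundance vector")
    return rel / total * transcriptome_size


def estimate_total_footprints(
    per_gene_totals: Sequence[float],
    n_genes: int = 600,
    n_draws: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> float:
    """Subsample-sum estimate of the cell-wide footprint total.

    Mean over ``n_draws`` of sums of ``n_genes`` distinct genes sampled
    without replacement; unbiased for ``n_genes/N`` times the pool total.
    The defaults (600 of the profiled pool, 1000 draws) reflect the typical
    number of genes a bacterial cell expresses simultaneously.
    """
    totals = np.asarray(per_gene_totals, dtype=float)
    if n_genes > totals.size:
        raise InvalidInputError(
            f"cannot sample {n_genes} genes from a pool of {totals.size}"
        )
    rng = np.random.default_rng(seed)
    sums = np.empty(n_draws)
    for i in range(n_draws):
        sums[i] = totals[rng.choice(totals.size, size=n_genes, replace=False)].sum()
    return float(sums.mean())


def ribosome_load(
    footprint_share: float, constants: OrganismConstants, x: float
) -> float:
    """Ribosomes per transcript copy from a gene's share of cellular footprints.

    ``w = share * active_fraction * ribosomes_per_cell / x``.
    """
    if not 0 <= footprint_share <= 1:
        raise InvalidInputError(f"footprint share must be in [0,1], got {footprint_share}")
    if x <= 0:
        raise UndefinedLoadError("ribosome load undefined for zero transcript copies")
    return footprint_share * constants.active_fraction * constants.ribosomes_per_cell / x


#: Filter thresholds, exposed for custom rule sets.
MIN_COMBINED_COUNTS = 128     # yeast/human: footprint + mRNA count floor
MIN_REPLICATE_COUNTS = 100    # bacterial rule: per-replicate footprint floor
MAX_DENSITY = 10.0            # ribosomes per 100 codons; packing limit at 10-codon footprint


def apply_filters(
    records: Sequence[GeneRecord],
    densities: Mapping[str, float],
    organism: str,
    *,
    min_combined: float = MIN_COMBINED_COUNTS,
    min_replicate: float = MIN_REPLICATE_COUNTS,
    max_density: float = MAX_DENSITY,
) -> tuple[list[GeneRecord], dict[str, int]]:
    """Apply the organism's count filters plus the density ceiling.

    Eukaryote rule (``yeast``/``human``): drop genes lacking footprint or
    mRNA counts entirely, or whose footprint+mRNA sum is below
    ``min_combined``. Bacterial rule (``ecoli``): drop genes with any
    replicate's footprint count below ``min_replicate``. All organisms:
    retain only densities ``g <= max_density``.

    Returns the retained records and a per-rule exclusion tally (a gene may
    trip several rules; the rules are order-independent).
    """
    if organism not in ("ecoli", "yeast", "human"):
        raise ConfigurationError(
            f"unknown organism {organism!r}; supply custom thresholds via "
            "one of ecoli/yeast/human plus keyword overrides"
        )
    tally = {"missing_counts": 0, "low_combined": 0, "low_replicate": 0, "high_density": 0}
    retained = []
    for rec in records:
        g = densities[rec.gene]
        drop = False
        if organism in ("yeast", "human"):
            if rec.footprint_total == 0 or rec.mrna_measure == 0:
                tally["missing_counts"] += 1
                drop = True
            elif rec.footprint_total + rec.mrna_measure < min_combined:
                tally["low_combined"] += 1
                drop = True
        else:  # ecoli
            if any(c < min_replicate for c in rec.footprint_counts):
                tally["low_replicate"] += 1
                drop = True
        if g > max_density:
            tally["high_density"] += 1
            drop = True
        if not drop:
            retained.append(rec)
    return retained, tally


def derive_params(
    record: GeneRecord,
    rate_table: CodonRateTable,
    w: float,
    x: float = float("nan"),
) -> TranslationParams:
    """Derive one gene's translational parameters from its CDS, rate table and load.

    ``E`` is the sum of the per-codon elongation times; ``I = E / w``;
    ``b = m / I`` when a lifetime is supplied.
    """
    if w <= 0:
        raise DerivationError(f"{record.gene}: ribosome load w must be > 0")
    try:
        profile = rate_table.tau_profile(record.cds)
    except KeyError as exc:
        raise DerivationError(
            f"{record.gene}: codon {exc.args[0]} missing from rate table"
        ) from exc
    L = len(record.cds)
    E = sum(profile)
    I = E / w
    m = record.mrna_lifetime
    return TranslationParams(
        gene=record.gene, L=L, x=x, w=w, g=100.0 * w / L,
        E=E, tau_mean=E / L, I=I, m=m, b=(m / I if m is not None else None),
    )


def mean_ribosome_gap(g: float, footprint: int = DEFAULT_FOOTPRINT) -> float:
    """Average gap between adjacent ribosomes, in codons, at density ``g``.

    At ``g`` ribosomes per 100 codons the centre-to-centre spacing is
    ``100/g`` codons, of which the footprint itself covers ``footprint``.
    """
    if g <= 0:
        raise InvalidInputError("density g must be > 0")
    return 100.0 / g - footprint


def collision_free_subset(
    entries: Sequence[tuple[GeneRecord, TranslationParams]],
    rate_table: CodonRateTable,
    footprint: int = DEFAULT_FOOTPRINT,
    horizon: float | None = None,
) -> tuple[list[tuple[GeneRecord, TranslationParams]], int]:
    """Drop transcripts on which ribosome queuing occurs at their derived I.

    Each gene is replayed through the exclusion-process simulator with its
    own initiation interval and dwell profile; genes where any ribosome is
    ever blocked are removed. Returns (retained, number dropped).
    """
    retained = []
    dropped = 0
    for rec, params in entries:
        profile = rate_table.tau_profile(rec.cds)
        cfg = SimConfig(
            initiation_interval=params.I,
            tau_profile=tuple(profile),
            footprint=footprint,
            collision_mode="halt",
            horizon=horizon,
        )
        queued, _ = detect_queuing(rec.cds, cfg)
        if queued:
            dropped += 1
        else:
            retained.append((rec, params))
    return retained, dropped


def spearman_rho_ci(
    x: Sequence[float],
    y: Sequence[float],
    level: float = 0.95,
    method: str = "fisher",
    n_boot: int = 10_000,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float, float]:
    """Spearman rank correlation with a two-sided confidence interval.

    ``method='fisher'`` (default) applies the Fisher z-transform with
    standard error ``1/sqrt(n-3)``; ``method='bootstrap'`` uses the
    percentile interval over ``n_boot`` pair resamples.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidInputError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 4:
        raise InvalidInputError("need at least 4 pairs")
    if np.isnan(x).any() or np.isnan(y).any():
        raise InvalidInputError("missing values not allowed")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("constant input vector")
    rho = float(stats.spearmanr(x, y).statistic)
    if method == "fisher":
        z = np.arctanh(np.clip(rho, -1 + 1e-15, 1 - 1e-15))
        half = stats.norm.ppf(0.5 + level / 2) / np.sqrt(n - 3)
        lo, hi = np.tanh(z - half), np.tanh(z + half)
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n, size=(n_boot, n))
        rhos = np.array([
            stats.spearmanr(x[i], y[i]).statistic for i in idx
        ])
        rhos = rhos[~np.isnan(rhos)]
        alpha = (1 - level) / 2
        lo, hi = np.quantile(rhos, [alpha, 1 - alpha])
    else:
        raise ConfigurationError(f"unknown CI method {method!r}")
    return rho, float(min(lo, rho)), float(max(hi, rho))


def derive_gene_table(
    records: Sequence[GeneRecord],
    rate_table: CodonRateTable,
    constants: OrganismConstants,
    *,
    use_subsample_estimator: bool = False,
    n_genes: int = 600,
    n_draws: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """End-to-end derivation for a gene table.

    Converts relative mRNA measures to absolute copies, turns footprint
    counts into per-transcript ribosome loads (optionally via the
    subsample-sum footprint-total estimator), and derives every per-gene
    parameter. Returns one row per gene with columns
    ``gene, L, x, w, g, E_s, tau_s, I_s, m_s, b``.
    """
    if not records:
        return pd.DataFrame(
            columns=["gene", "L", "x", "w", "g", "E_s", "tau_s", "I_s", "m_s", "b"]
        )
    xs = absolute_mrna([r.mrna_measure for r in records], constants.transcriptome_size)
    totals = np.array([r.footprint_total for r in records], dtype=float)
    if use_subsample_estimator:
        denom = estimate_total_footprints(totals, n_genes, n_draws, seed)
    else:
        denom = totals.sum()
    if denom <= 0:
        raise InvalidInputError("zero total footprint count")
    rows = []
    for rec, x, tot in zip(records, xs, totals):
        share = min(tot / denom, 1.0)
        w = ribosome_load(share, constants, x)
        if w <= 0:
            rows.append({"gene": rec.gene, "L": len(rec.cds), "x": x, "w": 0.0,
                         "g": 0.0, "E_s": np.nan, "tau_s": np.nan, "I_s": np.nan,
                         "m_s": rec.mrna_lifetime, "b": np.nan})
            continue
        p = derive_params(rec, rate_table, w, x)
        rows.append({"gene": p.gene, "L": p.L, "x": p.x, "w": p.w, "g": p.g,
                     "E_s": p.E, "tau_s": p.tau_mean, "I_s": p.I,
                     "m_s": p.m, "b": p.b})
    return pd.DataFrame(rows)
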