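"""Synthetic test data with known ground truth.

Everything the pipeline consumes can be generated here: tRNA pools with
guaranteed sense-codon coverage, coding sequences with a tunable codon-usage
bias, and measurement tables constructed by inverting the derivation chain,
so that noise-free derivation returns the stored true parameters exactly.

The generated pools mimic the *shape* of real isoacceptor sets (one to a few
species per amino acid, lognormal abundances spanning ~two decades, tRNA-scale
diffusion coefficients and sizes) but none of their organism-specific
structure — no wobble rules, no codon-usage/abundance co-adaptation. What
passes on these fixtures therefore validates the arithmetic and the
simulation logic, not any biological claim about a particular genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .codon_kinetics import (
    CodonRateTable,
    KineticConstants,
    TRNASpecies,
    build_rate_table,
)
from .errors import GenerationError
from .genetics import SENSE_CODONS, translate_codon, wc_anticodon
from .parameters import GeneRecord, OrganismConstants, TranslationParams

# plausible physical ranges for a tRNA molecule
_DIFFUSION_MEAN = 1.0e-11   # m^2/s
_SIZE_MEAN = 1.0e-8         # m


def make_minimal_pool(abundance: float = 1000.0) -> list[TRNASpecies]:
    """Competition-free limit: a single species decoding every sense codon.

    Each codon then has exactly one cognate and empty near-/non-cognate
    sets, so every elongation time collapses to the cognate insertion time.
    """
    return [
        TRNASpecies(
            id="tRNA-universal",
            anticodon=wc_anticodon("GCT"),
            amino_acid="X",
            decoded_codons=frozenset(SENSE_CODONS),
            abundance=abundance,
            diffusion_coeff=_DIFFUSION_MEAN,
            size=_SIZE_MEAN,
        )
    ]


def make_trna_pool(
    seed: int | np.random.Generator = 0,
    relative: bool = False,
    constants: KineticConstants | None = None,
) -> tuple[list[TRNASpecies], KineticConstants]:
    """Random tRNA pool covering all 61 sense codons, plus kinetic constants.

    Codons of each amino acid are partitioned into isoacceptor groups; each
    species decodes one group and carries the Watson-Crick anticodon of its
    first codon, so near-cognate competition arises naturally from
    single-mismatch neighbours. With ``relative=True`` abundances are
    fractions summing to 1 (to exercise the rescaling path).
    """
    rng = np.random.default_rng(seed)
    by_aa: dict[str, list[str]] = {}
    for codon in SENSE_CODONS:
        by_aa.setdefault(translate_codon(codon), []).append(codon)

    pool: list[TRNASpecies] = []
    for aa, codons in sorted(by_aa.items()):
        codons = list(codons)
        rng.shuffle(codons)
        n_species = int(rng.integers(1, min(len(codons), 3) + 1))
        groups = np.array_split(codons, n_species)
        for gi, grp in enumerate(groups):
            grp = list(grp)
            pool.append(
                TRNASpecies(
                    id=f"tRNA-{aa}-{gi + 1}",
                    anticodon=wc_anticodon(grp[0]),
                    amino_acid=aa,
                    decoded_codons=frozenset(grp),
                    abundance=float(rng.lognormal(np.log(2000.0), 0.8)),
                    diffusion_coeff=float(_DIFFUSION_MEAN * rng.uniform(0.7, 1.3)),
                    size=float(_SIZE_MEAN * rng.uniform(0.8, 1.2)),
                )
            )
    if relative:
        total = sum(sp.abundance for sp in pool)
        from dataclasses import replace
        pool = [replace(sp, abundance=sp.abundance / total) for sp in pool]
    return pool, constants if constants is not None else KineticConstants()


@dataclass(frozen=True)
class FixtureSpec:
    """Ground-truth design of a synthetic gene set.

    ``dispersion`` is the overdispersion of the count noise (gamma-Poisson;
    variance mu + dispersion*mu^2); 0 means exact noise-free counts.
    """

    n_genes: int = 50
    length_range: tuple[int, int] = (60, 400)   # codons
    codon_bias: float = 0.5                     # sd of per-codon log-usage weights
    density_range: tuple[float, float] = (0.5, 8.0)   # g, ribosomes/100 codons
    lifetime_range: tuple[float, float] = (300.0, 3000.0)  # s
    n_replicates: int = 2
    total_footprints: float = 1.0e6
    transcriptome_size: float = 50_000.0
    dispersion: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.density_range[1] > 10.0:
            raise GenerationError(
                "requested density exceeds the 10 ribosomes/100 codons packing "
                "limit for a 10-codon footprint"
            )
        if self.n_genes < 1 or self.length_range[0] < 1:
            raise GenerationError("need at least one gene of at least one codon")


def make_gene_set(
    spec: FixtureSpec, rate_table: CodonRateTable
) -> tuple[list[GeneRecord], list[TranslationParams], OrganismConstants]:
    """Generate gene records plus the exact ground-truth parameters behind them.

    The measurement tables are built by inverting the derivation chain: true
    densities g fix w = g*L/100, true E follows from the CDS and rate table,
    and footprint counts are allotted in proportion to each gene's ribosome
    allocation w*x. The returned organism constants are constructed so the
    generated genes account for the whole active ribosome pool and the whole
    transcriptome, which makes noise-free derivation an exact inverse.
    """
    rng = np.random.default_rng(spec.seed)
    codons = np.array(SENSE_CODONS)
    usage = np.exp(rng.normal(0.0, spec.codon_bias, size=len(codons)))
    usage /= usage.sum()
    taus = {c: rate_table.tau(c) for c in SENSE_CODONS}

    lengths = rng.integers(spec.length_range[0], spec.length_range[1] + 1, spec.n_genes)
    rel = rng.lognormal(0.0, 1.0, spec.n_genes)
    x = rel / rel.sum() * spec.transcriptome_size
    g = rng.uniform(*spec.density_range, spec.n_genes)
    m = rng.uniform(*spec.lifetime_range, spec.n_genes)

    cds_list, E, w = [], np.empty(spec.n_genes), np.empty(spec.n_genes)
    for i, L in enumerate(lengths):
        cds = tuple(rng.choice(codons, size=int(L), p=usage))
        cds_list.append(cds)
        E[i] = sum(taus[c] for c in cds)
        w[i] = g[i] * L / 100.0

    active_fraction = 0.85
    ribosomes_per_cell = float((w * x).sum() / active_fraction)
    constants = OrganismConstants(
        name="synthetic",
        transcriptome_size=spec.transcriptome_size,
        ribosomes_per_cell=ribosomes_per_cell,
        cell_volume=1e-18,
        total_trnas=71_000,
        temperature=37.0,
        active_fraction=active_fraction,
    )

    share = (w * x) / (w * x).sum()
    fp_total = share * spec.total_footprints
    records, truths = [], []
    for i in range(spec.n_genes):
        per_rep = fp_total[i] / spec.n_replicates
        if spec.dispersion > 0:
            lam = rng.gamma(1.0 / spec.dispersion, spec.dispersion * per_rep,
                            spec.n_replicates)
            counts = tuple(float(c) for c in rng.poisson(lam))
            mrna = float(rng.poisson(rng.gamma(1.0 / spec.dispersion,
                                               spec.dispersion * rel[i] * 1e4)))
        else:
            counts = (per_rep,) * spec.n_replicates
            mrna = float(rel[i])
        I = E[i] / w[i]
        records.append(
            GeneRecord(
                gene=f"g{i:04d}", cds=cds_list[i], footprint_counts=counts,
                mrna_measure=mrna, mrna_lifetime=float(m[i]),
            )
        )
        truths.append(
            TranslationParams(
                gene=f"g{i:04d}", L=int(lengths[i]), x=float(x[i]), w=float(w[i]),
                g=float(g[i]), E=float(E[i]), tau_mean=float(E[i] / lengths[i]),
                I=float(I), m=float(m[i]), b=float(m[i] / I),
            )
        )
    return records, truths, constants


def make_queuing_cds(
    rate_table: CodonRateTable, length: int = 60, slow_factor: float = 10.0
) -> tuple[tuple[str, ...], tuple[float, ...], float]:
    """A CDS plus dwell profile engineered to queue, and an I that triggers it.

    The profile carries one codon slowed ``slow_factor``-fold mid-sequence;
    initiating faster than ribosomes can clear the slow site guarantees a
    pile-up upstream of it.
    """
    base = min(rate_table.entries.values(), key=lambda ck: ck.tau)
    cds = (base.codon,) * length
    profile = [base.tau] * length
    k = length // 2
    profile[k] = base.tau * slow_factor
    interval = profile[k] / 2.0  # arrivals outpace the slow site
    return cds, tuple(profile), interval
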