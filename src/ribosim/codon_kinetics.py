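"""Mean codon elongation times from tRNA competition.

The elongation time of a sense codon is set by how long the ribosomal A
site waits for a productive cognate aa-tRNA while near- and non-cognate
species make unproductive binding attempts.  Each tRNA species arrives at
a diffusion-limited frequency

    f = kappa * D * s * N / V

(``D`` diffusion coefficient in m^2/s, ``s`` molecule size in m, ``N``
copies per cell, ``V`` cell volume in m^3; ``kappa`` is the collision-kernel
proportionality constant, 4*pi for the Smoluchowski encounter rate).  For a
codon the two competition measures are quotients of summed arrival
frequencies,

    c_near = sum f(near-cognates) / sum f(cognates)
    c_non  = sum f(non-cognates)  / sum f(cognates)

and the mean elongation time combines the cognate insertion time ``tau1``
with the per-attempt delays ``tau2`` (near-cognate) and ``tau3``
(non-cognate):

    tau = tau1 + c_near * tau2 + c_non * tau3

Cognate status is carried entirely by decoding-specificity tables; a
near-cognate is a *non-decoding* species whose anticodon pairs the codon
with exactly one non-Watson-Crick pair, located at codon position 2 or 3.
A species listed as decoding a codon is cognate even when it pairs that
codon with a wobble (3rd-position) mismatch, and is then excluded from the
near-cognate set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

from .errors import (
    DegenerateCodonError,
    InvalidInputError,
    TableConstructionError,
)
from .genetics import (
    SENSE_CODONS,
    mismatch_positions,
    normalize_codon,
    require_sense_codon,
    validate_anticodon,
)

#: Proportionality constant of the diffusion collision kernel (Smoluchowski).
SMOLUCHOWSKI_KERNEL: float = 4.0 * math.pi


@dataclass(frozen=True)
class TRNASpecies:
    """One tRNA isoacceptor.

    Parameters
    ----------
    id : str
        Species label (e.g. ``tRNA-Ala-AGC``).
    anticodon : str
        RNA 3-mer read 5'->3'.
    amino_acid : str
        One-letter code, or ``"Sec"`` for selenocysteine.
    decoded_codons : frozenset of str
        Codons this species decodes according to the specificity table.
    abundance : float
        Molecules per cell (absolute count, or a relative fraction to be
        rescaled at table-build time).
    diffusion_coeff : float or None
        m^2/s. ``None`` allowed only for the Sec species (the Cys value is
        substituted at table-build time).
    size : float
        Molecule size in m.
    """

    id: str
    anticodon: str
    amino_acid: str
    decoded_codons: frozenset[str]
    abundance: float
    diffusion_coeff: float | None
    size: float

    def __post_init__(self):
        object.__setattr__(self, "anticodon", validate_anticodon(self.anticodon))
        object.__setattr__(
            self,
            "decoded_codons",
            frozenset(require_sense_codon(c) for c in self.decoded_codons),
        )
        if self.abundance < 0:
            raise InvalidInputError(f"{self.id}: abundance must be >= 0")
        if self.size < 0:
            raise InvalidInputError(f"{self.id}: size must be >= 0")
        if self.diffusion_coeff is not None and self.diffusion_coeff < 0:
            raise InvalidInputError(f"{self.id}: diffusion_coeff must be >= 0")


@dataclass(frozen=True)
class KineticConstants:
    """Kinetic constants of the elongation-time combination.

    ``tau_cognate`` (tau1) is the mean time to insert an amino acid from a
    cognate aa-tRNA, either one global value or a per-codon mapping;
    ``delay_near`` (tau2) and ``delay_non`` (tau3) are the mean delays per
    competition unit caused by near- and non-cognate binding attempts.

    The packaged defaults are synthetic placeholders of plausible magnitude
    (tens of ms cognate insertion, ms-scale delays); organism-calibrated
    values are supplied as configuration.
    """

    tau_cognate: float | Mapping[str, float] = 0.05
    delay_near: float = 0.005
    delay_non: float = 0.0005
    temperature: float = 37.0

    def __post_init__(self):
        taus = (
            [self.tau_cognate]
            if isinstance(self.tau_cognate, (int, float))
            else list(self.tau_cognate.values())
        )
        if any(t <= 0 for t in taus) or self.delay_near <= 0 or self.delay_non <= 0:
            raise InvalidInputError("all kinetic times must be > 0")

    def tau1(self, codon: str) -> float:
        if isinstance(self.tau_cognate, (int, float)):
            return float(self.tau_cognate)
        return float(self.tau_cognate[normalize_codon(codon)])


@dataclass(frozen=True)
class CodonKinetics:
    """Classified competition state and mean elongation time of one codon."""

    codon: str
    tau: float
    c_near: float
    c_non: float
    cognates: frozenset[str]
    near_cognates: frozenset[str]
    non_cognates: frozenset[str]


@dataclass
class CodonRateTable:
    """Per-codon mean elongation times for the 61 sense codons."""

    entries: dict[str, CodonKinetics]
    organism: str = "custom"
    provenance: str = "computed"

    def __post_init__(self):
        missing = set(SENSE_CODONS) - set(self.entries)
        if missing:
            raise TableConstructionError(
                f"rate table missing sense codons: {sorted(missing)}"
            )
        extra = set(self.entries) - set(SENSE_CODONS)
        if extra:
            raise TableConstructionError(f"non-sense codons in table: {sorted(extra)}")
        for ck in self.entries.values():
            if not math.isfinite(ck.tau) or ck.tau <= 0:
                raise TableConstructionError(f"non-positive tau for {ck.codon}")

    def tau(self, codon: str) -> float:
        return self.entries[require_sense_codon(codon)].tau

    def tau_profile(self, codons: Iterable[str]) -> list[float]:
        """Dwell-time profile (s per codon) for a codon sequence."""
        return [self.tau(c) for c in codons]


def classify_trnas(
    codon: str, pool: Iterable[TRNASpecies]
) -> tuple[frozenset[str], frozenset[str], frozenset[str]]:
    """Partition a tRNA pool into (cognate, near-cognate, non-cognate) id sets.

    Cognate: listed as decoding the codon. Near-cognate: non-decoding with a
    single strict-WC mismatch at codon position 2 or 3. Non-cognate: the rest.
    """
    c = require_sense_codon(codon)
    cognate, near, non = set(), set(), set()
    for sp in pool:
        if c in sp.decoded_codons:
            cognate.add(sp.id)
            continue
        mm = mismatch_positions(c, sp.anticodon)
        if len(mm) == 1 and mm[0] in (2, 3):
            near.add(sp.id)
        else:
            non.add(sp.id)
    return frozenset(cognate), frozenset(near), frozenset(non)


def arrival_frequency(
    species: TRNASpecies,
    cell_volume: float,
    kernel_const: float = SMOLUCHOWSKI_KERNEL,
) -> float:
    """Diffusion-limited arrival frequency (events/s) of one species at the A site."""
    if cell_volume <= 0:
        raise InvalidInputError(f"cell_volume must be > 0, got {cell_volume}")
    if species.diffusion_coeff is None:
        raise InvalidInputError(
            f"{species.id}: diffusion coefficient unresolved (Sec substitution "
            "happens at table-build time)"
        )
    return kernel_const * species.diffusion_coeff * species.size * species.abundance / cell_volume


def competition_measures(
    codon: str,
    pool: Iterable[TRNASpecies],
    cell_volume: float,
    kernel_const: float = SMOLUCHOWSKI_KERNEL,
) -> tuple[float, float]:
    """(c_near, c_non) for a codon: class arrival-frequency sums over the cognate sum."""
    pool = list(pool)
    cognate, near, non = classify_trnas(codon, pool)
    by_id = {sp.id: sp for sp in pool}

    def class_sum(ids: frozenset[str]) -> float:
        return sum(arrival_frequency(by_id[i], cell_volume, kernel_const) for i in ids)

    f_cog = class_sum(cognate)
    if f_cog <= 0.0:
        raise DegenerateCodonError(
            f"codon {codon}: zero total cognate arrival frequency"
        )
    return class_sum(near) / f_cog, class_sum(non) / f_cog


def codon_elongation_time(
    codon: str,
    pool: Iterable[TRNASpecies],
    constants: KineticConstants,
    cell_volume: float,
    kernel_const: float = SMOLUCHOWSKI_KERNEL,
) -> float:
    """Mean elongation time (s) of one codon: tau1 + c_near*tau2 + c_non*tau3."""
    c_near, c_non = competition_measures(codon, pool, cell_volume, kernel_const)
    return constants.tau1(codon) + c_near * constants.delay_near + c_non * constants.delay_non


def _resolve_sec_diffusion(pool: list[TRNASpecies]) -> list[TRNASpecies]:
    # The Sec isoacceptor borrows the Cys diffusion coefficient when its own
    # is absent (tRNA size varies little with the accepted amino acid).
    cys_d = next(
        (sp.diffusion_coeff for sp in pool
         if sp.amino_acid == "C" and sp.diffusion_coeff is not None),
        None,
    )
    out = []
    for sp in pool:
        if sp.diffusion_coeff is None:
            if sp.amino_acid not in ("Sec", "U") or cys_d is None:
                raise TableConstructionError(
                    f"{sp.id}: missing diffusion coefficient and no Cys fallback"
                )
            sp = replace(sp, diffusion_coeff=cys_d)
        out.append(sp)
    return out


def build_rate_table(
    pool: Iterable[TRNASpecies],
    constants: KineticConstants,
    cell_volume: float,
    total_trnas: float | None = None,
    organism: str = "custom",
    kernel_const: float = SMOLUCHOWSKI_KERNEL,
) -> CodonRateTable:
    """Build the 61-codon rate table from a tRNA pool.

    If the pool abundances are relative (they sum to <= 1) and ``total_trnas``
    is given, they are rescaled to sum to the cell-wide tRNA count before the
    collision kernel is evaluated; absolute pools pass through unchanged.
    """
    pool = _resolve_sec_diffusion(list(pool))
    total_abund = sum(sp.abundance for sp in pool)
    if total_abund <= 0:
        raise TableConstructionError("pool has zero total abundance")
    if total_trnas is not None and total_abund <= 1.0 + 1e-9:
        scale = total_trnas / total_abund
        pool = [replace(sp, abundance=sp.abundance * scale) for sp in pool]

    entries: dict[str, CodonKinetics] = {}
    for codon in SENSE_CODONS:
        cognate, near, non = classify_trnas(codon, pool)
        try:
            c_near, c_non = competition_measures(codon, pool, cell_volume, kernel_const)
        except DegenerateCodonError as exc:
            raise TableConstructionError(
                f"cannot build table: codon {codon} has no cognate with "
                "positive abundance"
            ) from exc
        tau = constants.tau1(codon) + c_near * constants.delay_near + c_non * constants.delay_non
        entries[codon] = CodonKinetics(
            codon=codon, tau=tau, c_near=c_near, c_non=c_non,
            cognates=cognate, near_cognates=near, non_cognates=non,
        )
    return CodonRateTable(entries=entries, organism=organism)
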