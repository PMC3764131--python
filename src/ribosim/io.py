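"""Readers and writers for the interchange formats, plus packaged organism constants.

TSV dialect: tab-separated, ``#``-prefixed metadata lines above a plain
column-header row, ``.`` for missing values. Writers are deterministic
(no timestamps), so every writer/reader pair round-trips byte-exactly on
its own output.
"""

from __future__ import annotations

import io as _io
import logging
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codon_kinetics import CodonKinetics, CodonRateTable, KineticConstants, TRNASpecies
from .errors import ConfigurationError, InvalidCDSError
from .genetics import STOP_CODONS, codons_of
from .parameters import GeneRecord, OrganismConstants

logger = logging.getLogger("ribosim")

MISSING = "."

#: Packaged cell-wide constant sets (volumes in m^3, temperatures in deg C).
ORGANISMS: dict[str, dict] = {
    "ecoli": dict(transcriptome_size=1_500, ribosomes_per_cell=20_000,
                  cell_volume=1e-18, total_trnas=71_000, temperature=37.0),
    "yeast": dict(transcriptome_size=36_000, ribosomes_per_cell=200_000,
                  cell_volume=42e-18, total_trnas=2_800_000, temperature=30.0),
    "human": dict(transcriptome_size=700_000, ribosomes_per_cell=9_500_000,
                  cell_volume=2425e-18, total_trnas=60_000_000, temperature=37.0),
}


def load_organism_constants(
    name: str, config_path: str | Path | None = None, **overrides
) -> OrganismConstants:
    """Constants for a packaged organism, optionally overridden from a YAML file.

    A config file may name a packaged ``base`` organism; any field it does
    not set is inherited from that base.
    """
    fields: dict = {}
    if name in ORGANISMS:
        fields.update(ORGANISMS[name])
        fields["name"] = name
    elif config_path is None:
        raise ConfigurationError(
            f"unknown organism {name!r} and no config file supplied "
            f"(packaged: {sorted(ORGANISMS)})"
        )
    if config_path is not None:
        with open(config_path) as fh:
            cfg = yaml.safe_load(fh) or {}
        base = cfg.pop("base", None)
        if base is not None:
            if base not in ORGANISMS:
                raise ConfigurationError(f"unknown base organism {base!r}")
            fields.update(ORGANISMS[base])
        fields.setdefault("name", name)
        fields.update(cfg)
    fields.update(overrides)
    try:
        return OrganismConstants(**fields)
    except TypeError as exc:
        raise ConfigurationError(f"bad organism config: {exc}") from exc


# ---------------------------------------------------------------------------
# FASTA

def read_cds_fasta(path: str | Path) -> list[tuple[str, list[str]]]:
    """Read coding sequences; returns (id, codon list) pairs.

    U is normalized to T; a trailing stop codon is stripped with a logged
    notice. Records with a length not divisible by 3, ambiguity codes, or
    internal stop codons raise a named error identifying the record.
    """
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        if len(seq) % 3:
            raise InvalidCDSError(f"{rec.id}: length {len(seq)} not divisible by 3")
        if any(b not in "ACGT" for b in seq):
            raise InvalidCDSError(f"{rec.id}: ambiguity codes in sequence")
        codons = codons_of(seq)
        if codons and codons[-1] in STOP_CODONS:
            logger.info("%s: stripped trailing stop codon %s", rec.id, codons[-1])
            codons = codons[:-1]
        for i, c in enumerate(codons, start=1):
            if c in STOP_CODONS:
                raise InvalidCDSError(f"{rec.id}: internal stop codon {c} at codon {i}")
        if not codons:
            raise InvalidCDSError(f"{rec.id}: empty CDS after stop stripping")
        out.append((rec.id, codons))
    return out


def write_cds_fasta(path: str | Path, records: Iterable[tuple[str, Sequence[str]]]) -> None:
    seqs = [
        SeqRecord(Seq("".join(codons)), id=gene, description="")
        for gene, codons in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


# ---------------------------------------------------------------------------
# TSV helpers

def _write_tsv(path: str | Path, df: pd.DataFrame, header_lines: Sequence[str]) -> None:
    buf = _io.StringIO()
    for line in header_lines:
        buf.write(f"# {line}\n")
    df.to_csv(buf, sep="\t", index=False, na_rep=MISSING)
    Path(path).write_text(buf.getvalue())


def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=[MISSING],
                       float_precision="round_trip")


# ---------------------------------------------------------------------------
# tRNA pools

def write_trna_pool(path: str | Path, pool: Iterable[TRNASpecies]) -> None:
    df = pd.DataFrame(
        [
            dict(
                id=sp.id, anticodon=sp.anticodon, amino_acid=sp.amino_acid,
                decoded_codons=",".join(sorted(sp.decoded_codons)),
                abundance=sp.abundance, diffusion_coeff=sp.diffusion_coeff,
                size=sp.size,
            )
            for sp in pool
        ]
    )
    _write_tsv(path, df, ["ribosim tRNA pool"])


def read_trna_pool(path: str | Path) -> list[TRNASpecies]:
    df = _read_tsv(path)
    pool = []
    for row in df.itertuples(index=False):
        d = row.diffusion_coeff
        pool.append(
            TRNASpecies(
                id=str(row.id), anticodon=str(row.anticodon),
                amino_acid=str(row.amino_acid),
                decoded_codons=frozenset(str(row.decoded_codons).split(",")),
                abundance=float(row.abundance),
                diffusion_coeff=None if pd.isna(d) else float(d),
                size=float(row.size),
            )
        )
    return pool


# ---------------------------------------------------------------------------
# codon rate tables (the downloadable flat-file format)

def write_rate_table(path: str | Path, table: CodonRateTable) -> None:
    df = pd.DataFrame(
        [
            dict(codon=ck.codon, tau_s=ck.tau, c_near=ck.c_near, c_non=ck.c_non)
            for ck in sorted(table.entries.values(), key=lambda c: c.codon)
        ]
    )
    _write_tsv(path, df, [f"ribosim codon rate table", f"organism: {table.organism}"])


def read_rate_table(path: str | Path, organism: str | None = None) -> CodonRateTable:
    df = _read_tsv(path)
    if organism is None:
        organism = "custom"
        for line in Path(path).read_text().splitlines():
            if line.startswith("# organism:"):
                organism = line.split(":", 1)[1].strip()
                break
    empty = frozenset()
    entries = {
        str(r.codon): CodonKinetics(
            codon=str(r.codon), tau=float(r.tau_s),
            c_near=float(r.c_near), c_non=float(r.c_non),
            cognates=empty, near_cognates=empty, non_cognates=empty,
        )
        for r in df.itertuples(index=False)
    }
    return CodonRateTable(entries=entries, organism=organism, provenance="loaded")


# ---------------------------------------------------------------------------
# gene measurement tables

def write_gene_table(path: str | Path, records: Iterable[GeneRecord]) -> None:
    records = list(records)
    n_reps = max((len(r.footprint_counts) for r in records), default=1)
    rows = []
    for r in records:
        row = {"gene": r.gene}
        for i in range(n_reps):
            row[f"fp_rep{i + 1}"] = (
                r.footprint_counts[i] if i < len(r.footprint_counts) else None
            )
        row["mrna_rel"] = r.mrna_measure
        row["lifetime_s"] = r.mrna_lifetime
        rows.append(row)
    _write_tsv(path, pd.DataFrame(rows), ["ribosim gene measurements"])


def read_gene_table(
    path: str | Path, cds_by_gene: dict[str, Sequence[str]]
) -> list[GeneRecord]:
    """Join a measurement table with coding sequences into gene records."""
    df = _read_tsv(path)
    rep_cols = [c for c in df.columns if c.startswith("fp_rep")]
    out = []
    for row in df.itertuples(index=False):
        gene = str(row.gene)
        if gene not in cds_by_gene:
            raise InvalidCDSError(f"{gene}: no coding sequence supplied")
        counts = tuple(
            float(getattr(row, c)) for c in rep_cols if not pd.isna(getattr(row, c))
        )
        lt = row.lifetime_s
        out.append(
            GeneRecord(
                gene=gene, cds=tuple(cds_by_gene[gene]), footprint_counts=counts,
                mrna_measure=float(row.mrna_rel),
                mrna_lifetime=None if pd.isna(lt) else float(lt),
            )
        )
    return out


# ---------------------------------------------------------------------------
# kinetic constants

def read_kinetic_constants(path: str | Path) -> KineticConstants:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return KineticConstants(**cfg)
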