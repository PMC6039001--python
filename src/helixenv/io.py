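"""Readers and writers for the plain-text formats the pipeline uses.

Canonical table dialect: tab-separated, UTF-8, '.' decimal point.  The
DSSP writer exists so that synthetic chains can be round-tripped through
the DSSP parser in tests and demos.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from helixenv._errors import InputError
from helixenv.types import HELIX_CODE, ChainRecord


# -- FASTA -----------------------------------------------------------------

def write_fasta(records: Iterable[ChainRecord], path: str | Path) -> None:
    seqs = [SeqRecord(Seq(r.sequence), id=r.chain_id, description="")
            for r in records]
    SeqIO.write(seqs, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# -- annotation TSV (chain_id, assigner, annotation) -----------------------

def write_annotations(records: Iterable[ChainRecord], path: str | Path,
                      ) -> None:
    rows = [{"chain_id": r.chain_id, "assigner": role, "annotation": ann}
            for r in records for role, ann in sorted(r.annotations.items())]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_annotations(path: str | Path) -> dict[str, dict[str, str]]:
    table = pd.read_csv(path, sep="\t", dtype=str)
    needed = {"chain_id", "assigner", "annotation"}
    if not needed <= set(table.columns):
        raise InputError(f"annotation TSV needs columns {sorted(needed)}")
    out: dict[str, dict[str, str]] = {}
    for row in table.itertuples(index=False):
        out.setdefault(row.chain_id, {})[row.assigner] = row.annotation
    return out


def load_chain_records(fasta_path: str | Path, annotations_path: str | Path,
                       class_label: str = "all-alpha") -> list[ChainRecord]:
    sequences = read_fasta(fasta_path)
    annotations = read_annotations(annotations_path)
    records = []
    for chain_id, seq in sequences.items():
        records.append(ChainRecord(
            chain_id=chain_id, sequence=seq,
            annotations=annotations.get(chain_id, {}),
            class_label=class_label))
    return records


# -- descriptor TSV --------------------------------------------------------

def write_descriptor_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_descriptor_table(path: str | Path) -> pd.DataFrame:
    """Read a per-residue descriptor table.

    Requires chain_id and residue_index columns; rejects duplicate
    (chain, residue) pairs and non-numeric descriptor cells with the
    offending location.  Missing cells stay missing (NaN), never zero.
    """
    table = pd.read_csv(path, sep="\t")
    needed = {"chain_id", "residue_index"}
    if not needed <= set(table.columns):
        raise InputError(f"descriptor table needs columns {sorted(needed)}")
    dup = table.duplicated(subset=["chain_id", "residue_index"])
    if dup.any():
        row = table[dup].iloc[0]
        raise InputError(
            f"duplicate descriptor row for chain {row['chain_id']!r} "
            f"residue {row['residue_index']}")
    for col in table.columns:
        if col in ("chain_id", "residue_index"):
            continue
        coerced = pd.to_numeric(table[col], errors="coerce")
        bad = coerced.isna() & table[col].notna()
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise InputError(
                f"non-numeric value {table[col].iloc[i]!r} in column "
                f"{col!r}, row {i + 2} of {path}")
        table[col] = coerced
    return table


# -- DSSP ------------------------------------------------------------------

_DSSP_HEADER = (
    "==== Secondary Structure Definition, synthetic fixture ====\n"
    "REFERENCE    .\n"
    "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC\n")


def format_dssp(chains: Sequence[tuple[str, str, str]]) -> str:
    """Render (chain_id, sequence, annotation) triples as DSSP-style text.

    Only the columns the parser consumes are populated; chains are
    separated by '!*' terminator records as in real DSSP output.
    """
    lines = [_DSSP_HEADER.rstrip("\n")]
    serial = 0
    for c, (chain_id, seq, ann) in enumerate(chains):
        if len(seq) != len(ann):
            raise InputError(
                f"chain {chain_id!r}: sequence/annotation length mismatch")
        if len(chain_id) != 1:
            raise InputError("DSSP chain ids are single characters")
        for i, (aa, code) in enumerate(zip(seq, ann)):
            serial += 1
            ss = "H" if code == HELIX_CODE else " "
            lines.append(f"{serial:5d}{i + 1:5d} {chain_id} {aa}  {ss}")
        if c < len(chains) - 1:
            serial += 1
            lines.append(f"{serial:5d}      ! !*")
    return "\n".join(lines) + "\n"


# -- manifest --------------------------------------------------------------

def sha256_of(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(outdir: str | Path, config: Mapping,
                   files: Sequence[str | Path]) -> Path:
    """Record the run configuration and a checksum for every output file."""
    outdir = Path(outdir)
    config_json = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "config": json.loads(config_json),
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "files": {str(Path(f).relative_to(outdir)): sha256_of(f)
                  for f in files},
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
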