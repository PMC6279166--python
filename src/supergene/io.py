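"""File formats: codon-trio FASTA, BED-like gene tables, Ct panels, JSON.

All tabular formats are plain TSV with headers and 1-based inclusive
coordinates; FASTA records of a trio encode their role with the id suffixes
``_hapA``, ``_hapB`` and ``_outgroup``.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .dnds import CodonTrioAlignment

ROLE_SUFFIXES = {"_hapA": "seq_a", "_hapB": "seq_b", "_outgroup": "seq_out"}


def write_trio_fasta(trio: CodonTrioAlignment, path) -> None:
    records = [
        SeqRecord(Seq(trio.seq_a), id=f"{trio.gene_id}_hapA", description=""),
        SeqRecord(Seq(trio.seq_b), id=f"{trio.gene_id}_hapB", description=""),
        SeqRecord(Seq(trio.seq_out), id=f"{trio.gene_id}_outgroup", description=""),
    ]
    SeqIO.write(records, str(path), "fasta")


def read_trio_fasta(path) -> CodonTrioAlignment:
    """Read one gene's trio; roles are taken from the record-id suffixes."""
    found: dict[str, str] = {}
    gene_id = None
    for rec in SeqIO.parse(str(path), "fasta"):
        for suffix, attr in ROLE_SUFFIXES.items():
            if rec.id.endswith(suffix):
                found[attr] = str(rec.seq).upper()
                gene_id = rec.id[: -len(suffix)]
                break
        else:
            raise ValueError(f"{path}: record {rec.id!r} has no role suffix "
                             f"({', '.join(ROLE_SUFFIXES)})")
    missing = set(ROLE_SUFFIXES.values()) - set(found)
    if missing:
        raise ValueError(f"{path}: missing records for {sorted(missing)}")
    return CodonTrioAlignment(gene_id=gene_id, **found)


def write_trio_dir(trios: Iterable[CodonTrioAlignment], directory) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for trio in trios:
        p = directory / f"{trio.gene_id}.fasta"
        write_trio_fasta(trio, p)
        paths.append(p)
    return paths


def read_trio_dir(directory) -> list[CodonTrioAlignment]:
    return [read_trio_fasta(p) for p in sorted(Path(directory).glob("*.fasta"))]


def write_tsv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_gene_table(path) -> pd.DataFrame:
    """BED-like gene table: scaffold, start, end, strand, gene_id, sample_id, haplotype."""
    table = pd.read_csv(path, sep="\t")
    required = {"scaffold", "start", "end", "strand", "gene_id", "sample_id"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return table


def read_ct_panel(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_jsonify)
        fh.write("\n")


def _jsonify(x):
    try:
        return x.item()  # numpy scalars
    except AttributeError:
        raise TypeError(f"not JSON serializable: {type(x)}")


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
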