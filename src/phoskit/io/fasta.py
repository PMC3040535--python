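"""FASTA reading and writing (Biopython-backed)."""

from __future__ import annotations

import os
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ..core import Protein
from ..errors import FormatError


def read_fasta(path: str | os.PathLike) -> list[Protein]:
    """Read proteins from FASTA.

    The accession is the first whitespace-delimited header token; the rest of
    the header, if any, becomes the protein name. Sequences are uppercased.
    """
    proteins = []
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        if not seq:
            raise FormatError(f"FASTA record {record.description!r} has an empty sequence")
        desc = record.description
        name = desc.split(None, 1)[1] if len(desc.split(None, 1)) > 1 else None
        proteins.append(Protein(accession=record.id, sequence=seq, name=name))
    return proteins


def write_fasta(proteins: Iterable[Protein], path: str | os.PathLike) -> None:
    """Write proteins as FASTA with 60-column sequence wrapping."""
    records = [
        SeqRecord(Seq(p.sequence), id=p.accession, description=p.name or "")
        for p in proteins
    ]
    SeqIO.write(records, str(path), "fasta")
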