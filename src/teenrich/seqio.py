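"""FASTA genome I/O and small sequence utilities.

A genome is represented in memory as a plain ``dict`` mapping chromosome
name to an uppercase DNA string (alphabet A,C,G,T,N); insertion order is the
canonical chromosome order.  Reading and writing go through Bio.SeqIO.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import GenomeLayout

__all__ = [
    "read_fasta",
    "write_fasta",
    "layout_from_genome",
    "revcomp",
    "encode",
    "decode",
]

ALPHABET = "ACGT"
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMP = str.maketrans("ACGTN", "TGCAN")
N_CODE = 4


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into {name: uppercase sequence}."""
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        genome[rec.id] = str(rec.seq).upper()
    if not genome:
        raise ValueError(f"no sequences found in {path}")
    return genome


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 70) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
    del width  # Bio.SeqIO wraps at 60 columns; kept for signature stability


def layout_from_genome(genome: dict[str, str]) -> GenomeLayout:
    return GenomeLayout(tuple(genome), {c: len(s) for c, s in genome.items()})


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode A,C,G,T,N as 0..4 (int8). Unknown letters raise."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    lut = np.full(256, -1, dtype=np.int8)
    for ch, code in _CODE.items():
        lut[ord(ch)] = code
    out = lut[arr]
    if (out < 0).any():
        bad = sorted({chr(b) for b in arr[out < 0]})
        raise ValueError(f"non-ACGTN letters in sequence: {bad}")
    return out


def decode(codes: np.ndarray) -> str:
    return "".join("ACGTN"[c] for c in codes)
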