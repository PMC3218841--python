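"""Small DNA sequence helpers shared across the pipeline."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")

#: integer encoding used by the folding and target-scanning kernels
#: A=0, C=1, G=2, T/U=3, anything else (N, gaps) = 4
BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA/RNA string (result uses DNA letters)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as uint8 codes (unknown letters map to 4)."""
    return np.fromiter((BASE_CODE.get(c, 4) for c in seq.upper()), dtype=np.uint8,
                       count=len(seq))


def random_seq(rng: np.random.Generator, n: int) -> str:
    """Uniform random DNA string of length ``n``."""
    return "".join(rng.choice(list("ACGT"), size=n))


def read_fasta(path) -> dict[str, str]:
    """Load a FASTA file into an ordered ``{id: upper-case sequence}`` dict."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, records: dict[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
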