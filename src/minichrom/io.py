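"""Plain-text writers (FASTA/BED/BEDGRAPH/TSV) with provenance headers.

Every output embeds the tool version, the seed and a hash of the governing
parameters in a leading comment, plus the model's coordinate scale where
relevant, so that any file can be traced back to the run that made it.
"""
from __future__ import annotations

import numpy as np

from ._util import header_lines


def write_fasta(path, sequences: dict[str, str], width: int = 80,
                seed=0, params: dict | None = None) -> None:
    with open(path, "w") as fh:
        for line in header_lines(seed, params, prefix=";"):
            fh.write(line + "\n")
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_bed(path, rows, seed=0, params: dict | None = None) -> None:
    """rows: iterables of (contig, start, end, name, *extra)."""
    with open(path, "w") as fh:
        for line in header_lines(seed, params):
            fh.write(line + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def write_bedgraph(path, contig: str, values: np.ndarray, bin_size: int,
                   seed=0, params: dict | None = None) -> None:
    with open(path, "w") as fh:
        for line in header_lines(seed, params):
            fh.write(line + "\n")
        for i, v in enumerate(values):
            fh.write(f"{contig}\t{i * bin_size}\t{(i + 1) * bin_size}\t{v:.6g}\n")


def write_tsv(path, columns: list[str], rows, seed=0, params: dict | None = None) -> None:
    with open(path, "w") as fh:
        for line in header_lines(seed, params):
            fh.write(line + "\n")
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
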