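"""Plain-text interchange: TSV tables and paired-FASTA alignments."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .compat import PairwiseAlignment


def write_tsv(frame: pd.DataFrame, path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=index)


def read_tsv(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_matrix(matrix: pd.DataFrame, path) -> None:
    """Expression matrix TSV: probeset_id + one column per sample."""
    write_tsv(matrix, path, index=True)


def read_matrix(path) -> pd.DataFrame:
    return read_tsv(path, index_col="probeset_id")


def write_paired_fasta(alignments: pd.DataFrame, path) -> None:
    """Aligned ortholog pairs as gapped FASTA, two records per probe-set.

    Headers carry the probe-set id, the species tag (a/b) and the source
    start offset of the alignment.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for row in alignments.itertuples(index=False):
            fh.write(f">{row.probeset_id}|a|start={row.a_start}\n{row.aligned_a}\n")
            fh.write(f">{row.probeset_id}|b\n{row.aligned_b}\n")


def read_paired_fasta(path) -> dict[str, PairwiseAlignment]:
    """Read alignments written by :func:`write_paired_fasta`."""
    records: dict[str, dict] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                fields = line[1:].split("|")
                ps_id, tag = fields[0], fields[1]
                entry = records.setdefault(ps_id, {"a_start": 0})
                if tag == "a" and len(fields) > 2:
                    entry["a_start"] = int(fields[2].split("=")[1])
                name = (ps_id, tag)
            else:
                records[name[0]][name[1]] = records[name[0]].get(name[1], "") + line
    return {
        ps_id: PairwiseAlignment(entry["a"], entry["b"], entry["a_start"])
        for ps_id, entry in records.items()
    }
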