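"""File helpers: .smi lists, FASTA sequences, array bundles."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_smi(path: str | Path) -> list[str]:
    """One SMILES per line; trailing whitespace/name fields after a tab are dropped."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        out.append(line.split()[0])
    return out


def write_smi(path: str | Path, smiles: list[str]) -> None:
    Path(path).write_text("".join(s + "\n" for s in smiles))


def read_fasta(path: str | Path) -> dict[str, str]:
    """id -> sequence, preserving file order. Raises on duplicate ids."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA id: {rec.id}")
        out[rec.id] = str(rec.seq)
    return out


def write_fasta(path: str | Path, sequences: dict[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=k, description="") for k, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def write_json(path: str | Path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def write_array_bundle(prefix: str | Path, array: np.ndarray, ids: list[str]) -> None:
    """Array as .npy next to a TSV index mapping id -> row."""
    prefix = Path(prefix)
    np.save(str(prefix) + ".npy", array)
    pd.DataFrame({"id": ids, "row": range(len(ids))}).to_csv(
        str(prefix) + ".tsv", sep="\t", index=False)


def read_array_bundle(prefix: str | Path) -> tuple[np.ndarray, list[str]]:
    prefix = Path(prefix)
    arr = np.load(str(prefix) + ".npy")
    idx = pd.read_csv(str(prefix) + ".tsv", sep="\t")
    return arr, idx["id"].astype(str).tolist()
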