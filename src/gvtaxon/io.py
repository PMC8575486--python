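"""Shared I/O: FASTA, Newick (single and multi-tree), TSV tables, JSON, seeds.

All readers/writers round-trip their payloads exactly: FASTA preserves id,
description and sequence; Newick preserves topology, branch lengths (to 10
significant digits) and labels, including polytomies; tables are
tab-separated with a header line.  Coordinates in internal tables are
0-based half-open; conversion to external 1-based inclusive conventions
happens only at the writer for those formats (see :mod:`gvtaxon.markers`).
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class DuplicateIdError(ValueError):
    """Raised when a FASTA file contains two records with the same id."""


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` mapping."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise DuplicateIdError(f"duplicate sequence id {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq)
    return records


def write_fasta(records: Mapping[str, str], path: str | Path) -> None:
    seqs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    with open(path, "w") as fh:
        SeqIO.write(seqs, fh, "fasta-2line")


# ---------------------------------------------------------------------------
# Newick


def read_newick(path: str | Path) -> dendropy.Tree:
    tree = dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)
    return tree


_NEWICK_WRITE_KWARGS = dict(
    schema="newick",
    # labels with spaces stay quoted; underscores stay unquoted and are
    # read back verbatim via preserve_underscores
    preserve_spaces=True,
    unquoted_underscores=True,
    real_value_format_specifier=".10g",
)


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), **_NEWICK_WRITE_KWARGS)


def read_tree_list(path: str | Path) -> list[dendropy.Tree]:
    """Read a multi-tree Newick file (one tree per line)."""
    trees = dendropy.TreeList.get(path=str(path), schema="newick",
                                  preserve_underscores=True)
    return list(trees)


def write_tree_list(trees: Iterable[dendropy.Tree], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in trees:
            fh.write(t.as_string(**_NEWICK_WRITE_KWARGS).strip())
            fh.write("\n")


def tree_from_string(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)


def tree_to_string(tree: dendropy.Tree) -> str:
    return tree.as_string(**_NEWICK_WRITE_KWARGS).strip()


# ---------------------------------------------------------------------------
# Tables / JSON


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# Seeds and digests


def derive_seed(master_seed: int, stage: str) -> int:
    """Derive a per-stage seed from a single global seed.

    The derivation hashes ``"{master_seed}:{stage}"`` so that adding or
    removing stages never perturbs the seeds of the others, and the result
    always fits in a 31-bit nonnegative integer.
    """
    h = hashlib.blake2b(f"{master_seed}:{stage}".encode(), digest_size=8)
    return int.from_bytes(h.digest(), "big") % (2 ** 31)


def file_digest(path: str | Path) -> str:
    """SHA-256 content digest, used for run-manifest provenance."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def string_digest(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()
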