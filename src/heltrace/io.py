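"""Readers and writers for the standard formats the pipeline speaks.

FASTA goes through Biopython, trees through dendropy.  GFF3 output is 1-based
closed per the standard; everything in memory is 0-based half-open, and the
conversion lives here and nowhere else.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

from .records import SequenceRecord

FASTA_WIDTH = 60


# ---------------------------------------------------------------- FASTA

def read_fasta(path: str | Path) -> list[SequenceRecord]:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        taxon = region = None
        for token in rec.description.split()[1:]:
            if token.startswith("taxon="):
                taxon = token[6:]
            elif token.startswith("region="):
                region = token[7:]
        records.append(SequenceRecord(rec.id, str(rec.seq).upper(), taxon, region))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = []
    for r in records:
        desc = []
        if r.taxon:
            desc.append(f"taxon={r.taxon}")
        if r.region:
            desc.append(f"region={r.region}")
        bio.append(_BioRecord(Seq(r.seq), id=r.id, description=" ".join(desc)))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=FASTA_WIDTH)
        writer.write_file(bio)


# ---------------------------------------------------------------- GFF3

def _gff3_attrs(attrs: dict) -> str:
    if not attrs:
        return "."
    return ";".join(f"{k}={v}" for k, v in attrs.items())


def write_gff3(
    features: Sequence[tuple],
    path: str | Path,
    *,
    source: str = "heltrace",
) -> None:
    """Write features as GFF3.

    Each feature is ``(seqid, ftype, start0, end0, strand, attrs)`` with
    0-based half-open coordinates; they are emitted 1-based closed.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for seqid, ftype, start, end, strand, attrs in features:
            fh.write(
                "\t".join(
                    [
                        seqid,
                        source,
                        ftype,
                        str(start + 1),
                        str(end),
                        ".",
                        strand or ".",
                        ".",
                        _gff3_attrs(attrs),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------- JSON truth

def write_truth_json(truth: Sequence, path: str | Path) -> None:
    """Truth records as JSON with 0-based half-open intervals."""
    payload = [
        {
            "feature_type": t.feature_type,
            "intervals": [list(iv) for iv in t.intervals],
            "attributes": t.attributes,
        }
        for t in truth
    ]
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


# ---------------------------------------------------------------- matrices

def write_matrix_tsv(matrix, path: str | Path) -> None:
    """Square taxon-labeled TSV for a :class:`heltrace.distance.DistanceMatrix`."""
    matrix.to_dataframe().to_csv(path, sep="\t", index_label="taxon")


def read_matrix_tsv(path: str | Path):
    import pandas as pd

    from .distance import DistanceMatrix

    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(list(df.columns), df.to_numpy(dtype=float))


# ---------------------------------------------------------------- trees

def read_newick(source: str | Path) -> dendropy.Tree:
    """Parse a newick tree from a path or a literal newick string."""
    text = None
    p = Path(str(source))
    if p.exists():
        text = p.read_text()
    else:
        text = str(source)
    return dendropy.Tree.get(data=text, schema="newick")


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    Path(path).write_text(tree.as_string(schema="newick"))
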