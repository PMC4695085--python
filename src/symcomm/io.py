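"""Readers and writers for the on-disk formats.

FASTA via Biopython, newick via scikit-bio, tables via pandas. All
writers round-trip through their readers.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from skbio import TreeNode

from .table import CountTable, validate_metadata
from .taxonomy import AmpliconRead, RefRecord, ReferenceDB, number_internal_nodes


def read_fasta(path) -> list[tuple[str, str]]:
    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records, path) -> None:
    seqs = [SeqRecord(Seq(s), id=name, description="") for name, s in records]
    SeqIO.write(seqs, str(path), "fasta-2line")


def write_reads_fasta(reads: list[AmpliconRead], path,
                      qual_path=None) -> None:
    """Reads as FASTA with the sample id in the header
    (``>read_id sample=<id>``); qualities, when present, as a TSV of
    read_id and space-separated Phred scores."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f">{r.read_id} sample={r.sample_id}\n{r.sequence}\n")
    if qual_path is not None:
        with open(qual_path, "w") as fh:
            for r in reads:
                if r.qualities is not None:
                    fh.write(f"{r.read_id}\t"
                             + " ".join(map(str, r.qualities)) + "\n")


def read_reads_fasta(path, qual_path=None) -> list[AmpliconRead]:
    quals = {}
    if qual_path is not None and Path(qual_path).exists():
        with open(qual_path) as fh:
            for line in fh:
                rid, qstr = line.rstrip("\n").split("\t")
                quals[rid] = tuple(int(q) for q in qstr.split())
    reads = []
    for rec in SeqIO.parse(str(path), "fasta"):
        sample = ""
        for token in rec.description.split():
            if token.startswith("sample="):
                sample = token[len("sample="):]
        reads.append(AmpliconRead(rec.id, str(rec.seq).upper(),
                                  qualities=quals.get(rec.id),
                                  sample_id=sample))
    if not reads:
        raise ValueError(f"no reads in {path}")
    return reads


def read_newick(path) -> TreeNode:
    tree = TreeNode.read(str(path), convert_underscores=False)
    return number_internal_nodes(tree)


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path))


def read_reference_db(fasta_path, taxonomy_path, trees_dir=None) -> ReferenceDB:
    """Reference DB from FASTA + 2-column taxonomy TSV (name, clade),
    with optional per-clade newick guide trees ``<clade>.nwk``."""
    seqs = dict(read_fasta(fasta_path))
    tax = pd.read_csv(taxonomy_path, sep="\t", header=None,
                      names=["name", "clade"], dtype=str)
    missing = sorted(set(tax["name"]) - set(seqs))
    if missing:
        raise ValueError(f"taxonomy names missing from FASTA: {missing}")
    records = [RefRecord(row["name"], row.clade, seqs[row["name"]])
               for _, row in tax.iterrows()]
    trees = {}
    if trees_dir is not None:
        for p in sorted(Path(trees_dir).glob("*.nwk")):
            trees[p.stem] = read_newick(p)
    return ReferenceDB(records, trees or None)


def write_reference_db(db: ReferenceDB, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta([(r.name, r.sequence) for r in db.records],
                outdir / "references.fasta")
    with open(outdir / "taxonomy.tsv", "w") as fh:
        for r in db.records:
            fh.write(f"{r.name}\t{r.clade}\n")
    trees_dir = outdir / "trees"
    trees_dir.mkdir(exist_ok=True)
    for clade in db.clades:
        write_newick(db.guide_tree(clade), trees_dir / f"{clade}.nwk")


def read_metadata(path) -> pd.DataFrame:
    md = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in md.columns:
        raise ValueError("metadata must have a sample_id column")
    return validate_metadata(md.set_index("sample_id"))


def write_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, sep="\t", index_label="sample_id")


def read_counts(counts_path, metadata_path) -> CountTable:
    counts = pd.read_csv(counts_path, index_col=0)
    counts.index = counts.index.astype(str)
    return CountTable(counts, read_metadata(metadata_path))


def write_counts(table: CountTable, counts_path, metadata_path=None) -> None:
    table.counts.to_csv(counts_path, index_label="sample_id")
    if metadata_path is not None:
        write_metadata(table.metadata, metadata_path)
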