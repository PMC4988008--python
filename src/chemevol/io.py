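"""Small text-format helpers (FASTA, newick files, TSV manifests)."""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO

from .trees import TreeNode, parse_newick, write_newick


def read_fasta(path) -> dict[str, str]:
    """FASTA file -> ordered {id: sequence} dict."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_tree(path) -> TreeNode:
    return parse_newick(Path(path).read_text())


def write_tree(tree: TreeNode, path) -> None:
    Path(path).write_text(write_newick(tree) + "\n")
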