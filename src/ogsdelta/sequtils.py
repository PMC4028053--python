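"""Small sequence helpers used across the package."""

from __future__ import annotations

from Bio.Seq import Seq

from .models import GeneModel

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


def revcomp(s: str) -> str:
    return str(Seq(s).reverse_complement())


def translate(cds: str) -> str:
    """Translate a CDS, dropping a trailing stop codon if present."""
    n = len(cds) - len(cds) % 3
    aa = str(Seq(cds[:n]).translate())
    return aa[:-1] if aa.endswith("*") else aa


def extract_cds(gene: GeneModel, scaffold_seq: str) -> str:
    """Spliced coding sequence of ``gene``, 5'->3' (reverse-complemented on '-')."""
    s = "".join(scaffold_seq[a:b] for a, b in gene.coding_exons)
    return revcomp(s) if gene.strand == "-" else s
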