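"""Core domain types for paired-chain single-cell TCR repertoires.

A *chain record* is one assembled TCR contig (one chain of one cell).  A
*cell* passes quality control when it carries exactly one TRA and one TRB
chain.  A *clone* is the set of cells sharing identical paired CDR3
nucleotide sequences (the clonotype key), and a *repertoire* is the set of
clones observed in one animal/sample together with its infection-group
label.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from ._errors import ValidationError

#: Loci handled by the pipeline; contigs from other loci are dropped on read.
TCR_LOCI = ("TRA", "TRB")

#: The 20 standard amino acids (one-letter codes).
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

EXPANDED = "expanded"
LOWLY_EXPANDED = "lowly_expanded"


@dataclass(frozen=True)
class ChainRecord:
    """One sequenced TCR chain contig for one cell barcode."""

    barcode: str
    sample_id: str
    locus: str  # "TRA" or "TRB"
    cdr3_nt: str
    cdr3_aa: str
    v_gene: str
    j_gene: str
    d_gene: str | None = None
    productive: bool = True
    is_cell_flag: bool = True
    high_confidence_flag: bool = True
    umis: int = 0

    def __post_init__(self) -> None:
        if self.locus not in TCR_LOCI:
            raise ValidationError(f"locus must be one of {TCR_LOCI}, got {self.locus!r}")
        if self.v_gene and not self.v_gene.upper().startswith(self.locus[:3]):
            # v_gene prefix (TRA/TRB) must agree with the locus field
            raise ValidationError(
                f"v_gene {self.v_gene!r} contradicts locus {self.locus!r}"
            )
        if self.umis < 0:
            raise ValidationError("umis must be non-negative")


@dataclass(frozen=True)
class CellVDJ:
    """A QC-passed cell holding exactly one TRA and one TRB chain."""

    barcode: str
    sample_id: str
    tra: ChainRecord
    trb: ChainRecord

    def __post_init__(self) -> None:
        if self.tra.locus != "TRA" or self.trb.locus != "TRB":
            raise ValidationError("CellVDJ requires tra.locus==TRA and trb.locus==TRB")

    @property
    def clonotype_key(self) -> str:
        """Paired clonotype key: CDRb3 and CDRa3 nucleotide sequences appended."""
        return f"{self.trb.cdr3_nt}_{self.tra.cdr3_nt}"


@dataclass(frozen=True)
class CellAnnotation:
    """Upstream per-cell labels: sample, infection group, transcriptional cluster."""

    barcode: str
    sample_id: str
    group_label: str
    cluster_id: str


@dataclass
class Clone:
    """Cells sharing one paired-CDR3-nucleotide clonotype key."""

    clone_id: str
    cdr3b_nt: str
    cdr3a_nt: str
    cdr3b_aa: str
    cdr3a_aa: str
    member_barcodes: frozenset[str]
    v_genes: Counter = field(default_factory=Counter)  # (TRBV, TRAV) pair -> n cells
    expansion_class: str | None = None

    @property
    def size(self) -> int:
        return len(self.member_barcodes)

    def majority_v_pair(self) -> tuple[str, str]:
        """Most frequent (TRBV, TRAV) pair among member cells.

        Ties are broken by lexicographically smallest pair so the result is
        deterministic regardless of input order.
        """
        if not self.v_genes:
            raise ValidationError(f"clone {self.clone_id} has no V-gene calls")
        top_count = max(self.v_genes.values())
        return min(p for p, c in self.v_genes.items() if c == top_count)


@dataclass
class Repertoire:
    """All clones of one sample, plus its group label."""

    sample_id: str
    group_label: str
    clones: list[Clone]
    n_cells: int

    def __post_init__(self) -> None:
        total = sum(c.size for c in self.clones)
        if total != self.n_cells:
            raise ValidationError(
                f"clone sizes sum to {total}, but n_cells={self.n_cells}"
            )
        ids = [c.clone_id for c in self.clones]
        if len(ids) != len(set(ids)):
            raise ValidationError("clone_ids must be unique within a repertoire")

    @property
    def richness(self) -> int:
        return len(self.clones)

    def sizes(self) -> list[int]:
        return [c.size for c in self.clones]
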