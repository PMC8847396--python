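"""Clone definition, clonal frequency, and expansion classification.

A clone is the set of cells carrying identical paired CDR3 *nucleotide*
sequences (CDRb3 + CDRa3); synonymous amino-acid matches are distinct
clones.  Clonal frequency counts distinct cell barcodes per clonotype key.
Clones supported by a single cell are "lowly expanded"; two or more cells
make a clone "expanded".
"""

from __future__ import annotations

from collections import Counter, defaultdict

import pandas as pd

from ._errors import ValidationError
from .model import EXPANDED, LOWLY_EXPANDED, CellVDJ, Clone, Repertoire


def build_clones(
    cells: list[CellVDJ], group_label: str, sample_id: str | None = None
) -> Repertoire:
    """Group cells into clones by the paired CDR3-nucleotide clonotype key.

    Parameters
    ----------
    cells
        QC-passed cells from a single sample.
    group_label
        Infection-group (or other condition) label for the repertoire.
    sample_id
        Required only when *cells* is empty; otherwise inferred (and
        checked to be unique across cells).
    """
    sample_ids = {c.sample_id for c in cells}
    if len(sample_ids) > 1:
        raise ValidationError(f"cells span multiple samples: {sorted(sample_ids)}")
    if sample_ids:
        inferred = next(iter(sample_ids))
        if sample_id is not None and sample_id != inferred:
            raise ValidationError(
                f"sample_id {sample_id!r} does not match cells ({inferred!r})"
            )
        sample_id = inferred
    elif sample_id is None:
        raise ValidationError("sample_id required for an empty cell list")

    groups: dict[tuple[str, str], list[CellVDJ]] = defaultdict(list)
    for cell in cells:
        groups[(cell.trb.cdr3_nt, cell.tra.cdr3_nt)].append(cell)

    clones: list[Clone] = []
    for (b_nt, a_nt), members in sorted(groups.items()):
        barcodes = frozenset(m.barcode for m in members)
        v_genes = Counter((m.trb.v_gene, m.tra.v_gene) for m in members)
        first = members[0]
        clones.append(Clone(
            clone_id=f"{b_nt}_{a_nt}",
            cdr3b_nt=b_nt, cdr3a_nt=a_nt,
            cdr3b_aa=first.trb.cdr3_aa, cdr3a_aa=first.tra.cdr3_aa,
            member_barcodes=barcodes,
            v_genes=v_genes,
        ))
    rep = Repertoire(
        sample_id=sample_id, group_label=group_label,
        clones=clones, n_cells=len({c.barcode for c in cells}),
    )
    return classify_expansion(rep)


def classify_expansion(rep: Repertoire) -> Repertoire:
    """Label every clone expanded (>= 2 cells) or lowly expanded (1 cell)."""
    for clone in rep.clones:
        clone.expansion_class = EXPANDED if clone.size >= 2 else LOWLY_EXPANDED
    return rep


def top_clones(rep: Repertoire, n: int) -> list[Clone]:
    """The *n* most expanded clones, sizes descending.

    Equal sizes are ordered by clone_id (lexicographic ascending) so the
    result is deterministic.  Returns fewer than *n* clones when the
    repertoire is smaller.
    """
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    ranked = sorted(rep.clones, key=lambda c: (-c.size, c.clone_id))
    return ranked[:n]


def clone_fraction_table(rep: Repertoire) -> pd.DataFrame:
    """Table of (clone_id, size, fraction of repertoire cells), sorted as top_clones."""
    if rep.n_cells == 0:
        raise ValidationError(f"repertoire {rep.sample_id} is empty")
    ranked = sorted(rep.clones, key=lambda c: (-c.size, c.clone_id))
    return pd.DataFrame({
        "clone_id": [c.clone_id for c in ranked],
        "size": [c.size for c in ranked],
        "fraction": [c.size / rep.n_cells for c in ranked],
    })


def clone_table(rep: Repertoire) -> pd.DataFrame:
    """Full per-clone export table for one repertoire."""
    if rep.n_cells == 0:
        raise ValidationError(f"repertoire {rep.sample_id} is empty")
    rows = []
    for c in sorted(rep.clones, key=lambda c: (-c.size, c.clone_id)):
        trbv, trav = c.majority_v_pair() if c.v_genes else ("NA", "NA")
        rows.append({
            "clone_id": c.clone_id,
            "cdr3b_aa": c.cdr3b_aa, "cdr3a_aa": c.cdr3a_aa,
            "TRBV": trbv, "TRAV": trav,
            "size": c.size, "fraction": c.size / rep.n_cells,
            "expansion_class": c.expansion_class or "NA",
        })
    return pd.DataFrame(rows)
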