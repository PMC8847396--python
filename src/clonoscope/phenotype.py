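"""Joining clonal structure with per-cell transcriptional cluster labels.

The transcriptional clusters come from an upstream gene-expression
pipeline and enter only as a barcode -> cluster table.  This module
computes per-clone and per-expansion-stratum cluster composition, a formal
cell-level association between expansion and cluster membership
(Fisher/chi-square per cluster with Benjamini-Hochberg adjustment), and
position-by-residue CDR3 motif matrices for logo-style comparison.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._errors import ValidationError
from .clonotype import top_clones
from .model import AMINO_ACIDS, EXPANDED, LOWLY_EXPANDED, CellAnnotation, Clone, Repertoire

logger = logging.getLogger(__name__)


def _annotation_map(annotations: list[CellAnnotation], sample_id: str) -> dict[str, str]:
    return {a.barcode: a.cluster_id for a in annotations if a.sample_id == sample_id}


@dataclass
class ClusterComposition:
    """Fractions of cells across transcriptional clusters for one unit."""

    unit: str  # "clone" or "stratum"
    unit_id: str
    fractions: dict[str, float]  # cluster_id -> fraction, sums to 1
    n_cells: int


def clone_cluster_composition(
    rep: Repertoire,
    annotations: list[CellAnnotation],
    top_n: int | None = None,
) -> list[ClusterComposition]:
    """Per-clone cluster membership fractions.

    Restricted to the *top_n* most expanded clones when given.
    Unannotated barcodes are dropped with a logged count; a clone with no
    annotated cells is omitted (and logged).
    """
    lookup = _annotation_map(annotations, rep.sample_id)
    clones = top_clones(rep, top_n) if top_n is not None else sorted(
        rep.clones, key=lambda c: (-c.size, c.clone_id)
    )
    out: list[ClusterComposition] = []
    n_unannotated = 0
    for clone in clones:
        labels = [lookup[b] for b in clone.member_barcodes if b in lookup]
        n_unannotated += clone.size - len(labels)
        if not labels:
            logger.warning("clone %s has no annotated cells; omitted", clone.clone_id)
            continue
        counts = Counter(labels)
        n = len(labels)
        out.append(ClusterComposition(
            unit="clone", unit_id=clone.clone_id,
            fractions={k: v / n for k, v in sorted(counts.items())},
            n_cells=n,
        ))
    if n_unannotated:
        logger.info("dropped %d unannotated cells", n_unannotated)
    return out


def stratum_composition(
    rep: Repertoire,
    annotations: list[CellAnnotation],
    stratum: str,
) -> ClusterComposition:
    """Cell-level cluster fractions pooled over all clones in one
    expansion stratum ("expanded" or "lowly_expanded")."""
    if stratum not in (EXPANDED, LOWLY_EXPANDED):
        raise ValidationError(f"unknown stratum {stratum!r}")
    lookup = _annotation_map(annotations, rep.sample_id)
    labels: list[str] = []
    for clone in rep.clones:
        if clone.expansion_class != stratum:
            continue
        labels.extend(lookup[b] for b in clone.member_barcodes if b in lookup)
    if not labels:
        raise ValidationError(f"stratum {stratum!r} has no annotated cells in {rep.sample_id}")
    counts = Counter(labels)
    n = len(labels)
    return ClusterComposition(
        unit="stratum", unit_id=stratum,
        fractions={k: v / n for k, v in sorted(counts.items())},
        n_cells=n,
    )


def composition_table(compositions: list[ClusterComposition]) -> pd.DataFrame:
    """Long-format export: unit_id, cluster, fraction, n."""
    rows = [
        {"unit": c.unit, "unit_id": c.unit_id, "cluster": k,
         "fraction": f, "n": c.n_cells}
        for c in compositions for k, f in c.fractions.items()
    ]
    return pd.DataFrame(rows, columns=["unit", "unit_id", "cluster", "fraction", "n"])


@dataclass
class ExpansionAssociation:
    """Cluster-level 2x2 association between expansion and membership.

    table rows: (expanded, lowly_expanded); columns: (in cluster, out of
    cluster).  The odds ratio uses a Haldane-Anscombe 0.5 correction when
    any table cell is zero.
    """

    cluster_id: str
    table: np.ndarray  # 2x2 int
    odds_ratio: float
    log_odds_ratio: float
    p_value: float
    adjusted_p: float = float("nan")


def _odds_ratio(table: np.ndarray) -> float:
    t = table.astype(float)
    if (t == 0).any():
        t = t + 0.5
    return (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])


def expansion_cluster_association(
    rep: Repertoire,
    annotations: list[CellAnnotation],
    method: str = "fisher",
    unit: str = "cell",
) -> list[ExpansionAssociation]:
    """Test, per cluster, whether expanded cells are enriched in it.

    unit="cell" tests cell-level membership (each cell is one observation,
    matching fraction-of-cells displays); unit="clone" lets each clone vote
    its majority cluster once, avoiding pseudo-replication.  P-values are
    Benjamini-Hochberg adjusted across clusters.
    """
    if method not in ("fisher", "chi2"):
        raise ValidationError("method must be 'fisher' or 'chi2'")
    if unit not in ("cell", "clone"):
        raise ValidationError("unit must be 'cell' or 'clone'")
    lookup = _annotation_map(annotations, rep.sample_id)

    exp_labels: list[str] = []
    low_labels: list[str] = []
    for clone in rep.clones:
        if clone.expansion_class not in (EXPANDED, LOWLY_EXPANDED):
            raise ValidationError("expansion classes not assigned; run classify_expansion")
        labels = [lookup[b] for b in clone.member_barcodes if b in lookup]
        if not labels:
            continue
        if unit == "clone":
            counts = Counter(labels)
            top = max(counts.values())
            labels = [min(k for k, v in counts.items() if v == top)]
        (exp_labels if clone.expansion_class == EXPANDED else low_labels).extend(labels)

    if not exp_labels or not low_labels:
        raise ValidationError("both expansion strata must be non-empty")
    exp_counts = Counter(exp_labels)
    low_counts = Counter(low_labels)
    n_exp, n_low = len(exp_labels), len(low_labels)
    clusters = sorted(set(exp_counts) | set(low_counts))

    results: list[ExpansionAssociation] = []
    for cluster in clusters:
        a = exp_counts.get(cluster, 0)
        c = low_counts.get(cluster, 0)
        table = np.array([[a, n_exp - a], [c, n_low - c]])
        if method == "fisher":
            p = stats.fisher_exact(table)[1]
        else:
            # chi-square needs nonzero expected counts; fall back if degenerate
            try:
                p = stats.chi2_contingency(table, correction=True)[1]
            except ValueError:
                p = 1.0
        or_ = _odds_ratio(table)
        results.append(ExpansionAssociation(
            cluster_id=cluster, table=table,
            odds_ratio=or_, log_odds_ratio=float(np.log(or_)), p_value=float(p),
        ))
    adjusted = multipletests([r.p_value for r in results], method="fdr_bh")[1]
    for r, ap in zip(results, adjusted):
        r.adjusted_p = float(ap)
    return results


def association_table(associations: list[ExpansionAssociation]) -> pd.DataFrame:
    rows = [
        {"cluster": r.cluster_id,
         "n_expanded_in": int(r.table[0, 0]), "n_expanded_out": int(r.table[0, 1]),
         "n_lowly_in": int(r.table[1, 0]), "n_lowly_out": int(r.table[1, 1]),
         "odds_ratio": r.odds_ratio, "log_odds_ratio": r.log_odds_ratio,
         "p_value": r.p_value, "adjusted_p": r.adjusted_p}
        for r in associations
    ]
    return pd.DataFrame(rows)


@dataclass
class MotifMatrix:
    """Position-by-residue frequency matrix for CDR3s of one exact length."""

    chain: str  # "TRA" or "TRB"
    cdr3_length: int
    matrix: pd.DataFrame  # index 1..L, columns the 20 residues
    n_sequences: int


def motif_matrix(
    clones: list[Clone],
    chain: str,
    length: int,
    unique_sequences: bool = True,
) -> MotifMatrix:
    """Positional residue frequencies over CDR3 amino-acid sequences of one
    exact length (positions 1-based from the N-terminal cysteine).

    With ``unique_sequences`` (default, matching logo plots built on unique
    CDR3s) duplicate sequences count once.
    """
    if chain not in ("TRA", "TRB"):
        raise ValidationError("chain must be 'TRA' or 'TRB'")
    seqs = [c.cdr3b_aa if chain == "TRB" else c.cdr3a_aa for c in clones]
    if unique_sequences:
        seqs = sorted(set(seqs))
    matching = [s for s in seqs if len(s) == length]
    if not matching:
        available = sorted({len(s) for s in seqs})
        raise ValidationError(
            f"no {chain} CDR3 of length {length}; available lengths: {available}"
        )
    mat = pd.DataFrame(0.0, index=range(1, length + 1), columns=list(AMINO_ACIDS))
    for seq in matching:
        for pos, res in enumerate(seq, start=1):
            if res not in AMINO_ACIDS:
                raise ValidationError(f"non-amino-acid residue {res!r} in {seq!r}")
            mat.loc[pos, res] += 1
    mat /= len(matching)
    return MotifMatrix(chain=chain, cdr3_length=length,
                       matrix=mat, n_sequences=len(matching))


def dominant_length(clones: list[Clone], chain: str, unique_sequences: bool = True) -> int:
    """Most common CDR3 length for a chain (ties -> shortest)."""
    seqs = [c.cdr3b_aa if chain == "TRB" else c.cdr3a_aa for c in clones]
    if unique_sequences:
        seqs = set(seqs)
    if not seqs:
        raise ValidationError("no sequences supplied")
    counts = Counter(len(s) for s in seqs)
    top = max(counts.values())
    return min(k for k, v in counts.items() if v == top)


def motif_contrast(m1: MotifMatrix, m2: MotifMatrix) -> pd.DataFrame:
    """Entrywise difference m1 - m2; each position row sums to 0."""
    if m1.chain != m2.chain or m1.cdr3_length != m2.cdr3_length:
        raise ValidationError(
            f"motif matrices differ in chain/length: "
            f"{m1.chain}/{m1.cdr3_length} vs {m2.chain}/{m2.cdr3_length}"
        )
    return m1.matrix - m2.matrix
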