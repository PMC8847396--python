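"""V-gene usage statistics, TRBV x TRAV pairing, and usage correlation.

Usage can be weighted per cell (each cell votes its V-gene call; expansion
inflates heavily used genes) or per clone (each clone votes the majority
call of its members once).  Pairwise Pearson correlation between usage
frequency vectors, followed by average-linkage hierarchical clustering on
1 - r, summarizes which repertoires draw from similar germline gene pools.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from ._errors import ValidationError
from .model import Repertoire

logger = logging.getLogger(__name__)

GENE_SPACES = ("TRBV", "TRAV", "TRBV+TRAV")
WEIGHTINGS = ("per_cell", "per_clone")

_GENE_RE = re.compile(r"^TR[ABGD][VDJ]", re.IGNORECASE)


def normalize_gene_name(name: str) -> str:
    """Canonicalize an IMGT-style gene name.

    Uppercases, strips allele suffixes ("*01"), and converts dotted
    family/member separators ("TRBV13.1") to the hyphenated form
    ("TRBV13-1").  Names that do not look like TR-locus genes are returned
    unchanged (and logged) so dialect mismatches stay visible.
    """
    s = name.strip().upper()
    s = s.split("*", 1)[0]
    if not _GENE_RE.match(s):
        logger.warning("unresolvable gene name %r left as-is", name)
        return s
    return s.replace(".", "-")


@dataclass
class UsageVector:
    """Germline gene usage for one sample in one gene space."""

    sample_id: str
    gene_space: str
    counts: pd.Series  # gene -> count
    weighting: str

    @property
    def frequencies(self) -> pd.Series:
        total = self.counts.sum()
        if total == 0:
            return self.counts.astype(float)
        return self.counts / total


def usage_vector(
    rep: Repertoire, gene_space: str = "TRBV", weighting: str = "per_cell"
) -> UsageVector:
    """Count V-gene usage for one repertoire.

    per_cell counts every member cell once; per_clone counts each clone
    once using its majority (TRBV, TRAV) pair.
    """
    if gene_space not in GENE_SPACES:
        raise ValidationError(f"gene_space must be one of {GENE_SPACES}")
    if weighting not in WEIGHTINGS:
        raise ValidationError(f"weighting must be one of {WEIGHTINGS}")
    if rep.richness == 0:
        raise ValidationError(f"repertoire {rep.sample_id} is empty")
    counts: dict[str, int] = {}

    def _add(gene: str, k: int) -> None:
        gene = normalize_gene_name(gene)
        counts[gene] = counts.get(gene, 0) + k

    for clone in rep.clones:
        if weighting == "per_clone":
            pairs = [(clone.majority_v_pair(), 1)]
        else:
            pairs = [(pair, k) for pair, k in clone.v_genes.items()]
        for (trbv, trav), k in pairs:
            if gene_space in ("TRBV", "TRBV+TRAV"):
                _add(trbv, k)
            if gene_space in ("TRAV", "TRBV+TRAV"):
                _add(trav, k)
    series = pd.Series(counts, dtype=float).sort_index()
    return UsageVector(
        sample_id=rep.sample_id, gene_space=gene_space,
        counts=series, weighting=weighting,
    )


@dataclass
class PairingMatrix:
    """Counts of cells (or clones) using each (TRBV, TRAV) combination."""

    sample_id: str
    counts: pd.DataFrame  # rows TRBV, cols TRAV
    label_threshold: int = 5
    weighting: str = "per_cell"

    def labeled_pairs(self) -> pd.DataFrame:
        """Chord-diagram export: pairs with count >= label_threshold."""
        rows = [
            {"TRBV": b, "TRAV": a, "count": int(v)}
            for (b, a), v in self.counts.stack().items()
            if v >= self.label_threshold
        ]
        rows.sort(key=lambda r: (-r["count"], r["TRBV"], r["TRAV"]))
        return pd.DataFrame(rows, columns=["TRBV", "TRAV", "count"])


def pairing_matrix(
    rep: Repertoire,
    weighting: str = "per_cell",
    label_threshold: int = 5,
) -> PairingMatrix:
    """TRBV x TRAV pairing counts for one repertoire.

    Row and column marginals equal the corresponding single-chain usage
    counts under the same weighting.
    """
    if weighting not in WEIGHTINGS:
        raise ValidationError(f"weighting must be one of {WEIGHTINGS}")
    if rep.richness == 0:
        raise ValidationError(f"repertoire {rep.sample_id} is empty")
    counts: dict[tuple[str, str], int] = {}
    for clone in rep.clones:
        if weighting == "per_clone":
            pairs = [(clone.majority_v_pair(), 1)]
        else:
            pairs = list(clone.v_genes.items())
        for (trbv, trav), k in pairs:
            key = (normalize_gene_name(trbv), normalize_gene_name(trav))
            counts[key] = counts.get(key, 0) + k
    trbvs = sorted({b for b, _ in counts})
    travs = sorted({a for _, a in counts})
    mat = pd.DataFrame(0, index=trbvs, columns=travs)
    for (b, a), k in counts.items():
        mat.loc[b, a] = k
    return PairingMatrix(
        sample_id=rep.sample_id, counts=mat,
        label_threshold=label_threshold, weighting=weighting,
    )


def _aligned_frequency_frame(vectors: list[UsageVector]) -> pd.DataFrame:
    """Samples x genes frequency matrix over the union gene set (missing -> 0)."""
    spaces = {v.gene_space for v in vectors}
    if len(spaces) > 1:
        raise ValidationError(f"vectors span multiple gene spaces: {sorted(spaces)}")
    freq = pd.DataFrame(
        {v.sample_id: v.frequencies for v in vectors}
    ).fillna(0.0).T
    return freq.reindex(sorted(freq.columns), axis=1)


def usage_correlation(
    vectors: list[UsageVector], method: str = "pearson"
) -> tuple[pd.DataFrame, list[str]]:
    """Pairwise correlation of usage frequency vectors with dendrogram order.

    Returns the correlation matrix (NaN where a vector is constant) and the
    deterministic leaf order of an average-linkage clustering on 1 - r.
    """
    if len(vectors) < 2:
        raise ValidationError("usage correlation requires >= 2 vectors")
    if method not in ("pearson", "spearman"):
        raise ValidationError("method must be 'pearson' or 'spearman'")
    freq = _aligned_frequency_frame(
        sorted(vectors, key=lambda v: v.sample_id)
    )
    corr = freq.T.corr(method=method)
    # cluster on 1 - r; undefined correlations are treated as maximally distant
    dist = (1.0 - corr).fillna(2.0).to_numpy()
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    link = hierarchy.linkage(condensed, method="average")
    order = [freq.index[i] for i in hierarchy.leaves_list(link)]
    return corr, order


def compare_external_usage(
    vectors: list[UsageVector],
    external: list[UsageVector],
    method: str = "pearson",
) -> tuple[pd.DataFrame, list[str]]:
    """Correlate sample usage against externally supplied usage tables.

    External vectors (e.g. published naive or bystander repertoires given
    as gene/frequency tables) are re-normalized onto the union gene set;
    gene-name dialects are canonicalized via :func:`normalize_gene_name`.
    """
    if not external:
        raise ValidationError("no external usage vectors supplied")
    normed = []
    for v in external:
        counts = v.counts.copy()
        counts.index = [normalize_gene_name(g) for g in counts.index]
        counts = counts.groupby(level=0).sum()
        normed.append(UsageVector(v.sample_id, v.gene_space, counts, v.weighting))
    return usage_correlation(list(vectors) + normed, method=method)


def external_usage_from_table(
    table: pd.DataFrame, sample_id: str, gene_space: str = "TRBV"
) -> UsageVector:
    """Build a usage vector from a (gene, frequency) table."""
    if not {"gene", "frequency"} <= set(table.columns):
        raise ValidationError("external usage table needs columns: gene, frequency")
    counts = pd.Series(
        table["frequency"].to_numpy(dtype=float),
        index=[normalize_gene_name(g) for g in table["gene"]],
    ).groupby(level=0).sum().sort_index()
    return UsageVector(sample_id=sample_id, gene_space=gene_space,
                       counts=counts, weighting="per_cell")
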