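"""Public (shared) clones across repertoires by exact clonotype-key match.

Sharing is keyed on the appended CDRb3+CDRa3 nucleotide sequences, the
same key that defines clones.  An optional amino-acid mode relaxes the key
to the paired CDR3 amino-acid sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._errors import ValidationError
from .clonotype import top_clones
from .model import EXPANDED, Clone, Repertoire

RESTRICTIONS = ("all", "expanded_only", "top_n")


def _clone_keys(rep: Repertoire, restriction: str, n: int | None, level: str) -> set[str]:
    if restriction == "all":
        clones: list[Clone] = rep.clones
    elif restriction == "expanded_only":
        clones = [c for c in rep.clones if c.size >= 2]
    elif restriction == "top_n":
        clones = top_clones(rep, n)
    else:
        raise ValidationError(f"restriction must be one of {RESTRICTIONS}")
    if level == "nt":
        return {c.clone_id for c in clones}
    return {f"{c.cdr3b_aa}_{c.cdr3a_aa}" for c in clones}


@dataclass
class OverlapMatrix:
    """Pairwise shared-clone counts; the diagonal is not applicable."""

    sample_ids: list[str]
    counts: np.ndarray  # float matrix, NaN on the diagonal
    restricted_to: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.sample_ids)

    def write_tsv(self, path) -> None:
        df = self.to_frame()
        # integer counts with literal "NA" on the diagonal
        out = df.map(lambda v: "NA" if np.isnan(v) else str(int(v)))
        out.to_csv(path, sep="\t", index_label="sample_id")


def overlap_matrix(
    reps: list[Repertoire],
    restriction: str = "all",
    n: int | None = None,
    level: str = "nt",
) -> OverlapMatrix:
    """Count identical clones between every pair of repertoires.

    ``restriction`` limits which clones participate: all clones, expanded
    clones only (size >= 2), or each repertoire's ``n`` most expanded
    clones (``top_n``, *n* required).
    """
    if len(reps) < 2:
        raise ValidationError("overlap requires at least 2 repertoires")
    if (restriction == "top_n") != (n is not None):
        raise ValidationError("n must be given exactly when restriction == 'top_n'")
    keysets = [_clone_keys(r, restriction, n, level) for r in reps]
    m = len(reps)
    counts = np.full((m, m), np.nan)
    for i in range(m):
        for j in range(i + 1, m):
            shared = len(keysets[i] & keysets[j])
            counts[i, j] = counts[j, i] = shared
    return OverlapMatrix(
        sample_ids=[r.sample_id for r in reps],
        counts=counts,
        restricted_to=restriction,
    )


def public_clone_table(reps: list[Repertoire], level: str = "nt") -> pd.DataFrame:
    """One row per clonotype key found in >= 2 samples.

    Columns: clone_id, samples_sharing, groups_sharing.
    """
    if len(reps) < 2:
        raise ValidationError("public-clone analysis requires at least 2 repertoires")
    samples_by_key: dict[str, set[str]] = {}
    groups_by_key: dict[str, set[str]] = {}
    for rep in reps:
        for key in _clone_keys(rep, "all", None, level):
            samples_by_key.setdefault(key, set()).add(rep.sample_id)
            groups_by_key.setdefault(key, set()).add(rep.group_label)
    rows = [
        {"clone_id": key,
         "samples_sharing": len(samples),
         "groups_sharing": len(groups_by_key[key])}
        for key, samples in sorted(samples_by_key.items())
        if len(samples) >= 2
    ]
    return pd.DataFrame(rows, columns=["clone_id", "samples_sharing", "groups_sharing"])
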