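"""Global clonal-expansion structure: Shannon entropy and evenness.

Shannon entropy of the clone-size proportions summarizes how evenly the
repertoire is spread across clones; Pielou's evenness J = H / ln(S)
normalizes it to [0, 1] so repertoires of different richness are
comparable.  A value near 1 indicates a flat, polyclonal repertoire; values
near 0 indicate dominance by few expanded clones.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import ValidationError
from .model import Repertoire

logger = logging.getLogger(__name__)


def _validate_sizes(sizes) -> np.ndarray:
    arr = np.asarray(list(sizes), dtype=float)
    if arr.size == 0:
        raise ValidationError("sizes must be non-empty")
    if np.any(arr < 1):
        raise ValidationError("all clone sizes must be >= 1")
    return arr


def shannon_entropy(sizes, base: float | None = None) -> float:
    """Shannon entropy H = -sum p_i log p_i of clone-size proportions.

    Natural log by default; H lies in [0, log S].
    """
    arr = _validate_sizes(sizes)
    return float(stats.entropy(arr, base=base))


def shannon_evenness(sizes, base: float | None = None) -> float:
    """Pielou's evenness J = H / log(S); 0 by convention for S == 1.

    The value is independent of the log base.
    """
    arr = _validate_sizes(sizes)
    s = arr.size
    if s == 1:
        logger.warning("monoclonal repertoire: evenness defined as 0")
        return 0.0
    log = math.log if base is None else (lambda x: math.log(x, base))
    return float(stats.entropy(arr, base=base) / log(s))


def singleton_fraction(rep: Repertoire) -> float:
    """Fraction of clones supported by a single cell barcode."""
    if rep.richness == 0:
        raise ValidationError(f"repertoire {rep.sample_id} has no clones")
    return sum(1 for c in rep.clones if c.size == 1) / rep.richness


@dataclass(frozen=True)
class DiversitySummary:
    sample_id: str
    richness: int
    shannon_entropy: float
    shannon_evenness: float
    fraction_singletons: float


def diversity_summary(rep: Repertoire) -> DiversitySummary:
    """All diversity statistics for one repertoire."""
    sizes = rep.sizes()
    return DiversitySummary(
        sample_id=rep.sample_id,
        richness=rep.richness,
        shannon_entropy=shannon_entropy(sizes),
        shannon_evenness=shannon_evenness(sizes),
        fraction_singletons=singleton_fraction(rep),
    )


def diversity_table(reps: list[Repertoire]) -> pd.DataFrame:
    """Diversity summary TSV-ready table across samples."""
    rows = [diversity_summary(r).__dict__ | {"group_label": r.group_label} for r in reps]
    cols = ["sample_id", "group_label", "richness", "shannon_entropy",
            "shannon_evenness", "fraction_singletons"]
    return pd.DataFrame(rows, columns=cols)
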