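"""Reading and writing single-cell V(D)J tables, and the chain-count QC filter.

Two input dialects are supported: the 10x Genomics
``filtered_contig_annotations.csv`` table produced by ``cellranger vdj``,
and the AIRR Rearrangement TSV.  After reading, contigs are assembled into
cells and the core quality filter is applied: a cell is retained only if it
carries exactly one TRA and one TRB contig (after the per-contig
productive / is-cell / high-confidence predicates).
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from ._errors import FormatError, IntegrityError, ValidationError
from .model import TCR_LOCI, CellAnnotation, CellVDJ, ChainRecord

logger = logging.getLogger(__name__)

TENX_COLUMNS = (
    "barcode", "chain", "cdr3", "cdr3_nt", "v_gene", "j_gene",
    "productive", "is_cell", "high_confidence", "umis",
)
AIRR_COLUMNS = (
    "cell_id", "locus", "junction", "junction_aa", "v_call", "j_call", "productive",
)


def _parse_flag(value, default: bool = False) -> bool:
    """Normalize cellranger-style booleans: 'True'/'true'/'TRUE' etc.

    ``'None'`` (cellranger's marker for undetermined productivity) maps to
    False.  Missing values map to *default*.
    """
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return default
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in ("true", "t", "1", "yes"):
        return True
    if s in ("false", "f", "0", "no", "none", "nan", ""):
        return False
    raise FormatError(f"unrecognized boolean value {value!r}")


def _read_table(path, sep: str) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return pd.DataFrame()


def read_contigs(path, dialect: str, sample_id: str) -> list[ChainRecord]:
    """Read per-contig chain records from a 10x CSV or AIRR TSV.

    Contigs from loci other than TRA/TRB (TRG, TRD, IGH, ...) are dropped
    with a logged count.  An empty file yields an empty list.
    """
    if dialect not in ("tenx_csv", "airr_tsv"):
        raise ValidationError(f"unknown dialect {dialect!r}")
    df = _read_table(path, "," if dialect == "tenx_csv" else "\t")
    if df.empty and df.columns.empty:
        return []
    return contigs_from_frame(df, dialect, sample_id, source=str(path))


def contigs_from_frame(
    df: pd.DataFrame, dialect: str, sample_id: str, source: str = "<frame>"
) -> list[ChainRecord]:
    """Build chain records from an already-loaded contig table.

    Same contract as :func:`read_contigs`, for in-memory tables (e.g. those
    produced by the synthetic-data generator).  All values are treated as
    strings, matching the file-reading path.
    """
    if dialect not in ("tenx_csv", "airr_tsv"):
        raise ValidationError(f"unknown dialect {dialect!r}")
    df = df.astype(str) if not df.empty else df
    required = TENX_COLUMNS if dialect == "tenx_csv" else AIRR_COLUMNS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{source}: missing required column(s): {', '.join(missing)}")
    records: list[ChainRecord] = []
    dropped = 0
    for row in df.itertuples(index=False):
        r = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        if dialect == "tenx_csv":
            locus = r["chain"].strip().upper()
            if locus not in TCR_LOCI:
                dropped += 1
                continue
            records.append(ChainRecord(
                barcode=r["barcode"],
                sample_id=sample_id,
                locus=locus,
                cdr3_nt=r["cdr3_nt"].strip().upper(),
                cdr3_aa=r["cdr3"].strip().upper(),
                v_gene=r["v_gene"].strip(),
                j_gene=r["j_gene"].strip(),
                d_gene=(r.get("d_gene") or None),
                productive=_parse_flag(r["productive"]),
                is_cell_flag=_parse_flag(r["is_cell"]),
                high_confidence_flag=_parse_flag(r["high_confidence"]),
                umis=int(r["umis"] or 0),
            ))
        else:
            locus = r["locus"].strip().upper()
            if locus not in TCR_LOCI:
                dropped += 1
                continue
            umis = r.get("duplicate_count") or r.get("umi_count") or 0
            records.append(ChainRecord(
                barcode=r["cell_id"],
                sample_id=sample_id,
                locus=locus,
                cdr3_nt=r["junction"].strip().upper(),
                cdr3_aa=r["junction_aa"].strip().upper(),
                v_gene=r["v_call"].strip(),
                j_gene=r["j_call"].strip(),
                d_gene=(r.get("d_call") or None),
                productive=_parse_flag(r["productive"], default=True),
                is_cell_flag=_parse_flag(r.get("is_cell"), default=True),
                high_confidence_flag=_parse_flag(r.get("high_confidence"), default=True),
                umis=int(umis or 0),
            ))
    if dropped:
        logger.info("contigs(%s): dropped %d non-TRA/TRB contigs", source, dropped)
    return records


@dataclass
class FilterReport:
    """Per-reason accounting for barcodes discarded by the chain-count filter.

    Every distinct input barcode appears exactly once in
    retained + the per-reason discard counts.
    """

    n_barcodes: int = 0
    n_retained: int = 0
    no_tra: int = 0
    multi_tra: int = 0
    no_trb: int = 0
    multi_trb: int = 0
    n_contigs_failed_predicates: int = 0
    n_duplicate_contigs: int = 0

    def as_dict(self) -> dict:
        return asdict(self)

    def check_conservation(self) -> None:
        total = self.n_retained + self.no_tra + self.multi_tra + self.no_trb + self.multi_trb
        if total != self.n_barcodes:
            raise IntegrityError(
                f"filter report does not reconcile: {total} != {self.n_barcodes}"
            )


def assemble_cells(
    records: list[ChainRecord],
    require_productive: bool = True,
    require_cell: bool = True,
    require_high_confidence: bool = True,
) -> tuple[list[CellVDJ], FilterReport]:
    """Assemble contigs into QC-passed cells (exactly one TRA + one TRB).

    Contigs failing the per-contig predicates are removed before the chain
    count is taken, so e.g. a barcode with one productive and one
    non-productive TRB still passes under ``require_productive``.  Duplicate
    identical (barcode, locus, cdr3_nt) rows are deduplicated silently.

    Returns the retained cells and a :class:`FilterReport` accounting for
    every input barcode.
    """
    report = FilterReport()
    seen: set[tuple[str, str, str]] = set()
    by_barcode: dict[str, dict[str, list[ChainRecord]]] = defaultdict(
        lambda: {"TRA": [], "TRB": []}
    )
    all_barcodes: set[str] = set()
    for rec in records:
        all_barcodes.add(rec.barcode)
        key = (rec.barcode, rec.locus, rec.cdr3_nt)
        if key in seen:
            report.n_duplicate_contigs += 1
            continue
        seen.add(key)
        if (
            (require_productive and not rec.productive)
            or (require_cell and not rec.is_cell_flag)
            or (require_high_confidence and not rec.high_confidence_flag)
        ):
            report.n_contigs_failed_predicates += 1
            continue
        by_barcode[rec.barcode][rec.locus].append(rec)

    report.n_barcodes = len(all_barcodes)
    cells: list[CellVDJ] = []
    for barcode in sorted(all_barcodes):
        chains = by_barcode.get(barcode, {"TRA": [], "TRB": []})
        tras, trbs = chains["TRA"], chains["TRB"]
        if len(tras) == 0:
            report.no_tra += 1
        elif len(tras) > 1:
            report.multi_tra += 1
        elif len(trbs) == 0:
            report.no_trb += 1
        elif len(trbs) > 1:
            report.multi_trb += 1
        else:
            cells.append(CellVDJ(
                barcode=barcode, sample_id=tras[0].sample_id,
                tra=tras[0], trb=trbs[0],
            ))
    report.n_retained = len(cells)
    report.check_conservation()
    return cells, report


def read_annotations(path) -> list[CellAnnotation]:
    """Read the per-cell annotation table (barcode, sample, group, cluster)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = _read_table(path, sep)
    required = ("barcode", "sample_id", "group_label", "cluster_id")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    dup = df.duplicated(subset=["barcode", "sample_id"], keep=False)
    if dup.any():
        offenders = sorted(set(df.loc[dup, "barcode"]))
        raise IntegrityError(
            f"duplicate (barcode, sample_id) keys for barcodes: {offenders[:20]}"
        )
    return [
        CellAnnotation(
            barcode=r.barcode, sample_id=r.sample_id,
            group_label=r.group_label, cluster_id=str(r.cluster_id),
        )
        for r in df.itertuples(index=False)
    ]


AIRR_OUT_COLUMNS = (
    "cell_id", "locus", "junction", "junction_aa",
    "v_call", "d_call", "j_call", "productive", "duplicate_count",
)


def write_airr(cells: list[CellVDJ], path) -> None:
    """Write QC-passed cells as an AIRR Rearrangement TSV (two rows per cell).

    The output round-trips through ``read_contigs`` + ``assemble_cells`` to
    an identical cell set.
    """
    rows = []
    for cell in cells:
        for chain in (cell.tra, cell.trb):
            if not chain.cdr3_nt:
                raise ValidationError(
                    f"cell {cell.barcode}: empty cdr3_nt on {chain.locus}, refusing to write"
                )
            rows.append({
                "cell_id": cell.barcode,
                "locus": chain.locus,
                "junction": chain.cdr3_nt,
                "junction_aa": chain.cdr3_aa,
                "v_call": chain.v_gene,
                "d_call": chain.d_gene or "",
                "j_call": chain.j_gene,
                "productive": "T" if chain.productive else "F",
                "duplicate_count": chain.umis,
            })
    df = pd.DataFrame(rows, columns=list(AIRR_OUT_COLUMNS))
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
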