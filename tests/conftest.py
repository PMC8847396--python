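from __future__ import annotations

import pytest

from clonoscope.model import CellVDJ, ChainRecord


def make_chain(
    barcode: str,
    locus: str,
    cdr3_nt: str,
    cdr3_aa: str | None = None,
    sample_id: str = "s1",
    v_gene: str | None = None,
    **kwargs,
) -> ChainRecord:
    """Convenience ChainRecord constructor for fixtures."""
    if v_gene is None:
        v_gene = "TRBV13-1" if locus == "TRB" else "TRAV9-1"
    if cdr3_aa is None:
        cdr3_aa = "X" * (len(cdr3_nt) // 3)
    return ChainRecord(
        barcode=barcode, sample_id=sample_id, locus=locus,
        cdr3_nt=cdr3_nt, cdr3_aa=cdr3_aa,
        v_gene=v_gene, j_gene="TRBJ1-1" if locus == "TRB" else "TRAJ12",
        **kwargs,
    )


def make_cell(
    barcode: str,
    trb_nt: str = "TGTGCCAGCAGC",
    tra_nt: str = "TGTGCTGTGAGA",
    trb_aa: str = "CASS",
    tra_aa: str = "CAVR",
    sample_id: str = "s1",
    trbv: str = "TRBV13-1",
    trav: str = "TRAV9-1",
) -> CellVDJ:
    return CellVDJ(
        barcode=barcode, sample_id=sample_id,
        tra=make_chain(barcode, "TRA", tra_nt, tra_aa, sample_id, v_gene=trav),
        trb=make_chain(barcode, "TRB", trb_nt, trb_aa, sample_id, v_gene=trbv),
    )


TENX_HEADER = "barcode,is_cell,contig_id,high_confidence,chain,v_gene,d_gene,j_gene,productive,cdr3,cdr3_nt,umis"


def tenx_row(barcode, chain, cdr3_aa, cdr3_nt, v_gene="TRBV13-1", j_gene="TRBJ1-1",
             productive="True", is_cell="True", high_confidence="True", umis=3) -> str:
    return ",".join([barcode, is_cell, f"{barcode}_contig", high_confidence, chain,
                     v_gene, "", j_gene, productive, cdr3_aa, cdr3_nt, str(umis)])


@pytest.fixture
def tenx_csv(tmp_path):
    """Write a 10x-dialect contig CSV from row strings."""

    def _write(rows, name="contigs.csv"):
        path = tmp_path / name
        path.write_text("\n".join([TENX_HEADER, *rows]) + "\n")
        return path

    return _write
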