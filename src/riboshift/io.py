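"""Input/output and basic containers for transcript-space ribosome-profiling data.

All coordinates are transcript-space and 0-based: position 0 is the first
base of the start codon, negative positions lie in the upstream extension
of the CDS reference (25 nt by default).  Antisense records do not exist in
this coordinate system; reads are implicitly sense-strand.

Aligned reads are held as a pandas DataFrame with columns
``gene_id, five_prime_pos, length`` (one row per read) rather than as one
object per read — every downstream operation is vectorised over this table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

READ_COLUMNS = ["gene_id", "five_prime_pos", "length"]

#: Reads shorter than this many nt are discarded by default.
DEFAULT_MIN_READ_LENGTH = 24

#: Default upstream extension of the CDS reference, in nt.
DEFAULT_UPSTREAM_EXTENSION = 25


class FormatError(ValueError):
    """A file does not match the expected tabular layout."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


@dataclass(frozen=True)
class GeneModel:
    """A coding sequence extended upstream of the start codon.

    Parameters
    ----------
    gene_id : str
        Unique gene identifier within an annotation set.
    cds_length : int
        Length of the coding sequence in nt; must be >= 3.
    upstream_extension : int
        How far upstream of the start codon the reference extends (nt);
        valid 5' read positions are >= ``-upstream_extension``.
    is_top : bool
        Whether the gene carries a 5' terminal oligopyrimidine (TOP) motif.
    """

    gene_id: str
    cds_length: int
    upstream_extension: int = DEFAULT_UPSTREAM_EXTENSION
    is_top: bool = False

    def __post_init__(self) -> None:
        if self.cds_length < 3:
            raise ValidationError(
                f"gene {self.gene_id!r}: cds_length must be >= 3, got {self.cds_length}"
            )
        if self.upstream_extension < 0:
            raise ValidationError(
                f"gene {self.gene_id!r}: upstream_extension must be >= 0,"
                f" got {self.upstream_extension}"
            )


class Annotation:
    """An ordered set of :class:`GeneModel` with unique gene ids."""

    def __init__(self, genes: Iterable[GeneModel]):
        self._genes: dict[str, GeneModel] = {}
        for g in genes:
            if g.gene_id in self._genes:
                raise ValidationError(f"duplicate gene_id {g.gene_id!r} in annotation")
            self._genes[g.gene_id] = g

    def __len__(self) -> int:
        return len(self._genes)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self._genes.values())

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._genes

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self._genes[gene_id]

    @property
    def gene_ids(self) -> list[str]:
        return list(self._genes)

    @property
    def top_gene_ids(self) -> list[str]:
        return [g.gene_id for g in self if g.is_top]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in self],
                "cds_length": [g.cds_length for g in self],
                "upstream_extension": [g.upstream_extension for g in self],
                "is_top": [g.is_top for g in self],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df["is_top"] = np.where(df["is_top"], "true", "false")
        df.to_csv(path, sep="\t", index=False)


def load_annotation(path: str | Path) -> Annotation:
    """Read an annotation TSV (gene_id, cds_length, upstream_extension, is_top)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    required = {"gene_id", "cds_length", "upstream_extension", "is_top"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing annotation column(s) {sorted(missing)}")

    def parse_bool(v: object) -> bool:
        s = str(v).strip().lower()
        if s in {"true", "1", "yes"}:
            return True
        if s in {"false", "0", "no"}:
            return False
        raise FormatError(f"{path}: cannot parse is_top value {v!r}")

    genes = [
        GeneModel(
            gene_id=row.gene_id,
            cds_length=int(row.cds_length),
            upstream_extension=int(row.upstream_extension),
            is_top=parse_bool(row.is_top),
        )
        for row in df.itertuples()
    ]
    return Annotation(genes)


def _as_read_frame(df: pd.DataFrame) -> pd.DataFrame:
    out = df.loc[:, READ_COLUMNS].copy()
    out["five_prime_pos"] = out["five_prime_pos"].astype(np.int64)
    out["length"] = out["length"].astype(np.int64)
    return out


def validate_reads(
    reads: pd.DataFrame, annotation: Annotation, strict: bool = False
) -> pd.DataFrame:
    """Drop (or reject, if ``strict``) reads outside their gene's reference bounds.

    A read is valid when its gene is annotated, its 5' end is not upstream of
    the gene's extension, and it ends within the CDS
    (``five_prime_pos + length <= cds_length``).
    """
    reads = _as_read_frame(reads)
    ann = annotation.to_frame().set_index("gene_id")
    known = reads["gene_id"].isin(ann.index)
    n_unknown = int((~known).sum())
    if n_unknown:
        msg = f"{n_unknown} read(s) reference unknown gene ids"
        if strict:
            raise ValidationError(msg)
        log.warning("%s; skipped", msg)
    sub = reads[known]
    ext = ann["upstream_extension"].reindex(sub["gene_id"]).to_numpy()
    cds = ann["cds_length"].reindex(sub["gene_id"]).to_numpy()
    pos = sub["five_prime_pos"].to_numpy()
    length = sub["length"].to_numpy()
    in_bounds = (pos >= -ext) & (pos + length <= cds) & (length >= 1)
    n_oob = int((~in_bounds).sum())
    if n_oob:
        msg = f"{n_oob} read(s) out of reference bounds"
        if strict:
            raise ValidationError(msg)
        log.warning("%s; rejected", msg)
    return sub[in_bounds].reset_index(drop=True)


def load_reads(
    path: str | Path, annotation: Annotation, strict: bool = False
) -> pd.DataFrame:
    """Read aligned reads from TSV ``gene_id<TAB>five_prime_pos<TAB>length``."""
    df = pd.read_csv(path, sep="\t", header=None, names=READ_COLUMNS, dtype={0: str})
    return validate_reads(df, annotation, strict=strict)


def write_reads(reads: pd.DataFrame, path: str | Path) -> None:
    _as_read_frame(reads).to_csv(path, sep="\t", index=False, header=False)


def load_reads_sam(
    path: str | Path, annotation: Annotation, strict: bool = False
) -> pd.DataFrame:
    """Read a minimal SAM dialect where each reference sequence is one gene's
    extended CDS.

    Only mapped records are used.  ``POS`` is 1-based on the extended
    reference, whose first base sits ``upstream_extension`` nt upstream of the
    start codon, so ``five_prime_pos = (POS - 1) - upstream_extension``.
    Read length is taken from the sequence field; CIGAR clipping is not
    interpreted.
    """
    rows: list[tuple[str, int, int]] = []
    ext_by_gene = {g.gene_id: g.upstream_extension for g in annotation}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("@"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 10:
                raise FormatError(f"{path}: SAM record with fewer than 10 fields")
            flag = int(fields[1])
            rname, pos1, seq = fields[2], int(fields[3]), fields[9]
            if flag & 0x4 or rname == "*":
                continue
            ext = ext_by_gene.get(rname, DEFAULT_UPSTREAM_EXTENSION)
            rows.append((rname, pos1 - 1 - ext, len(seq)))
    df = pd.DataFrame(rows, columns=READ_COLUMNS)
    return validate_reads(df, annotation, strict=strict)


def filter_by_length(
    reads: pd.DataFrame, min_len: int = DEFAULT_MIN_READ_LENGTH
) -> pd.DataFrame:
    """Remove reads shorter than ``min_len`` nt (order preserved)."""
    return reads[reads["length"] >= min_len].reset_index(drop=True)


def count_reads(
    reads: pd.DataFrame, annotation: Annotation, sample_id: str
) -> pd.Series:
    """Count reads per gene; genes without reads get 0.

    Returns a Series named ``sample_id`` indexed by all annotated gene ids;
    its sum is the library size.
    """
    counts = reads["gene_id"].value_counts()
    return (
        counts.reindex(annotation.gene_ids, fill_value=0)
        .astype(np.int64)
        .rename(sample_id)
        .rename_axis("gene_id")
    )


def make_count_table(columns: Iterable[pd.Series]) -> pd.DataFrame:
    """Assemble per-sample count Series (shared gene index) into a gene x sample table."""
    table = pd.concat(list(columns), axis=1)
    if table.isna().any().any():
        raise ValidationError("count columns do not share a common gene set")
    return table.astype(np.int64)


def library_sizes(table: pd.DataFrame) -> pd.Series:
    return table.sum(axis=0)


def rpm_normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Reads-per-million normalisation: count / library_size * 1e6 per column."""
    sizes = library_sizes(table)
    empty = sizes[sizes <= 0]
    if len(empty):
        raise ValidationError(
            f"cannot RPM-normalise sample(s) with zero library size: {list(empty.index)}"
        )
    return table / sizes * 1e6


def load_counts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    if (df < 0).any().any():
        raise ValidationError(f"{path}: negative counts")
    return df.astype(np.int64)


def write_counts(table: pd.DataFrame, path: str | Path) -> None:
    table.rename_axis("gene_id").to_csv(path, sep="\t")


PANEL_GROUPS = ("NoEx", "0h", "1h", "2h", "4h")
PANEL_RESPONSE = "Slc25a25_protein"
PANEL_PREDICTORS = (
    "Slc25a25_mRNA",
    "Mmp2",
    "Nrf2",
    "Atrogin1",
    "MuRF1",
    "Pmpca",
    "Yme1l1",
    "Immp2l",
)


def load_panel(path: str | Path) -> pd.DataFrame:
    """Read a per-mouse expression panel TSV.

    Columns: mouse_id, group, Slc25a25_protein, then the predictor genes.
    """
    df = pd.read_csv(path, sep="\t", dtype={"mouse_id": str, "group": str})
    required = {"mouse_id", "group", PANEL_RESPONSE, *PANEL_PREDICTORS}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing panel column(s) {sorted(missing)}")
    if df[PANEL_RESPONSE].isna().any():
        raise ValidationError(f"{path}: missing response values")
    return df


def write_panel(panel: pd.DataFrame, path: str | Path) -> None:
    panel.to_csv(path, sep="\t", index=False)
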