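"""Sequencing-validity diagnostics for ribosome profiling.

Three checks distinguish genuine ribosome footprints from generic RNA
fragments: (1) agreement of biological replicates (Pearson r of log2 RPM),
(2) triplet periodicity of footprint 5' ends — ribosomes advance codon by
codon, so 5' ends pile onto one reading frame — and (3) a metagene density
profile around the start codon, where initiating ribosomes dwell and
produce a sharp peak (here, of 5' ends about 4 codons upstream of the AUG).
mRNA-Seq fragments show neither periodicity nor a start peak.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Annotation

log = logging.getLogger(__name__)

FRAME_LABELS = {0: "0", 1: "+1", 2: "-1"}


@dataclass(frozen=True)
class FrameProfile:
    """Fractions of read 5' ends on the main frame (0) and the two
    off-frames (+1, -1)."""

    frac_frame0: float
    frac_plus1: float
    frac_minus1: float
    n_reads: int

    def as_dict(self) -> dict[str, float]:
        return {"0": self.frac_frame0, "+1": self.frac_plus1, "-1": self.frac_minus1}


@dataclass(frozen=True)
class MetageneProfile:
    """Per-position footprint 5'-end density around the start codon,
    normalised so the mean over the normalisation window is 1."""

    positions: np.ndarray  # nt relative to start-codon base 0
    density: np.ndarray
    n_genes_used: int
    n_genes_excluded: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"position": self.positions, "density": self.density})


@dataclass(frozen=True)
class StartPeak:
    position_nt: int
    position_codon: int
    fold_over_median: float


def replicate_correlation(
    rpm_a: pd.Series, rpm_b: pd.Series, pseudocount: float = 0.5
) -> float:
    """Pearson r between two samples' log2(RPM + pseudocount) values."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if not rpm_a.index.equals(rpm_b.index):
        rpm_b = rpm_b.reindex(rpm_a.index)
        if rpm_b.isna().any():
            raise ValueError("samples do not share a gene set")
    if len(rpm_a) < 3:
        raise ValueError("need at least 3 genes for a correlation")
    x = np.log2(rpm_a.to_numpy(dtype=float) + pseudocount)
    y = np.log2(rpm_b.to_numpy(dtype=float) + pseudocount)
    return float(np.corrcoef(x, y)[0, 1])


def read_frames(reads: pd.DataFrame) -> np.ndarray:
    """Reading-frame index of each 5' end: ((pos mod 3) + 3) mod 3 in 0..2."""
    return np.mod(reads["five_prime_pos"].to_numpy(), 3)


def _fractions(frames: np.ndarray) -> FrameProfile:
    n = frames.size
    counts = np.bincount(frames, minlength=3)
    f = counts / n
    return FrameProfile(float(f[0]), float(f[1]), float(f[2]), int(n))


def frame_periodicity(
    reads: pd.DataFrame, annotation: Annotation | None = None
) -> tuple[FrameProfile, pd.DataFrame]:
    """Global and per-gene frame fractions of read 5' ends.

    Frame index 0 is the main coding frame; indices 1 and 2 are reported as
    "+1" and "-1".  Genes with no reads are absent from the per-gene table.
    Returns ``(global_profile, per_gene)`` where ``per_gene`` has columns
    frac_frame0, frac_plus1, frac_minus1, n_reads indexed by gene.
    """
    if len(reads) == 0:
        raise ValueError("no reads: frame periodicity undefined")
    frames = read_frames(reads)
    global_profile = _fractions(frames)

    df = pd.DataFrame({"gene_id": reads["gene_id"].to_numpy(), "frame": frames})
    tab = (
        df.groupby(["gene_id", "frame"], sort=True)
        .size()
        .unstack("frame", fill_value=0)
        .reindex(columns=[0, 1, 2], fill_value=0)
    )
    n = tab.sum(axis=1)
    per_gene = pd.DataFrame(
        {
            "frac_frame0": tab[0] / n,
            "frac_plus1": tab[1] / n,
            "frac_minus1": tab[2] / n,
            "n_reads": n.astype(int),
        }
    )
    return global_profile, per_gene


def metagene_profile(
    reads: pd.DataFrame,
    annotation: Annotation,
    window: tuple[int, int] = (-25, 115),
    norm_len: int = 140,
    per_gene_normalized: bool = False,
) -> MetageneProfile:
    """Aggregate 5'-end density around the start codon.

    Counts of read 5' ends are accumulated at each position of ``window``
    (half-open, default -25..+114) over all genes long enough to span it,
    then divided by the mean over the first ``norm_len`` window positions.
    With ``per_gene_normalized`` each gene's positional counts are first
    scaled to mean 1 so deep genes do not dominate the sum.
    """
    start, stop = window
    span = stop - start
    if norm_len > span:
        raise ValueError(f"norm_len {norm_len} exceeds window span {span}")

    ok_ids = [g.gene_id for g in annotation if g.cds_length >= stop]
    n_excl = len(annotation) - len(ok_ids)
    if not ok_ids:
        raise ValueError("no gene spans the metagene window")
    if n_excl:
        log.info("metagene: excluded %d gene(s) shorter than the window", n_excl)

    sub = reads[reads["gene_id"].isin(ok_ids)]
    pos = sub["five_prime_pos"].to_numpy()
    in_win = (pos >= start) & (pos < stop)
    sub = sub[in_win]
    offsets = sub["five_prime_pos"].to_numpy() - start

    if per_gene_normalized:
        sums = np.zeros(span)
        for _, grp in sub.groupby("gene_id", sort=False):
            h = np.bincount(grp["five_prime_pos"].to_numpy() - start, minlength=span)
            m = h.mean()
            if m > 0:
                sums += h / m
    else:
        sums = np.bincount(offsets, minlength=span).astype(float)

    norm = sums[:norm_len].mean()
    if norm == 0:
        raise ValueError("empty metagene window: cannot normalise")
    return MetageneProfile(
        positions=np.arange(start, stop),
        density=sums / norm,
        n_genes_used=len(ok_ids),
        n_genes_excluded=n_excl,
    )


def find_start_peak(
    profile: MetageneProfile, min_fold: float = 3.0
) -> StartPeak | None:
    """Call the start-codon dwell peak: the density maximum, if it exceeds
    ``min_fold`` times the median density; otherwise ``None`` ("no peak").

    The codon coordinate is the nt position floor-divided by 3 (toward -inf),
    so -12 nt is codon -4.
    """
    i = int(np.argmax(profile.density))
    peak = float(profile.density[i])
    med = float(np.median(profile.density))
    if med <= 0 or peak < min_fold * med:
        return None
    pos = int(profile.positions[i])
    return StartPeak(
        position_nt=pos,
        position_codon=pos // 3,
        fold_over_median=peak / med,
    )
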