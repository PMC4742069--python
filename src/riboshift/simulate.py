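"""Synthetic ribosome-profiling and mRNA-Seq data with the statistical
structure the downstream analysis assumes.

The generator emulates the study design this pipeline targets: two
biological replicates per condition, each pooling equal aliquots from three
mice; ~30-nt ribosome-protected footprints whose 5' ends show triplet
periodicity and a dwell peak 12 nt (4 codons) upstream of the start codon;
uniform non-periodic mRNA-Seq fragments; lognormal inter-mouse expression
variation on top of multinomial counting noise at fixed sequencing depth;
and injected condition effects — per-gene transcription and translation fold
changes, plus a translational-efficiency suppression of TOP-motif genes
under the exercise condition.

Everything is driven by a single integer seed; identical configurations
yield byte-identical output.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import Annotation, GeneModel, READ_COLUMNS

__all__ = [
    "SimulationConfig",
    "PanelConfig",
    "simulate_annotation",
    "simulate_abundances",
    "simulate_rpf_reads",
    "simulate_mrna_reads",
    "simulate_counts",
    "simulate_panel",
    "mouse_cv_for_fraction_sd",
]

#: Footprint length distribution over 26..34 nt, peaked at 30 nt.
DEFAULT_FOOTPRINT_LENGTHS = tuple(range(26, 35))
DEFAULT_FOOTPRINT_WEIGHTS = (0.01, 0.03, 0.07, 0.15, 0.40, 0.15, 0.10, 0.06, 0.03)

CONDITIONS = ("control", "exercise")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the sequencing-data generator.

    The defaults encode the study conditions this pipeline is built around:
    1010 genes of which 60 carry a TOP motif, two replicates of three pooled
    mice per condition, one million reads per library, a strong frame-0 bias
    of the footprint 5' ends and a 20-fold start-codon dwell peak whose 5'
    ends fall 12 nt upstream of the AUG.
    """

    seed: int = 0
    n_genes: int = 1010
    cds_length_range: tuple[int, int] = (150, 3000)
    top_fraction: float = 60 / 1010
    footprint_lengths: tuple[int, ...] = DEFAULT_FOOTPRINT_LENGTHS
    footprint_weights: tuple[float, ...] = DEFAULT_FOOTPRINT_WEIGHTS
    frame0_bias: float = 0.85
    start_peak_fold: float = 20.0
    peak_offset_nt: int = -12
    depth_rpf: int = 1_000_000
    depth_mrna: int = 1_000_000
    n_mice_per_replicate: int = 3
    n_replicates: int = 2
    mouse_cv: float = 0.1
    abundance_sigma: float = 1.5
    te_sigma: float = 0.5
    #: gene_id -> (transcription_fold, translation_fold) applied under exercise
    effects: dict[str, tuple[float, float]] = field(default_factory=dict)
    top_te_fold: float = 0.7

    def __post_init__(self) -> None:
        if not (1 / 3 < self.frame0_bias <= 1):
            raise ValueError("frame0_bias must lie in (1/3, 1]")
        if self.start_peak_fold < 1:
            raise ValueError("start_peak_fold must be >= 1")
        if self.depth_rpf < 0 or self.depth_mrna < 0:
            raise ValueError("depths must be non-negative")
        if self.top_te_fold <= 0:
            raise ValueError("top_te_fold must be > 0")
        if any(f <= 0 for pair in self.effects.values() for f in pair):
            raise ValueError("effect folds must be > 0")
        if len(self.footprint_lengths) != len(self.footprint_weights):
            raise ValueError("footprint length/weight vectors differ in length")


@dataclass(frozen=True)
class PanelConfig:
    """Parameters of the qPCR/densitometry expression-panel generator.

    ``group_means`` holds per-group mean relative expression for each
    predictor (NoEx baseline 1.0); the response is the configured linear
    combination of the predictors plus Gaussian noise.  The default
    coefficient vector plants a signal on Pmpca (+2.81), Immp2l (-3.32),
    Nrf2 (-0.59) and Mmp2 (+0.275); the remaining predictors are inert.
    """

    seed: int = 0
    n_per_group: int = 6
    groups: tuple[str, ...] = ("NoEx", "0h", "1h", "2h", "4h")
    group_means: dict[str, dict[str, float]] | None = None
    coefficients: dict[str, float] | None = None
    intercept: float = 1.0
    predictor_sd: float = 0.3
    noise_sd: float = 0.3

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.noise_sd < 0 or self.predictor_sd < 0:
            raise ValueError("noise sds must be >= 0")


#: Mean relative expression per predictor per group; trajectories follow the
#: qualitative time-course of the measured panel (transcript burst at 0h,
#: Nrf2/Mmp2 induction, Immp2l dip at 1h, Pmpca/Yme1l1 rise at 2h).
DEFAULT_GROUP_MEANS: dict[str, dict[str, float]] = {
    "Slc25a25_mRNA": {"NoEx": 1.0, "0h": 7.0, "1h": 3.0, "2h": 1.5, "4h": 1.2},
    "Mmp2": {"NoEx": 1.0, "0h": 2.0, "1h": 1.5, "2h": 1.2, "4h": 1.0},
    "Nrf2": {"NoEx": 1.0, "0h": 3.0, "1h": 2.0, "2h": 1.3, "4h": 1.1},
    "Atrogin1": {"NoEx": 1.0, "0h": 0.8, "1h": 0.7, "2h": 0.8, "4h": 0.9},
    "MuRF1": {"NoEx": 1.0, "0h": 0.8, "1h": 0.8, "2h": 0.9, "4h": 1.0},
    "Pmpca": {"NoEx": 1.0, "0h": 1.0, "1h": 1.2, "2h": 1.5, "4h": 1.3},
    "Yme1l1": {"NoEx": 1.0, "0h": 1.0, "1h": 1.1, "2h": 1.4, "4h": 1.2},
    "Immp2l": {"NoEx": 1.0, "0h": 0.9, "1h": 0.6, "2h": 0.8, "4h": 0.9},
}

DEFAULT_COEFFICIENTS: dict[str, float] = {
    "Slc25a25_mRNA": 0.0,
    "Mmp2": 0.275,
    "Nrf2": -0.59,
    "Atrogin1": 0.0,
    "MuRF1": 0.0,
    "Pmpca": 2.81,
    "Yme1l1": 0.0,
    "Immp2l": -3.32,
}


def _rng(seed: int, *key: object) -> np.random.Generator:
    """Generator keyed by (seed, purpose) so stages draw independent streams."""
    tokens = [zlib.crc32(str(k).encode()) for k in key]
    return np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, *tokens]))


def mouse_cv_for_fraction_sd(
    sd_f: float, n_mice: int = 3, p: float = 0.5
) -> float:
    """Inter-mouse CV that yields a target biological SD of the replicate
    read fraction.

    For small CV, a replicate pooling ``n_mice`` mice has relative SD
    cv/sqrt(n_mice); linearising f = A/(A+B) around p gives
    SD(f) ≈ p(1-p) * sqrt(2) * cv / sqrt(n_mice).
    """
    return sd_f * np.sqrt(n_mice) / (p * (1 - p) * np.sqrt(2))


def simulate_annotation(config: SimulationConfig) -> Annotation:
    """Draw gene models: CDS lengths in range rounded to codon multiples,
    a seeded subset flagged as TOP."""
    rng = _rng(config.seed, "annotation")
    lo, hi = config.cds_length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_genes)
    lengths = np.maximum((lengths // 3) * 3, max(3, (lo // 3) * 3))
    n_top = int(round(config.top_fraction * config.n_genes))
    top_idx = set(rng.choice(config.n_genes, size=n_top, replace=False).tolist())
    width = len(str(config.n_genes))
    return Annotation(
        GeneModel(
            gene_id=f"g{i + 1:0{width}d}",
            cds_length=int(lengths[i]),
            is_top=i in top_idx,
        )
        for i in range(config.n_genes)
    )


@dataclass(frozen=True)
class Abundances:
    """Per-(gene, replicate) expected abundances for one condition.

    ``rna`` drives mRNA-Seq fragment counts; ``loading`` (ribosome
    occupancy = RNA x translational efficiency) drives footprint counts.
    Both are genes x replicates DataFrames.
    """

    condition: str
    rna: pd.DataFrame
    loading: pd.DataFrame


def _base_abundances(config: SimulationConfig, annotation: Annotation):
    rng = _rng(config.seed, "base")
    n = len(annotation)
    base_rna = rng.lognormal(mean=0.0, sigma=config.abundance_sigma, size=n)
    base_te = rng.lognormal(mean=0.0, sigma=config.te_sigma, size=n)
    return pd.Series(base_rna, index=annotation.gene_ids), pd.Series(
        base_te, index=annotation.gene_ids
    )


def simulate_abundances(
    config: SimulationConfig, annotation: Annotation, condition: str
) -> Abundances:
    """Expected RNA and ribosome-loading abundance per gene per replicate.

    Each replicate pools ``n_mice_per_replicate`` mice; every mouse carries a
    per-gene lognormal(0, mouse_cv) multiplier, and the replicate abundance
    is the arithmetic mean over its mice (equal aliquots).  The same mouse
    multipliers apply to RNA and to ribosome loading of that replicate (both
    libraries derive from the same pooled lysate).  Under exercise, RNA is
    scaled by the gene's transcription fold; ribosome loading additionally by
    its translation fold, and for TOP genes by ``top_te_fold``.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}, got {condition!r}")
    base_rna, base_te = _base_abundances(config, annotation)
    gene_ids = annotation.gene_ids
    n = len(gene_ids)

    rna_cols, load_cols = {}, {}
    for rep in range(1, config.n_replicates + 1):
        rng = _rng(config.seed, "mice", condition, rep)
        if config.mouse_cv > 0:
            mult = rng.lognormal(
                mean=0.0,
                sigma=config.mouse_cv,
                size=(config.n_mice_per_replicate, n),
            ).mean(axis=0)
        else:
            mult = np.ones(n)
        rna = base_rna.to_numpy() * mult
        loading = rna * base_te.to_numpy()
        if condition == "exercise":
            tf = np.ones(n)
            tl = np.ones(n)
            for i, gid in enumerate(gene_ids):
                if gid in config.effects:
                    tf[i], tl[i] = config.effects[gid]
            rna = rna * tf
            loading = loading * tf * tl
            is_top = np.array([annotation[g].is_top for g in gene_ids])
            loading = np.where(is_top, loading * config.top_te_fold, loading)
        name = f"rep{rep}"
        rna_cols[name] = rna
        load_cols[name] = loading

    idx = pd.Index(gene_ids, name="gene_id")
    return Abundances(
        condition=condition,
        rna=pd.DataFrame(rna_cols, index=idx),
        loading=pd.DataFrame(load_cols, index=idx),
    )


def simulate_counts(
    config: SimulationConfig,
    abundance: pd.Series,
    depth: int,
    sample_id: str,
) -> pd.Series:
    """Multinomial gene counts at fixed depth, proportional to abundance.

    Count-level equivalent of the read simulators (the read path assigns
    genes from the same multinomial law); library size equals ``depth``
    exactly.
    """
    rng = _rng(config.seed, "counts", sample_id)
    p = abundance.to_numpy() / abundance.to_numpy().sum()
    counts = rng.multinomial(int(depth), p)
    return pd.Series(counts, index=abundance.index, name=sample_id)


# reads are drawn on the codon grid; keep 36 nt of 3'-slack so any footprint
# length up to 34 nt fits inside the CDS regardless of frame offset
_MAX_FOOTPRINT = 34
_BODY_SLACK = 36


def _gene_arrays(annotation: Annotation):
    ids = np.array(annotation.gene_ids)
    cds = np.array([annotation[g].cds_length for g in ids])
    return ids, cds


def simulate_rpf_reads(
    config: SimulationConfig,
    annotation: Annotation,
    abundances: Abundances,
    sample_id: str,
    replicate: str = "rep1",
) -> pd.DataFrame:
    """Draw ribosome footprints for one library.

    Genes receive reads from a multinomial over ribosome loading at total
    depth ``depth_rpf``.  Within a gene, a read is either part of the
    start-codon dwell peak (point mass at ``peak_offset_nt``, relative weight
    ``start_peak_fold`` versus 1 per body position) or a CDS-body read whose
    5' end sits on a uniformly drawn codon with frame offset 0 with
    probability ``frame0_bias`` and +1/-1 with probability (1-q)/2 each.
    Footprint lengths follow the configured 26..34 nt distribution.
    """
    rng = _rng(config.seed, "rpf", sample_id)
    ids, cds = _gene_arrays(annotation)
    loading = abundances.loading[replicate].to_numpy()
    n_per_gene = rng.multinomial(config.depth_rpf, loading / loading.sum())

    gene_idx = np.repeat(np.arange(len(ids)), n_per_gene)
    n = gene_idx.size
    if n == 0:
        return pd.DataFrame(columns=READ_COLUMNS)

    lengths = rng.choice(
        np.array(config.footprint_lengths),
        size=n,
        p=np.array(config.footprint_weights) / np.sum(config.footprint_weights),
    )

    n_codons = (cds - _BODY_SLACK) // 3 + 1  # usable body codons per gene
    n_body_pos = np.maximum(n_codons * 3, 1)
    p_peak = config.start_peak_fold / (n_body_pos + config.start_peak_fold)
    is_peak = rng.random(n) < p_peak[gene_idx]

    codon = np.floor(rng.random(n) * n_codons[gene_idx]).astype(np.int64)
    q = config.frame0_bias
    frame = rng.choice(np.array([0, 1, 2]), size=n, p=[q, (1 - q) / 2, (1 - q) / 2])
    pos = np.where(is_peak, config.peak_offset_nt, codon * 3 + frame)

    return pd.DataFrame(
        {
            "gene_id": ids[gene_idx],
            "five_prime_pos": pos,
            "length": lengths,
        }
    )


def simulate_mrna_reads(
    config: SimulationConfig,
    annotation: Annotation,
    abundances: Abundances,
    sample_id: str,
    replicate: str = "rep1",
) -> pd.DataFrame:
    """Draw mRNA-Seq fragments: uniform 5' positions over the extended
    reference, no frame bias, no start peak; gene totals multinomial over RNA
    abundance at depth ``depth_mrna``."""
    rng = _rng(config.seed, "mrna", sample_id)
    ids, cds = _gene_arrays(annotation)
    ext = np.array([annotation[g].upstream_extension for g in ids])
    rna = abundances.rna[replicate].to_numpy()
    if config.depth_mrna == 0:
        return pd.DataFrame(columns=READ_COLUMNS)
    n_per_gene = rng.multinomial(config.depth_mrna, rna / rna.sum())

    gene_idx = np.repeat(np.arange(len(ids)), n_per_gene)
    n = gene_idx.size
    lengths = rng.choice(
        np.array(config.footprint_lengths),
        size=n,
        p=np.array(config.footprint_weights) / np.sum(config.footprint_weights),
    )
    lo = -ext[gene_idx]
    hi = cds[gene_idx] - lengths  # inclusive upper bound for the 5' end
    pos = lo + np.floor(rng.random(n) * (hi - lo + 1)).astype(np.int64)
    return pd.DataFrame(
        {
            "gene_id": ids[gene_idx],
            "five_prime_pos": pos,
            "length": lengths,
        }
    )


def simulate_panel(pconfig: PanelConfig) -> pd.DataFrame:
    """Generate a per-mouse expression panel.

    Predictors are Gaussian around their group means (SD ``predictor_sd``);
    the response is ``intercept + sum(coef * predictor) + N(0, noise_sd)``.
    Returns a DataFrame with columns mouse_id, group, Slc25a25_protein and
    the eight predictor genes.
    """
    from .io import PANEL_PREDICTORS, PANEL_RESPONSE

    rng = _rng(pconfig.seed, "panel")
    means = pconfig.group_means or DEFAULT_GROUP_MEANS
    coefs = pconfig.coefficients or DEFAULT_COEFFICIENTS

    rows = []
    mouse = 0
    for group in pconfig.groups:
        for _ in range(pconfig.n_per_group):
            mouse += 1
            rec: dict[str, object] = {"mouse_id": f"m{mouse:02d}", "group": group}
            for var in PANEL_PREDICTORS:
                mu = means.get(var, {}).get(group, 1.0)
                rec[var] = mu + rng.normal(0.0, pconfig.predictor_sd)
            response = pconfig.intercept + sum(
                coefs.get(var, 0.0) * float(rec[var]) for var in PANEL_PREDICTORS
            )
            rec[PANEL_RESPONSE] = response + rng.normal(0.0, pconfig.noise_sd)
            rows.append(rec)
    df = pd.DataFrame(rows)
    cols = ["mouse_id", "group", PANEL_RESPONSE, *PANEL_PREDICTORS]
    return df[cols]
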