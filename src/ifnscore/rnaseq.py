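"""RNA-seq side of the IFN signature: FPKM, fold changes, PCA screening.

Inputs are gene-level count tables in the featureCounts output dialect
(``Geneid Chr Start End Strand Length <sample...>``, '#' comment lines) or
a plain ``gene_id,length,<samples>`` table. Counts are normalized either by
FPKM (for variability assessment of the panel genes across controls) or by
median-of-ratios size factors (for patient-vs-control fold changes that
feed the same median IFN score as the qPCR pipeline).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .errors import FormatError, ParseError, ValidationError
from .panel import DEFAULT_PANEL, GenePanel

logger = logging.getLogger(__name__)

_FEATURECOUNTS_META = ["Chr", "Start", "End", "Strand"]


@dataclass(frozen=True)
class CountsMatrix:
    """Gene × sample integer counts with per-gene feature lengths (bp)."""

    counts: pd.DataFrame  # genes × samples
    lengths: pd.Series  # index aligned with counts rows, bp

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.lengths.index):
            raise ValidationError("counts and lengths must share the same gene index")
        if (self.lengths <= 0).any():
            bad = list(self.lengths.index[self.lengths <= 0])
            raise ValidationError(f"non-positive gene length(s): {bad[:5]}")
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("counts must be non-negative")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def rename_genes(self, mapping: dict[str, str]) -> "CountsMatrix":
        return CountsMatrix(
            counts=self.counts.rename(index=mapping),
            lengths=self.lengths.rename(index=mapping),
        )


def read_counts(
    path: str | Path, symbol_map: str | Path | None = None
) -> CountsMatrix:
    """Read a featureCounts-style TSV (or a plain gene_id/length table).

    '#' program lines are skipped. If ``symbol_map`` is given it must be a
    two-column TSV mapping gene ids (e.g. Ensembl) to panel symbols; mapped
    ids are renamed, others kept as-is.
    """
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    cols = list(df.columns)
    if "Geneid" in cols and "Length" in cols:
        id_col, length_col = "Geneid", "Length"
        sample_cols = [c for c in cols if c not in [id_col, length_col] + _FEATURECOUNTS_META]
    elif len(cols) >= 3 and cols[1].lower() == "length":
        id_col, length_col = cols[0], cols[1]
        sample_cols = cols[2:]
    else:
        raise FormatError(
            "unrecognized counts dialect: need featureCounts columns "
            "(Geneid/.../Length/samples) or gene_id,length,<samples>"
        )
    if not sample_cols:
        raise FormatError("counts table has no sample columns")
    ids = df[id_col].astype(str)
    if ids.duplicated().any():
        dup = sorted(set(ids[ids.duplicated()]))
        raise FormatError(f"duplicate gene id(s): {dup}")
    try:
        counts = df[sample_cols].astype(float)
    except ValueError as exc:
        raise ParseError(f"non-numeric count value: {exc}") from exc
    if (counts.to_numpy() < 0).any():
        raise ParseError("negative count encountered")
    counts.index = pd.Index(ids, name="gene_id")
    lengths = pd.to_numeric(df[length_col]).astype(float)
    lengths.index = counts.index
    matrix = CountsMatrix(counts=counts, lengths=lengths)
    if symbol_map is not None:
        mapping_df = pd.read_csv(symbol_map, sep="\t", header=None, comment="#")
        mapping = dict(zip(mapping_df[0].astype(str), mapping_df[1].astype(str)))
        matrix = matrix.rename_genes(mapping)
    return matrix


def fpkm(matrix: CountsMatrix) -> pd.DataFrame:
    """Fragments per kilobase per million: counts·1e9 / (libsize·length).

    Library size is the per-sample sum of counted reads in the table. Per
    sample the identity Σ_g fpkm·length = 1e9 holds exactly.
    """
    libsize = matrix.counts.sum(axis=0)
    zero = list(libsize.index[libsize == 0])
    if zero:
        raise ValidationError(f"zero library size for sample(s): {zero}")
    return matrix.counts.div(libsize, axis=1).div(matrix.lengths, axis=0) * 1e9


def size_factors(matrix: CountsMatrix) -> pd.Series:
    """Median-of-ratios per-sample scale factors (DESeq-style, unscaled).

    For genes with nonzero counts in every sample, each sample's factor is
    the median ratio of its counts to the per-gene geometric mean.
    """
    counts = matrix.counts
    everywhere = (counts > 0).all(axis=1)
    if not everywhere.any():
        raise ValidationError(
            "no gene has nonzero counts in all samples; consider a pseudo-reference"
        )
    logc = np.log(counts.loc[everywhere])
    log_geomean = logc.mean(axis=1)
    factors = np.exp(logc.sub(log_geomean, axis=0).median(axis=0))
    factors.name = "size_factor"
    return factors


def relative_foldchange(
    matrix: CountsMatrix,
    control_ids: list[str],
    panel: GenePanel = DEFAULT_PANEL,
) -> pd.DataFrame:
    """Panel-gene fold changes of each non-control sample vs. the control mean.

    Counts are normalized by :func:`size_factors`; for each panel gene the
    fold change is the sample's normalized value divided by the mean of the
    controls' normalized values (missing, never infinite, if that mean is
    zero). Feeding the result to :func:`ifnscore.qpcr.ifn_score` gives the
    RNA-seq IFN score.
    """
    missing = [s for s in control_ids if s not in matrix.sample_ids]
    if missing:
        raise ValidationError(f"control id(s) not in counts matrix: {missing}")
    if len(control_ids) < 2:
        raise ValidationError("need at least 2 control samples")
    absent = [g for g in panel.targets if g not in matrix.gene_ids]
    if absent:
        raise ValidationError(f"panel gene(s) absent from counts: {absent}")
    norm = matrix.counts.div(size_factors(matrix), axis=1)
    panel_norm = norm.loc[list(panel.targets)]
    control_mean = panel_norm[control_ids].mean(axis=1)
    patients = [s for s in matrix.sample_ids if s not in set(control_ids)]
    fc = panel_norm[patients].div(control_mean, axis=0).T
    zero_mean = list(control_mean.index[control_mean == 0])
    if zero_mean:
        logger.warning("zero control mean for gene(s) %s; fold change missing", zero_mean)
        fc[zero_mean] = np.nan
    fc.index.name = "sample_id"
    return fc


@dataclass(frozen=True)
class PcaScreenResult:
    """PC scores, robust z-scores and outlier flags for candidate controls."""

    frame: pd.DataFrame  # sample_id × (pc1, pc2, robust_z1, robust_z2, outlier)
    explained_variance_ratio: tuple[float, float]
    threshold: float
    dropped_genes: tuple[str, ...]

    @property
    def outliers(self) -> list[str]:
        return list(self.frame.index[self.frame["outlier"]])


def _robust_z(x: np.ndarray) -> np.ndarray:
    med = np.median(x)
    mad = np.median(np.abs(x - med)) * 1.4826
    dev = x - med
    if mad == 0:
        # degenerate spread: only deviations above numerical noise count
        eps = 1e-9 * max(1.0, float(np.abs(x).max()))
        return np.where(np.abs(dev) <= eps, 0.0, np.inf)
    return dev / mad


def pca_screen(
    expr: pd.DataFrame,
    panel: GenePanel = DEFAULT_PANEL,
    threshold: float = 3.0,
) -> PcaScreenResult:
    """Flag candidate healthy controls with outlying panel-gene expression.

    ``expr`` is an FPKM matrix (genes × samples). Panel-gene rows are
    log2(fpkm+1)-transformed, centered and unit-scaled across samples, and
    decomposed by PCA (SVD). A sample is flagged when its median/MAD robust
    z-score on PC1 or PC2 exceeds ``threshold`` in absolute value.
    """
    if expr.shape[1] < 4:
        raise ValidationError("PCA screening needs at least 4 samples")
    absent = [g for g in panel.targets if g not in expr.index]
    if absent:
        raise ValidationError(f"panel gene(s) absent from expression matrix: {absent}")
    X = np.log2(expr.loc[list(panel.targets)].astype(float) + 1.0)
    sds = X.std(axis=1, ddof=0)
    dropped = tuple(sds.index[sds == 0])
    if dropped:
        logger.warning("constant gene(s) dropped before PCA: %s", list(dropped))
        X = X.loc[sds > 0]
    if X.shape[0] == 0:
        # every gene constant across samples: no variability, nothing to flag
        zeros = np.zeros(expr.shape[1])
        frame = pd.DataFrame(
            {"pc1": zeros, "pc2": zeros, "robust_z1": zeros, "robust_z2": zeros,
             "outlier": np.zeros(expr.shape[1], dtype=bool)},
            index=pd.Index(expr.columns, name="sample_id"),
        )
        return PcaScreenResult(
            frame=frame, explained_variance_ratio=(0.0, 0.0),
            threshold=float(threshold), dropped_genes=dropped,
        )
    if X.shape[0] < 2:
        raise ValidationError("fewer than 2 variable panel genes; cannot run PCA")
    Z = X.sub(X.mean(axis=1), axis=0).div(X.std(axis=1, ddof=0), axis=0)
    pca = PCA(n_components=2, svd_solver="full")
    scores = pca.fit_transform(Z.T.to_numpy())
    z1 = _robust_z(scores[:, 0])
    z2 = _robust_z(scores[:, 1])
    frame = pd.DataFrame(
        {
            "pc1": scores[:, 0],
            "pc2": scores[:, 1],
            "robust_z1": z1,
            "robust_z2": z2,
            "outlier": (np.abs(z1) > threshold) | (np.abs(z2) > threshold),
        },
        index=pd.Index(expr.columns, name="sample_id"),
    )
    evr = pca.explained_variance_ratio_
    return PcaScreenResult(
        frame=frame,
        explained_variance_ratio=(float(evr[0]), float(evr[1])),
        threshold=float(threshold),
        dropped_genes=dropped,
    )
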