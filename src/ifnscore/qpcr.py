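"""Relative quantification of qPCR data and the median-of-ISGs IFN score.

The pipeline is the classic comparative-Ct (2^−ΔΔCt) method: each target
gene's cycle threshold is normalized within-sample against housekeeping
genes (ΔCt), referenced to a calibrator profile (ΔΔCt), and exponentiated
to a fold change RQ = 2^−ΔΔCt. A sample's IFN score is the median RQ over
the panel targets.

Tables are plain pandas objects: a Ct table is a DataFrame indexed by
``sample_id`` with one column per gene (NaN = undetermined reaction); ΔCt
and fold-change tables have one column per target gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ParseError, ValidationError
from .panel import DEFAULT_PANEL, GenePanel

logger = logging.getLogger(__name__)

#: tokens treated as a missing (undetermined) reaction in input CSVs
MISSING_TOKENS = {"", "undetermined", "na", "nan"}

CT_MIN, CT_MAX = 0.0, 45.0


@dataclass(frozen=True)
class CalibratorProfile:
    """Per-target ΔCt of the calibrator all fold changes are relative to.

    ``provenance`` records whether the profile came from a physically pooled
    sample ("physical-sample") or was averaged in software from individual
    controls ("virtual-pool").
    """

    delta_ct: pd.Series  # index: target genes, values: ΔCt in cycles
    provenance: str = "virtual-pool"
    n_controls_pooled: int = 1

    def __post_init__(self) -> None:
        if not np.isfinite(self.delta_ct.to_numpy(dtype=float)).all():
            bad = self.delta_ct.index[~np.isfinite(self.delta_ct.astype(float))]
            raise ValidationError(f"calibrator ΔCt not finite for {list(bad)}")


def read_ct_table(path: str | Path, panel: GenePanel = DEFAULT_PANEL) -> pd.DataFrame:
    """Read a Ct CSV (``sample_id`` first column, one column per gene).

    Empty cells and the token "Undetermined" (any case) are missing values;
    any other non-numeric cell raises :class:`ParseError` naming row and
    column. Every panel gene must be present; extra columns are preserved.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if raw.columns[0] != "sample_id":
        raise FormatError(
            f"first column must be 'sample_id', found {raw.columns[0]!r}"
        )
    raw = raw.set_index("sample_id")
    if raw.index.duplicated().any():
        dup = sorted(set(raw.index[raw.index.duplicated()]))
        raise FormatError(f"duplicate sample_id(s): {dup}")
    for gene in panel.all_genes:
        if gene not in raw.columns:
            raise FormatError(f"missing panel gene column: {gene}")

    def _cell(value: str, sample: str, gene: str) -> float:
        token = value.strip()
        if token.lower() in MISSING_TOKENS:
            return np.nan
        try:
            ct = float(token)
        except ValueError:
            raise ParseError(
                f"non-numeric Ct {value!r} at sample {sample!r}, column {gene!r}"
            ) from None
        if not CT_MIN <= ct <= CT_MAX:
            raise ParseError(
                f"Ct {ct} out of range [{CT_MIN}, {CT_MAX}] "
                f"at sample {sample!r}, column {gene!r}"
            )
        return ct

    ct = pd.DataFrame(
        {
            gene: [_cell(v, s, gene) for s, v in raw[gene].items()]
            for gene in raw.columns
        },
        index=raw.index,
    )
    return ct


def normalize_ct(ct: pd.DataFrame, panel: GenePanel = DEFAULT_PANEL) -> pd.DataFrame:
    """ΔCt = target Ct − mean of the sample's measured housekeeper Cts.

    With two housekeepers this is the standard multi-reference rule
    (arithmetic mean of Cts = geometric mean of quantities). If only one
    housekeeper was measured for a sample it is used alone (warning logged);
    if none was, all the sample's ΔCt are missing and the sample is flagged.
    """
    for hk in panel.housekeepers:
        if hk not in ct.columns:
            raise FormatError(f"housekeeper {hk} absent from Ct table")
    for gene in panel.targets:
        if gene not in ct.columns:
            raise FormatError(f"target {gene} absent from Ct table")

    hk_ct = ct[list(panel.housekeepers)].astype(float)
    n_hk = hk_ct.notna().sum(axis=1)
    hk_mean = hk_ct.mean(axis=1, skipna=True)

    partial = ct.index[(n_hk > 0) & (n_hk < len(panel.housekeepers))]
    if len(partial):
        logger.warning(
            "%d sample(s) have only a subset of housekeepers measured: %s",
            len(partial), list(partial),
        )
    none = ct.index[n_hk == 0]
    if len(none):
        logger.warning(
            "%d sample(s) have no housekeeper measured; their ΔCt are missing: %s",
            len(none), list(none),
        )

    delta = ct[list(panel.targets)].astype(float).sub(hk_mean, axis=0)
    return delta


def make_virtual_calibrator(controls_delta: pd.DataFrame) -> CalibratorProfile:
    """Pool control ΔCt profiles into a virtual calibrator.

    Pooling is the arithmetic mean on the ΔCt (log2) scale — the software
    analogue of mixing equal amounts of control cDNA, and equivalent to a
    geometric mean of the controls' relative quantities. A pool of n
    identical samples therefore equals each sample.
    """
    if len(controls_delta) < 1:
        raise ValidationError("need at least one control sample")
    mean_delta = controls_delta.mean(axis=0, skipna=True)
    empty = mean_delta.index[mean_delta.isna()]
    if len(empty):
        raise ValidationError(
            f"no finite ΔCt in any control for target(s): {list(empty)}"
        )
    return CalibratorProfile(
        delta_ct=mean_delta,
        provenance="virtual-pool",
        n_controls_pooled=len(controls_delta),
    )


def relative_quantification(
    samples_delta: pd.DataFrame, calibrator: CalibratorProfile
) -> pd.DataFrame:
    """RQ = 2^−(ΔCt_sample − ΔCt_calibrator); missing ΔCt stays missing."""
    missing = [g for g in samples_delta.columns if g not in calibrator.delta_ct.index]
    if missing:
        raise ValidationError(f"calibrator lacks ΔCt for target(s): {missing}")
    ddct = samples_delta.sub(calibrator.delta_ct[samples_delta.columns], axis=1)
    return 2.0 ** (-ddct)


def ifn_score(fc: pd.DataFrame, panel: GenePanel = DEFAULT_PANEL) -> pd.DataFrame:
    """Per-sample IFN score: the median of the present panel fold changes.

    Returns a DataFrame indexed like ``fc`` with columns ``score``,
    ``n_genes_used`` and ``reason``. An even count of present genes uses the
    mean of the two central order statistics. Samples with fewer than
    ``panel.min_genes_for_score`` measurable genes get a missing score and a
    reason string rather than a value computed from too few genes.
    """
    targets = [g for g in panel.targets if g in fc.columns]
    extra = set(fc.columns) - set(panel.targets)
    if extra:
        raise ValidationError(f"fold-change table has non-panel columns: {sorted(extra)}")
    rq = fc[targets].astype(float)
    if (rq.dropna(how="all") <= 0).any().any():
        raise ValidationError("fold changes must be strictly positive")
    n_used = rq.notna().sum(axis=1)
    score = rq.median(axis=1, skipna=True)
    ok = n_used >= panel.min_genes_for_score
    out = pd.DataFrame(
        {
            "score": score.where(ok),
            "n_genes_used": n_used,
            "reason": np.where(
                ok, "", f"fewer than {panel.min_genes_for_score} genes measurable"
            ),
        },
        index=fc.index,
    )
    return out


def score_ct_table(
    ct: pd.DataFrame,
    control_ids: list[str],
    panel: GenePanel = DEFAULT_PANEL,
    lod_ct: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """End-to-end qPCR scoring: ΔCt → virtual calibrator → RQ → IFN score.

    ``control_ids`` name the rows of ``ct`` that form the calibrator pool;
    scores are reported for every sample (controls included, so their spread
    around 1 is visible). ``lod_ct`` optionally substitutes a fixed Ct for
    undetermined *target* reactions (limit-of-detection imputation); by
    default undetermined reactions are excluded from the median instead.

    Returns ``(scores, fold_changes)``.
    """
    missing = [s for s in control_ids if s not in ct.index]
    if missing:
        raise ValidationError(f"control id(s) not in Ct table: {missing}")
    if lod_ct is not None:
        ct = ct.copy()
        for gene in panel.targets:
            ct[gene] = ct[gene].fillna(float(lod_ct))
    delta = normalize_ct(ct, panel)
    calibrator = make_virtual_calibrator(delta.loc[control_ids])
    rq = relative_quantification(delta, calibrator)
    scores = ifn_score(rq, panel)
    return scores, rq


def write_scores(
    scores: pd.DataFrame, fc: pd.DataFrame, path: str | Path
) -> None:
    """Write ``sample_id,score,n_genes_used,<gene>_rq,...`` at 6 significant digits."""
    out = scores[["score", "n_genes_used"]].copy()
    for gene in fc.columns:
        out[f"{gene}_rq"] = fc[gene]
    out.to_csv(path, float_format="%.6g", index_label="sample_id")


def read_scores(path: str | Path, platform: str | None = None) -> pd.Series:
    """Read a score CSV written by :func:`write_scores` into a Series of scores."""
    df = pd.read_csv(path).set_index("sample_id")
    if "score" not in df.columns:
        raise FormatError("score CSV must have a 'score' column")
    s = df["score"].astype(float)
    s.name = platform or str(path)
    return s
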