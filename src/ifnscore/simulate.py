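"""Synthetic qPCR and RNA-seq cohorts with the structure the analysis assumes.

The qPCR generator draws housekeeper Cts and per-gene ΔCt values from
normal distributions on the cycle scale; because a fold change is
RQ = 2^−ΔΔCt, normal ΔCt noise makes RQ lognormal, and the requested
fold-change-scale coefficient of variation is mapped to the ΔCt standard
deviation in closed form (:func:`cv_to_logsd`). Patients receive per-gene
log2 fold-change elevations subtracted from their ΔCt; the implied true
score (median of 2^elevation) is returned alongside. The RNA-seq generator
draws negative-binomial counts around FPKM-scale baselines, with filler
genes so that size-factor estimation is well conditioned.

Every generator is a pure function of (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .panel import DEFAULT_PANEL, GenePanel
from .reference import QPCR_CONTROL_SUMMARY, RNASEQ_CONTROL_SUMMARY

LN2 = math.log(2.0)

#: per-gene fold-change CVs of the ten-donor qPCR reference cohort (as
#: published; RSAD2's printed 0.96 differs in the last digit from the
#: rounded ratio of the printed SD and mean)
DEFAULT_TARGET_CV: dict[str, float] = {
    "IFI27": 0.23, "IFI44L": 1.26, "IFIT1": 0.48,
    "ISG15": 0.13, "RSAD2": 0.96, "SIGLEC1": 0.08,
}

#: plausible whole-blood ΔCt means (cycles above housekeeper level)
DEFAULT_DELTA_CT_MEAN: dict[str, float] = {
    "IFI27": 6.0, "IFI44L": 8.0, "IFIT1": 5.0,
    "ISG15": 3.0, "RSAD2": 7.0, "SIGLEC1": 6.5,
}

#: plausible mature-transcript lengths in bp
DEFAULT_GENE_LENGTH: dict[str, int] = {
    "IFI27": 995, "IFI44L": 1919, "IFIT1": 2105,
    "ISG15": 666, "RSAD2": 3139, "SIGLEC1": 5527,
}

#: FPKM baselines of the twenty-donor RNA-seq reference cohort
DEFAULT_BASELINE_FPKM: dict[str, float] = {
    g: float(RNASEQ_CONTROL_SUMMARY[20].loc[g, "mean"])
    for g in RNASEQ_CONTROL_SUMMARY[20].index
}


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Study conditions for the generators (defaults follow the reference cohorts)."""

    panel: GenePanel = DEFAULT_PANEL
    target_delta_ct_mean: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DELTA_CT_MEAN)
    )
    target_cv: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TARGET_CV))
    housekeeper_ct_mean: dict[str, float] = field(
        default_factory=lambda: {"HPRT1": 24.0, "G6PD": 25.0}
    )
    housekeeper_ct_sd: float = 0.5
    #: patient per-gene log2 fold-change elevation distribution
    elevation_log2_mean: float = 3.0
    elevation_log2_sd: float = 1.0
    #: RNA-seq side
    baseline_fpkm: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINE_FPKM)
    )
    gene_length: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GENE_LENGTH))
    dispersion: float = 0.05
    libsize_range: tuple[float, float] = (2e7, 4e7)
    n_filler_genes: int = 200

    def __post_init__(self) -> None:
        for g in self.panel.targets:
            for name, table in (
                ("target_delta_ct_mean", self.target_delta_ct_mean),
                ("target_cv", self.target_cv),
                ("baseline_fpkm", self.baseline_fpkm),
                ("gene_length", self.gene_length),
            ):
                if g not in table:
                    raise ValidationError(f"{name} lacks an entry for {g}")
        if any(cv < 0 for cv in self.target_cv.values()):
            raise ValidationError("CVs must be >= 0")
        if any(l <= 0 for l in self.gene_length.values()):
            raise ValidationError("gene lengths must be > 0")
        if self.dispersion < 0:
            raise ValidationError("dispersion must be >= 0")
        lo, hi = self.libsize_range
        if not 0 < lo <= hi:
            raise ValidationError("libsize_range must be 0 < lo <= hi")


DEFAULT_SPEC = SyntheticCohortSpec()


def cv_to_logsd(cv: float) -> float:
    """ΔCt-scale (log2) SD giving a lognormal fold change with the requested CV.

    For RQ lognormal with natural-log SD σ_ln, CV = √(exp(σ_ln²) − 1), so
    σ_ln = √ln(1 + CV²); dividing by ln 2 converts to the log2/cycle scale.
    """
    if cv < 0:
        raise ValidationError(f"cv must be >= 0, got {cv}")
    return math.sqrt(math.log1p(cv * cv)) / LN2


def _draw_ct(
    spec: SyntheticCohortSpec,
    rng: np.random.Generator,
    ids: list[str],
    elevation_log2: np.ndarray | None = None,
) -> pd.DataFrame:
    """Shared Ct machinery: housekeepers + targets, optional ΔCt elevation."""
    n = len(ids)
    panel = spec.panel
    cols: dict[str, np.ndarray] = {}
    hk = np.empty((n, len(panel.housekeepers)))
    for j, gene in enumerate(panel.housekeepers):
        hk[:, j] = rng.normal(spec.housekeeper_ct_mean[gene], spec.housekeeper_ct_sd, n)
        cols[gene] = hk[:, j]
    hk_mean = hk.mean(axis=1)
    for i, gene in enumerate(panel.targets):
        sd = cv_to_logsd(spec.target_cv[gene])
        delta = rng.normal(spec.target_delta_ct_mean[gene], sd, n)
        if elevation_log2 is not None:
            delta = delta - elevation_log2[:, i]
        cols[gene] = hk_mean + delta
    order = list(panel.targets) + list(panel.housekeepers)
    return pd.DataFrame(cols, index=pd.Index(ids, name="sample_id"))[order]


def simulate_control_ct(
    spec: SyntheticCohortSpec, n: int, seed: int
) -> pd.DataFrame:
    """A healthy-control qPCR Ct table of ``n`` donors."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    ids = [f"HC{i + 1:03d}" for i in range(n)]
    return _draw_ct(spec, rng, ids)


def simulate_patient_ct(
    spec: SyntheticCohortSpec, n_patients: int, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """A patient qPCR Ct table plus the sidecar of true elevations/scores.

    Each patient gets a per-gene log2 fold-change elevation drawn from
    Normal(elevation_log2_mean, elevation_log2_sd); the sidecar records the
    elevations and the implied true score (median of 2^elevation over the
    panel).
    """
    if n_patients < 1:
        raise ValidationError("n_patients must be >= 1")
    rng = np.random.default_rng(seed)
    ids = [f"PT{i + 1:03d}" for i in range(n_patients)]
    panel = spec.panel
    elev = rng.normal(
        spec.elevation_log2_mean, spec.elevation_log2_sd,
        size=(n_patients, len(panel.targets)),
    )
    ct = _draw_ct(spec, rng, ids, elevation_log2=elev)
    truth = pd.DataFrame(
        elev, index=ct.index, columns=[f"elevation_log2_{g}" for g in panel.targets]
    )
    truth["true_score"] = np.median(2.0 ** elev, axis=1)
    return ct, truth


def simulate_counts(
    spec: SyntheticCohortSpec, n_controls: int, n_patients: int, seed: int
):
    """A featureCounts-like matrix of controls + patients, with truth sidecar.

    Counts are NegativeBinomial with mean = baselineFPKM · length · libsize
    / 1e9 · 2^elevation and var = μ + dispersion·μ²; dispersion 0 degenerates
    to Poisson. Filler genes (lognormal baselines) pad the matrix so that
    median-of-ratios size factors are stable. Returns ``(CountsMatrix, truth)``.
    """
    from .rnaseq import CountsMatrix  # local import to avoid a cycle

    if n_controls < 1 or n_patients < 0:
        raise ValidationError("need n_controls >= 1 and n_patients >= 0")
    rng = np.random.default_rng(seed)
    panel = spec.panel
    n = n_controls + n_patients
    ids = [f"HC{i + 1:03d}" for i in range(n_controls)] + [
        f"PT{i + 1:03d}" for i in range(n_patients)
    ]
    genes = list(panel.targets) + [f"FILLER{i + 1:04d}" for i in range(spec.n_filler_genes)]
    base_fpkm = np.array(
        [spec.baseline_fpkm[g] for g in panel.targets]
        + list(rng.lognormal(mean=1.5, sigma=1.2, size=spec.n_filler_genes))
    )
    lengths = np.array(
        [spec.gene_length[g] for g in panel.targets]
        + list(rng.integers(500, 5000, size=spec.n_filler_genes))
    )
    libsize = rng.uniform(*spec.libsize_range, size=n)
    elev = np.zeros((n, len(genes)))
    if n_patients:
        elev[n_controls:, : len(panel.targets)] = rng.normal(
            spec.elevation_log2_mean, spec.elevation_log2_sd,
            size=(n_patients, len(panel.targets)),
        )
    mu = base_fpkm[None, :] * lengths[None, :] * libsize[:, None] / 1e9 * 2.0 ** elev
    if spec.dispersion == 0:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / spec.dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
    counts_df = pd.DataFrame(
        counts.T, index=pd.Index(genes, name="gene_id"), columns=ids
    )
    matrix = CountsMatrix(
        counts=counts_df, lengths=pd.Series(lengths.astype(float), index=counts_df.index)
    )
    truth = pd.DataFrame(
        elev[:, : len(panel.targets)],
        index=pd.Index(ids, name="sample_id"),
        columns=[f"elevation_log2_{g}" for g in panel.targets],
    )
    truth["true_score"] = np.median(2.0 ** elev[:, : len(panel.targets)], axis=1)
    truth["libsize"] = libsize
    return matrix, truth


def simulate_paired_platform(
    spec: SyntheticCohortSpec, n: int, noise_sd_log2: float, seed: int
) -> tuple[pd.Series, pd.Series]:
    """Paired per-subject scores as seen by two platforms.

    Latent true scores are lognormal (log2-normal with mean 1.5, SD 2 —
    spanning roughly 0.3 to 100, like mixed low/intermediate/high signature
    cohorts); each platform observes latent × lognormal noise with log2-scale
    SD ``noise_sd_log2``.
    """
    if n < 5:
        raise ValidationError("n must be >= 5")
    if noise_sd_log2 < 0:
        raise ValidationError("noise_sd_log2 must be >= 0")
    rng = np.random.default_rng(seed)
    ids = pd.Index([f"S{i + 1:03d}" for i in range(n)], name="sample_id")
    latent = 2.0 ** rng.normal(1.5, 2.0, n)
    obs_a = latent * 2.0 ** rng.normal(0.0, noise_sd_log2, n)
    obs_b = latent * 2.0 ** rng.normal(0.0, noise_sd_log2, n)
    a = pd.Series(obs_a, index=ids, name="platform_a")
    b = pd.Series(obs_b, index=ids, name="platform_b")
    return a, b


def write_counts(matrix, path) -> None:
    """Write a CountsMatrix in the featureCounts TSV dialect accepted by
    :func:`ifnscore.rnaseq.read_counts`."""
    df = pd.DataFrame(
        {
            "Geneid": matrix.gene_ids,
            "Chr": "chr1",
            "Start": 1,
            "End": matrix.lengths.astype(int).to_numpy(),
            "Strand": "+",
            "Length": matrix.lengths.astype(int).to_numpy(),
        }
    )
    for s in matrix.sample_ids:
        df[s] = matrix.counts[s].to_numpy().astype(int)
    with open(path, "w") as fh:
        fh.write("# synthetic counts generated by ifnscore.simulate\n")
        df.to_csv(fh, sep="\t", index=False)
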