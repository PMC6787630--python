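"""Shared test helpers: published per-gene λ values and tolerance rules."""

from __future__ import annotations

import numpy as np
import pandas as pd

import ifnscore as ifs
from ifnscore.reference import QPCR_CONTROL_SUMMARY, RNASEQ_CONTROL_SUMMARY

GENES = list(QPCR_CONTROL_SUMMARY.index)

#: published λ rows (per gene, in panel order) and the cohort behind each
PUBLISHED_LAMBDA = {
    ("qpcr", 10): [13.92, 2.52, 6.56, 24.47, 3.28, 38.99],
    ("rnaseq", 15): [6.09, 15.64, 15.16, 9.39, 9.93, 8.21],
    ("rnaseq", 20): [6.68, 14.70, 16.77, 9.34, 10.98, 10.90],
    ("qpcr_projected", 15): [17.05, 3.08, 8.04, 29.97, 4.02, 47.75],
    ("qpcr_projected", 20): [19.69, 3.56, 9.28, 34.61, 4.64, 55.14],
}

PUBLISHED_LAMBDA_REF = {10: 3.15, 15: 3.01, 20: 2.95}


def summary_frame(kind: str) -> pd.DataFrame:
    if kind == "qpcr" or kind == "qpcr_projected":
        return QPCR_CONTROL_SUMMARY
    return RNASEQ_CONTROL_SUMMARY


def lambda_tolerance(mean: float, sd: float, computed: float) -> float:
    """Slack implied by the inputs being printed at two decimals.

    mean and sd each carry half-ulp (±0.005) rounding; λ = (mean/sd)·√n is
    linear in log-space, so the relative slack is the sum of the two relative
    half-ulps, plus the printed λ's own half-ulp.
    """
    return computed * (0.005 / mean + 0.005 / sd) + 0.005


def published_lambda_table(kind: str, n: int) -> pd.DataFrame:
    """Per-gene published λ with the means/SDs they were derived from."""
    if kind == "rnaseq":
        stats = RNASEQ_CONTROL_SUMMARY[n]
    else:
        stats = QPCR_CONTROL_SUMMARY
    out = stats[["mean", "sd"]].copy()
    out["lambda_published"] = PUBLISHED_LAMBDA[(kind, n)]
    return out


def noiseless_platform_scores(n_patients: int = 12, seed: int = 7):
    """Score the same subjects through the qPCR and RNA-seq pipelines.

    Controls are exact replicates of the panel's mean ΔCt profile, so the
    RNA-seq route's arithmetic control mean coincides with the qPCR route's
    geometric-mean virtual calibrator; counts are the deterministic
    round(K · 2^−ΔCt · length) with constant filler genes pinning size
    factors at one. Returns (qpcr_scores, rnaseq_scores) aligned by subject.
    """
    from ifnscore.simulate import DEFAULT_SPEC
    from ifnscore.rnaseq import CountsMatrix

    spec = DEFAULT_SPEC
    panel = spec.panel
    rng = np.random.default_rng(seed)
    ids_c = [f"HC{i}" for i in range(1, 4)]
    ids_p = [f"PT{i}" for i in range(1, n_patients + 1)]
    base = np.array([spec.target_delta_ct_mean[g] for g in panel.targets])
    delta_c = pd.DataFrame(
        np.tile(base, (len(ids_c), 1)), index=ids_c, columns=panel.targets
    )
    elev = rng.normal(1.5, 1.5, size=(n_patients, len(panel.targets)))
    delta_p = pd.DataFrame(base - elev, index=ids_p, columns=panel.targets)
    delta = pd.concat([delta_c, delta_p])

    # qPCR route
    calibrator = ifs.make_virtual_calibrator(delta.loc[ids_c])
    rq = ifs.relative_quantification(delta, calibrator)
    q_scores = ifs.ifn_score(rq)["score"]

    # RNA-seq route: deterministic counts from the same ΔCt profiles
    K = 2.0e5
    lengths = np.array([spec.gene_length[g] for g in panel.targets], dtype=float)
    counts_panel = np.round(K * 2.0 ** (-delta.to_numpy()) * lengths[None, :])
    n_filler = 30
    filler = np.full((len(delta), n_filler), 5.0e4)
    counts = pd.DataFrame(
        np.hstack([counts_panel, filler]).T,
        index=pd.Index(
            list(panel.targets) + [f"FILLER{i}" for i in range(n_filler)],
            name="gene_id",
        ),
        columns=delta.index,
    )
    all_lengths = pd.Series(
        np.concatenate([lengths, np.full(n_filler, 1000.0)]), index=counts.index
    )
    matrix = CountsMatrix(counts=counts, lengths=all_lengths)
    fc = ifs.relative_foldchange(matrix, ids_c)
    r_scores = ifs.ifn_score(fc)["score"]
    return q_scores.loc[ids_p], r_scores.loc[ids_p]
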