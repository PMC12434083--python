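"""Protein-level aggregation and empirical-Bayes moderated statistics.

Normalized peptide L/H ratios are summarized per protein and run by the
median and log2-transformed. For each protein g within a sample-type
group, the one-sample moderated t-test asks whether the mean log2 ratio
differs from 0 (i.e. whether the protein deviates from the 1:1 mixing
background):

    s2_post = (d0 * s0^2 + d_g * s2_g) / (d0 + d_g)
    t_mod   = mean / sqrt(s2_post / n),   df = d0 + d_g

where s2_g is the protein's sample variance with d_g = n - 1 residual
degrees of freedom, and the prior (d0, s0^2) is estimated across all
proteins by the standard method-of-moments fit of a scaled F distribution
to the observed variances: with

    e_g = log(s2_g) - psi(d_g / 2) + log(d_g / 2)

solve  psi'(d0 / 2) = var(e) - mean(psi'(d_g / 2))  for d0 on the
trigamma function (monotone, so a bracketed root-find suffices) and set
s0^2 = exp(mean(e) + psi(d0 / 2) - log(d0 / 2)). When the observed
log-variance dispersion does not exceed what sampling alone explains,
d0 is taken as effectively infinite (capped at ``D0_CAP``) and every
posterior variance collapses to s0^2.

P-values are two-sided from the t distribution with d0 + d_g degrees of
freedom and corrected by Benjamini-Hochberg within each sample type.
"""

from __future__ import annotations

import logging
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import digamma, polygamma
from scipy.stats import t as t_dist

from .errors import DomainError, HyperparameterError
from .filter_engine import STRATUM_KEY

log = logging.getLogger(__name__)

#: Finite stand-in for an infinite prior df ("complete shrinkage").
D0_CAP = 1e6

#: Bracket and tolerance for the trigamma root-find on d0.
_D0_BRACKET = (1e-3, 1e7)
_D0_XTOL = 1e-10


def _trigamma(x):
    return polygamma(1, x)


class ProteinQuant(NamedTuple):
    """Per-run protein summary: median normalized ratio on both scales."""

    protein_ratio: float
    log2_ratio: float
    n_peptides: int


def aggregate_protein(peptide_ratios, peptide_seqs) -> ProteinQuant:
    """Summarize one (protein, run)'s surviving peptides.

    The protein ratio is the median over all surviving peptide
    observations (duplicate rows of one peptide sequence each contribute
    to the median), while ``n_peptides`` counts distinct sequences.
    """
    arr = np.asarray(list(peptide_ratios), dtype=float)
    if arr.size == 0:
        raise DomainError("aggregate_protein requires at least one peptide")
    med = float(np.median(arr))
    return ProteinQuant(med, float(np.log2(med)), len(set(peptide_seqs)))


def fit_hyperparameters(s2, d_g, d0_cap: float = D0_CAP) -> tuple[float, float]:
    """Method-of-moments fit of the variance prior (d0, s0^2).

    ``s2`` is the vector of per-group sample variances; ``d_g`` the
    matching residual degrees of freedom (scalar or vector). Non-positive
    variances carry no information about the prior scale on the log scale
    and are set aside; if fewer than two informative variances remain from
    an otherwise usable input, the fit degenerates to complete shrinkage
    with ``s0^2 = 0`` (every informative variance is exactly zero).
    """
    s2 = np.asarray(s2, dtype=float)
    d = np.broadcast_to(np.asarray(d_g, dtype=float), s2.shape)
    ok = np.isfinite(s2) & (d >= 1)
    if ok.sum() < 2:
        raise HyperparameterError(
            f"need >= 2 groups with d_g >= 1, got {int(ok.sum())}"
        )
    s2, d = s2[ok], d[ok]
    pos = s2 > 0
    if pos.sum() < 2:
        return d0_cap, 0.0
    s2, d = s2[pos], d[pos]

    e = np.log(s2) - digamma(d / 2.0) + np.log(d / 2.0)
    evar = float(np.var(e, ddof=1)) - float(np.mean(_trigamma(d / 2.0)))
    if evar <= 0:
        d0 = d0_cap
    else:
        lo, hi = _D0_BRACKET
        if _trigamma(lo / 2.0) < evar:
            d0 = lo
        elif _trigamma(hi / 2.0) > evar:
            d0 = d0_cap
        else:
            d0 = brentq(lambda x: _trigamma(x / 2.0) - evar, lo, hi, xtol=_D0_XTOL)
            d0 = min(d0, d0_cap)
    s0_2 = float(np.exp(np.mean(e) + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return float(d0), s0_2


class ModeratedResult(NamedTuple):
    mean_log2: float
    s2_g: float
    d_g: float
    s2_post: float
    t_mod: float
    df: float
    p: float


def moderated_test(y, d0: float, s0_2: float) -> ModeratedResult:
    """One-sample moderated t-test of mean(log2 ratio) = 0.

    With ``d0 = 0`` this is exactly the classical one-sample t-test; as
    ``d0`` grows the posterior variance shrinks toward ``s0_2``. Degenerate
    zero posterior variance (noiseless data under complete shrinkage)
    yields t = 0, p = 1 for a zero mean and |t| = inf, p = 0 otherwise.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 2:
        raise DomainError(f"moderated_test requires >= 2 replicates, got {n}")
    mean = float(y.mean())
    s2_g = float(y.var(ddof=1))
    d_g = float(n - 1)
    s2_post = (d0 * s0_2 + d_g * s2_g) / (d0 + d_g)
    df = d0 + d_g
    if s2_post > 0:
        t_mod = mean / np.sqrt(s2_post / n)
        p = 2.0 * t_dist.sf(abs(t_mod), df)
    elif mean == 0.0:
        t_mod, p = 0.0, 1.0
    else:
        t_mod, p = float(np.sign(mean)) * np.inf, 0.0
    return ModeratedResult(mean, s2_g, d_g, float(s2_post), float(t_mod), float(df), float(p))


def bh_adjust(p):
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    Implements the step-up definition directly: on the sorted p-values,
    ``adj_(i) = min_{j >= i} p_(j) * m / j`` capped at 1, mapped back to
    the input order.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise DomainError("p-values must be finite and within [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    adj = np.empty(m)
    adj[order] = adj_sorted
    return adj


def aggregate_proteins_frame(surviving_rows: pd.DataFrame) -> pd.DataFrame:
    """Per-(protein, run) aggregation of surviving peptide rows.

    Returns one row per (protein, sample_type, condition, fa_level,
    replicate) with ``protein_ratio``, ``log2_ratio`` and ``n_peptides``.
    """
    grouped = surviving_rows.groupby(
        ["protein_id"] + STRATUM_KEY + ["replicate"], sort=False
    )
    out = grouped.agg(
        protein_ratio=("ratio_lh_norm", "median"),
        n_peptides=("peptide_seq", "nunique"),
    ).reset_index()
    out["log2_ratio"] = np.log2(out["protein_ratio"])
    return out


def run_differential(
    protein_quants: pd.DataFrame,
    alpha: float = 0.001,
    fc_threshold: float = 2.0,
    d0_cap: float = D0_CAP,
    per_group_fit: bool = False,
) -> pd.DataFrame:
    """Moderated one-sample tests for every (protein, sample_type) group.

    One hyperparameter fit is performed per (condition, fa_level) analysis
    on residual variances pooled across all three sample-type groups —
    mirroring a single linear-model fit with one coefficient per group —
    unless ``per_group_fit`` requests an independent fit per sample type.
    BH correction is applied within each sample type's p-value vector
    (each volcano panel is its own multiplicity universe).

    ``significant`` is ``adj_p <= alpha`` and ``enrichment_fold >=
    fc_threshold``; groups observed in fewer than two replicates are
    skipped with a logged warning.
    """
    results = []
    for (cond, fa), chunk in protein_quants.groupby(["condition", "fa_level"], sort=False):
        groups = []
        for (pid, stype), sub in chunk.groupby(["protein_id", "sample_type"], sort=False):
            y = sub["log2_ratio"].to_numpy()
            if y.size < 2:
                continue
            groups.append(
                {
                    "protein_id": pid,
                    "sample_type": stype,
                    "y": y,
                    "n_peptides_min": int(sub["n_peptides"].min()),
                }
            )
        skipped = chunk.groupby(["protein_id", "sample_type"]).size()
        n_skipped = int((skipped < 2).sum())
        if n_skipped:
            log.warning(
                "analysis (%s, %s): skipped %d protein/sample-type groups with < 2 replicates",
                cond, fa, n_skipped,
            )
        if not groups:
            continue

        s2 = np.array([g["y"].var(ddof=1) for g in groups])
        dg = np.array([g["y"].size - 1 for g in groups], dtype=float)
        stypes = np.array([g["sample_type"] for g in groups])

        def _fit(mask):
            try:
                return fit_hyperparameters(s2[mask], dg[mask], d0_cap)
            except HyperparameterError:
                return d0_cap, 0.0

        if per_group_fit:
            hyper = {st: _fit(stypes == st) for st in np.unique(stypes)}
        else:
            joint = _fit(np.ones(len(groups), dtype=bool))
            hyper = {st: joint for st in np.unique(stypes)}

        for g in groups:
            d0, s0_2 = hyper[g["sample_type"]]
            r = moderated_test(g["y"], d0, s0_2)
            results.append(
                {
                    "protein_id": g["protein_id"],
                    "sample_type": g["sample_type"],
                    "condition": cond,
                    "fa_level": fa,
                    "n_reps": g["y"].size,
                    "n_peptides_min": g["n_peptides_min"],
                    "mean_log2": r.mean_log2,
                    "enrichment_fold": float(2.0 ** r.mean_log2),
                    "s2_g": r.s2_g,
                    "s2_post": r.s2_post,
                    "d0": d0,
                    "s0_2": s0_2,
                    "t_mod": r.t_mod,
                    "df": r.df,
                    "p": r.p,
                }
            )

    if not results:
        return pd.DataFrame(
            columns=[
                "protein_id", "sample_type", "condition", "fa_level", "n_reps",
                "n_peptides_min", "mean_log2", "enrichment_fold", "s2_g", "s2_post",
                "d0", "s0_2", "t_mod", "df", "p", "adj_p", "significant",
            ]
        )
    res = pd.DataFrame(results)
    res["adj_p"] = np.nan
    for _, idx in res.groupby(["condition", "fa_level", "sample_type"], sort=False).groups.items():
        res.loc[idx, "adj_p"] = bh_adjust(res.loc[idx, "p"].to_numpy())
    res["significant"] = (res["adj_p"] <= alpha) & (res["enrichment_fold"] >= fc_threshold)
    return res.sort_values(
        ["condition", "fa_level", "sample_type", "protein_id"]
    ).reset_index(drop=True)
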